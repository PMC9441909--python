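"""Categorical confirmatory factor analysis by DWLS (delta parametrization).

One or more factors measured by binary/ordinal items.  The latent response
variables have unit variance and zero intercepts, factor variances are
fixed at 1, so for items j, k loading on factors f(j), f(k) the implied
polychoric correlation is ``lambda_j * Psi[f(j), f(k)] * lambda_k``.
Thresholds are free parameters; in a single-group model they are exactly
the sample thresholds at the DWLS solution, so the criterion is fitted on
the correlation block and threshold standard errors come straight from the
asymptotic covariance of the first-stage statistics.

Fit assessment follows the limited-information conventions: mean-adjusted
(scaled) test statistic with its trace scaling factor, RMSEA with a
noncentral-chi-square confidence interval, CFI against the
zero-correlation baseline, and SRMR over correlation residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, ncx2, norm

from .dwls import DwlsFit, dwls_fit
from .polychoric import TetrachoricSummary, bvn_cdf

__all__ = [
    "FactorModelSpec",
    "ParameterEstimates",
    "FitResult",
    "ReliabilityResult",
    "FactorCorrelationModel",
    "fit_factor_model",
    "implied_correlations",
    "fit_indices",
    "rmsea_from_t",
    "rmsea_ci",
    "residual_correlations",
    "omega_reliability",
    "IdentificationError",
]


class IdentificationError(ValueError):
    """Model has negative degrees of freedom or an unscaled factor."""


@dataclass
class FactorModelSpec:
    """Loading pattern for a correlated-factors model.

    ``item_factor`` maps each item to the single factor it measures
    (simple structure); factor variances are fixed at 1 and factor
    correlations are free.
    """

    item_factor: np.ndarray  # (J,) int factor index per item
    factor_names: list[str] | None = None

    @property
    def n_factors(self) -> int:
        return int(np.max(self.item_factor)) + 1

    @classmethod
    def one_factor(cls, n_items: int) -> "FactorModelSpec":
        return cls(item_factor=np.zeros(n_items, int))


@dataclass
class ParameterEstimates:
    loadings: np.ndarray
    loadings_se: np.ndarray
    thresholds: list[np.ndarray]
    thresholds_se: list[np.ndarray]
    psi: np.ndarray               # factor correlation matrix
    psi_se: np.ndarray
    ci_level: float = 0.995

    def loading_ci(self) -> np.ndarray:
        z = norm.ppf(0.5 + self.ci_level / 2.0)
        return np.column_stack(
            [self.loadings - z * self.loadings_se, self.loadings + z * self.loadings_se]
        )

    def threshold_ci(self) -> list[np.ndarray]:
        z = norm.ppf(0.5 + self.ci_level / 2.0)
        return [
            np.column_stack([t - z * s, t + z * s])
            for t, s in zip(self.thresholds, self.thresholds_se)
        ]


@dataclass
class FitResult:
    t_scaled: float
    df: int
    sf: float
    pvalue: float
    cfi: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    srmr: float
    bic: float
    n: int
    t_unscaled: float = np.nan
    n_groups: int = 1


@dataclass
class ReliabilityResult:
    omega_latent: float
    omega_sumscore: float


# ---------------------------------------------------------------------------
# Model structure
# ---------------------------------------------------------------------------

class FactorCorrelationModel:
    """Implied polychoric correlations of a simple-structure factor model.

    theta = (lambda_1..lambda_J, psi entries for factor pairs f < g).
    """

    def __init__(self, spec: FactorModelSpec, pairs: list[tuple[int, int]]):
        self.spec = spec
        self.pairs = pairs
        J = spec.item_factor.size
        nf = spec.n_factors
        self.J, self.nf = J, nf
        self.psi_pairs = [(f, g) for f in range(nf) for g in range(f + 1, nf)]
        self.param_names = [f"lambda_{j+1}" for j in range(J)] + [
            f"psi_{f+1}{g+1}" for f, g in self.psi_pairs
        ]

    def _unpack(self, theta):
        lam = theta[: self.J]
        psi = np.eye(self.nf)
        for m, (f, g) in enumerate(self.psi_pairs):
            psi[f, g] = psi[g, f] = theta[self.J + m]
        return lam, psi

    def implied(self, theta):
        lam, psi = self._unpack(theta)
        fac = self.spec.item_factor
        return np.array([lam[j] * lam[k] * psi[fac[j], fac[k]] for j, k in self.pairs])

    def jacobian(self, theta):
        lam, psi = self._unpack(theta)
        fac = self.spec.item_factor
        out = np.zeros((len(self.pairs), theta.size))
        psi_index = {p: self.J + m for m, p in enumerate(self.psi_pairs)}
        for r, (j, k) in enumerate(self.pairs):
            fj, fk = fac[j], fac[k]
            out[r, j] += lam[k] * psi[fj, fk]
            out[r, k] += lam[j] * psi[fj, fk]
            if fj != fk:
                key = (fj, fk) if fj < fk else (fk, fj)
                out[r, psi_index[key]] = lam[j] * lam[k]
        return out

    def start(self, stats):
        # average absolute correlation as a crude communality start
        lam0 = np.full(self.J, 0.6)
        return np.concatenate([lam0, np.zeros(len(self.psi_pairs))])

    def bounds(self):
        return [(-0.995, 0.995)] * self.J + [(-0.995, 0.995)] * len(self.psi_pairs)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _corr_block(summary: TetrachoricSummary):
    """Correlation-part statistics and their asymptotic covariance."""
    nthr = summary.n_thresholds
    s = summary.corr_vector
    xi = summary.asy_cov[nthr:, nthr:]
    return s, xi


def fit_factor_model(summary: TetrachoricSummary, spec: FactorModelSpec | None = None,
                     *, ci_level: float = 0.995):
    """Fit a correlated-factors model to a first-stage summary by DWLS.

    Returns (ParameterEstimates, FitResult, DwlsFit).
    """
    J = summary.n_items
    if spec is None:
        spec = FactorModelSpec.one_factor(J)
    if spec.item_factor.size != J:
        raise IdentificationError("loading pattern does not match summary dimension")
    pairs = summary.pairs
    n_par = J + len([(f, g) for f in range(spec.n_factors)
                     for g in range(f + 1, spec.n_factors)])
    if len(pairs) - n_par < 0:
        raise IdentificationError(
            f"df = {len(pairs) - n_par} < 0: too few items for the factor model"
        )
    s, xi = _corr_block(summary)
    model = FactorCorrelationModel(spec, pairs)
    fit = dwls_fit(s, xi, model, n=summary.n)

    lam = fit.theta[:J]
    lam_se = fit.se[:J]
    psi = np.eye(spec.n_factors)
    psi_se = np.zeros_like(psi)
    for m, (f, g) in enumerate(model.psi_pairs):
        psi[f, g] = psi[g, f] = fit.theta[J + m]
        psi_se[f, g] = psi_se[g, f] = fit.se[J + m]

    if np.any(np.abs(lam) > 0.98):
        import warnings

        warnings.warn("near-boundary (Heywood-adjacent) loading estimate",
                      stacklevel=2)

    thr_se = []
    off = 0
    av = summary.asy_var
    for j in range(J):
        k = summary.n_categories[j] - 1
        thr_se.append(np.sqrt(av[off: off + k]))
        off += k

    params = ParameterEstimates(
        loadings=lam, loadings_se=lam_se,
        thresholds=[t.copy() for t in summary.thresholds],
        thresholds_se=thr_se, psi=psi, psi_se=psi_se, ci_level=ci_level,
    )
    fitres = fit_result_from_dwls(fit)
    return params, fitres, fit


def baseline_t(stats, xi, *, n_free=0):
    """Zero-correlation baseline: T0 and trace for the same statistics."""
    w = 1.0 / np.diag(xi)
    t0 = float(np.dot(w * stats, stats))
    tr = float(np.sum(w * np.diag(xi)))
    df = stats.size - n_free
    sf = tr / df
    return t0 / sf, df


def fit_result_from_dwls(fit: DwlsFit, corr_rows: np.ndarray | None = None) -> FitResult:
    """Assemble global fit indices for a DWLS solution.

    The baseline is the zero-correlation model with free thresholds fitted
    to the same statistics.  ``corr_rows`` selects the correlation entries
    of a stacked statistic vector; when omitted the whole vector is the
    correlation block (single-group fits, thresholds saturated).
    """
    if corr_rows is None:
        sb, xib = fit.stats, fit.asy_cov
    else:
        sb = fit.stats[corr_rows]
        xib = fit.asy_cov[np.ix_(corr_rows, corr_rows)]
    tb, dfb = baseline_t(sb, xib)
    return _assemble_fit(fit, tb, dfb, corr_rows)


def _assemble_fit(fit: DwlsFit, t_baseline: float, df_baseline: int,
                  corr_rows: np.ndarray | None = None) -> FitResult:
    t, df, n = fit.t_scaled, fit.df, fit.n
    G = fit.n_groups
    rm = rmsea_from_t(t, df, n, G)
    ci = rmsea_ci(t, df, n, G)
    num = max(t - df, 0.0)
    den = max(t_baseline - df_baseline, num, 1e-300)
    cfi = 1.0 - num / den if df > 0 else 1.0
    resid = fit.residuals if corr_rows is None else fit.residuals[corr_rows]
    srmr = float(np.sqrt(np.mean(resid ** 2)))
    k = fit.theta.size
    # pseudo-BIC on the chi-square-calibrated (scaled) statistic: the raw
    # DWLS minimum is deflated by the scaling factor, which would make the
    # ln N penalty effectively stricter than in likelihood BIC
    bic = t + k * np.log(n)
    return FitResult(
        t_scaled=t, df=df, sf=fit.sf, pvalue=fit.pvalue, cfi=cfi, rmsea=rm,
        rmsea_ci90=ci, srmr=srmr, bic=bic, n=n, t_unscaled=fit.t0, n_groups=G,
    )


def fit_indices(t: float, df: int, n: int, t_baseline: float, df_baseline: int,
                residuals: np.ndarray, *, n_groups: int = 1,
                t_unscaled: float = np.nan, n_params: int = 0) -> FitResult:
    """Global fit indices from a (scaled) test statistic and baseline.

    RMSEA = sqrt(G * max(T - df, 0) / (df * N)) with the 90% interval from
    inverting the noncentral-chi-square coverage; CFI compares
    noncentrality against the zero-correlation baseline; SRMR is the root
    mean square of the correlation residuals.
    """
    if df == 0:
        rm, ci = np.nan, (np.nan, np.nan)
    else:
        rm = rmsea_from_t(t, df, n, n_groups)
        ci = rmsea_ci(t, df, n, n_groups)
    num = max(t - df, 0.0)
    den = max(t_baseline - df_baseline, num, 1e-300)
    cfi = 1.0 - num / den
    srmr = float(np.sqrt(np.mean(np.asarray(residuals) ** 2)))
    bic = (t_unscaled if np.isfinite(t_unscaled) else t) + n_params * np.log(n)
    return FitResult(t_scaled=t, df=df, sf=np.nan, pvalue=float(chi2.sf(t, df)) if df else np.nan,
                     cfi=cfi, rmsea=rm, rmsea_ci90=ci, srmr=srmr, bic=bic, n=n,
                     t_unscaled=t_unscaled, n_groups=n_groups)


def rmsea_from_t(t: float, df: int, n: int, n_groups: int = 1) -> float:
    if df <= 0:
        return np.nan
    return float(np.sqrt(n_groups * max(t - df, 0.0) / (df * n)))


def rmsea_ci(t: float, df: int, n: int, n_groups: int = 1,
             level: float = 0.90) -> tuple[float, float]:
    """Noncentrality-inversion confidence interval for RMSEA."""
    if df <= 0:
        return (np.nan, np.nan)
    a = (1.0 - level) / 2.0

    def bound(q):
        # find lambda with ncx2.cdf(t, df, lambda) = q
        if ncx2.cdf(t, df, 0.0) < q:
            return 0.0
        lo, hi = 0.0, max(10.0, 2.0 * t)
        while ncx2.cdf(t, df, hi) > q:
            hi *= 2.0
            if hi > 1e8:
                break
        for _ in range(200):
            mid = (lo + hi) / 2.0
            if ncx2.cdf(t, df, mid) > q:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2.0

    lam_lo = bound(1.0 - a)
    lam_hi = bound(a)
    return (
        float(np.sqrt(n_groups * lam_lo / (df * n))),
        float(np.sqrt(n_groups * lam_hi / (df * n))),
    )


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def implied_correlations(loadings, psi=None, item_factor=None) -> np.ndarray:
    """Model-implied correlation matrix Lambda Psi Lambda' with unit diagonal."""
    lam = np.asarray(loadings, float)
    J = lam.size
    if item_factor is None:
        item_factor = np.zeros(J, int)
    if psi is None:
        psi = np.eye(int(np.max(item_factor)) + 1)
    psi = np.atleast_2d(np.asarray(psi, float))
    out = np.empty((J, J))
    for j in range(J):
        for k in range(J):
            out[j, k] = lam[j] * lam[k] * psi[item_factor[j], item_factor[k]]
    np.fill_diagonal(out, 1.0)
    return out


def residual_correlations(observed: np.ndarray, implied: np.ndarray) -> np.ndarray:
    """Elementwise observed-minus-implied correlations, zero diagonal."""
    out = np.asarray(observed, float) - np.asarray(implied, float)
    np.fill_diagonal(out, 0.0)
    return out


def _categorical_cov(cuts1, cuts2, rho) -> float:
    """Model-implied covariance of two discretised items (codes 0..K-1)."""
    from .polychoric import _cell_probs

    pi = _cell_probs(np.atleast_1d(cuts1), np.atleast_1d(cuts2), rho)
    a = np.arange(pi.shape[0], dtype=float)
    b = np.arange(pi.shape[1], dtype=float)
    return float(a @ pi @ b - (a @ pi.sum(1)) * (pi.sum(0) @ b))


def omega_reliability(loadings, thresholds=None, scale: str = "latent") -> ReliabilityResult:
    """McDonald's omega for a unidimensional block.

    latent scale: omega = (sum lambda)^2 / ((sum lambda)^2 + sum(1 - lambda^2)).
    sum-score scale: the share of the model-implied covariance matrix of
    the observed categorical items attributable to the factor, with item
    (co)variances from bivariate-normal rectangle probabilities
    (Green-Yang-style categorical omega).  ``thresholds`` is a list of
    per-item cut-point arrays (length 1 for binary items).
    """
    if scale not in ("latent", "sumscore", "both"):
        raise ValueError("scale must be latent, sumscore or both")
    lam = np.asarray(loadings, float)
    s = lam.sum()
    omega_l = s * s / (s * s + np.sum(1.0 - lam ** 2)) if s != 0 else 0.0

    omega_s = np.nan
    if thresholds is not None:
        cuts = [np.atleast_1d(np.asarray(t, float)) for t in thresholds]
        J = lam.size
        num = 0.0
        den = 0.0
        for j in range(J):
            for k in range(J):
                r_factor = lam[j] * lam[k] if j != k else min(lam[j] ** 2, 1.0)
                num += _categorical_cov(cuts[j], cuts[k], r_factor)
                if j == k:
                    # total variance from the item's own margins
                    from scipy.special import ndtr

                    p_le = np.concatenate([ndtr(cuts[j]), [1.0]])
                    p_cat = np.diff(np.concatenate([[0.0], p_le]))
                    vals = np.arange(p_cat.size, dtype=float)
                    den += float(p_cat @ vals ** 2 - (p_cat @ vals) ** 2)
                else:
                    den += _categorical_cov(cuts[j], cuts[k], lam[j] * lam[k])
        omega_s = num / den if den > 0 else np.nan
    return ReliabilityResult(omega_latent=float(omega_l), omega_sumscore=float(omega_s))
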