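"""Thresholds, tetrachoric/polychoric correlations and their asymptotic covariance.

These are the first-stage summary statistics for limited-information
categorical SEM.  Each observed categorical item x_j is viewed as a
discretised standard-normal latent response y_j: for a binary item coded
0/1, ``P(x_j = 1) = 1 - Phi(tau_j)``; for a K-category ordinal item coded
1..K the cut-points tau_j1 < ... < tau_j,K-1 satisfy
``P(x_j <= c) = Phi(tau_jc)``.  The polychoric correlation of a pair is the
maximum-likelihood correlation of the underlying bivariate normal given the
(first-stage) thresholds.

The asymptotic covariance of the stacked statistic vector
(all thresholds, then all correlations) is obtained by the delta method
from the per-observation estimating equations (an M-estimator sandwich);
its diagonal provides the weights for diagonally weighted least squares,
and the full matrix the robust standard errors and scaled test statistics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri
from scipy.stats import norm

__all__ = [
    "bvn_cdf",
    "bvn_pdf",
    "estimate_thresholds",
    "estimate_tetrachoric",
    "estimate_summary",
    "TetrachoricSummary",
    "DegenerateItemError",
]

_CLAMP = 0.999
_ZLIM = 8.2  # |z| beyond this, Phi is 0/1 to ~1e-16


class DegenerateItemError(ValueError):
    """Raised when an item shows no variation (threshold would be infinite)."""


# ---------------------------------------------------------------------------
# Bivariate normal CDF (vectorised Gauss-Legendre scheme after Genz, 2004)
# ---------------------------------------------------------------------------

_GL_X, _GL_W = np.polynomial.legendre.leggauss(24)


def _phid(z):
    return ndtr(z)


def _bvnu(dh, dk, r):
    """Upper orthant probability P(X > dh, Y > dk) for standard BVN.

    Vectorised over broadcastable arrays.  Uses the single-integral
    reduction for |r| <= 0.925 and the transformed near-singular expansion
    otherwise, both integrated by 24-point Gauss-Legendre.
    """
    dh, dk, r = np.broadcast_arrays(
        np.clip(np.asarray(dh, float), -_ZLIM, _ZLIM),
        np.clip(np.asarray(dk, float), -_ZLIM, _ZLIM),
        np.asarray(r, float),
    )
    out = np.empty(dh.shape, float)

    near = np.abs(r) <= 0.925
    if np.any(near):
        h, k, rr = dh[near], dk[near], r[near]
        hk = h * k
        hs = (h * h + k * k) / 2.0
        asr = np.arcsin(rr)
        # nodes mapped to [0, asr]
        sn = np.sin(asr[..., None] * (1.0 + _GL_X) / 2.0)
        f = np.exp((sn * hk[..., None] - hs[..., None]) / (1.0 - sn * sn))
        val = (asr / (4.0 * np.pi)) * (f @ _GL_W) + _phid(-h) * _phid(-k)
        out[near] = val

    far = ~near
    if np.any(far):
        h, k, rr = dh[far], dk[far], r[far]
        sgn = np.where(rr < 0.0, -1.0, 1.0)
        k = k * sgn
        hk = h * k
        bvn = np.zeros(h.shape)
        small = np.abs(rr) < 1.0
        # asymptotic pieces for |r| < 1
        a_s = (1.0 - rr) * (1.0 + rr)
        a = np.sqrt(np.maximum(a_s, 1e-300))
        bs = (h - k) ** 2
        c = (4.0 - hk) / 8.0
        d = (12.0 - hk) / 16.0
        asr0 = -(bs / np.maximum(a_s, 1e-300) + hk) / 2.0
        t1 = np.where(
            asr0 > -100.0,
            a * np.exp(asr0) * (1.0 - c * (bs - a_s) * (1.0 - d * bs / 5.0) / 3.0
                                + c * d * a_s * a_s / 5.0),
            0.0,
        )
        b = np.sqrt(bs)
        sp = np.sqrt(2.0 * np.pi) * _phid(-b / np.maximum(a, 1e-300))
        t2 = np.where(
            -hk < 100.0,
            np.exp(-hk / 2.0) * sp * b * (1.0 - c * bs * (1.0 - d * bs / 5.0) / 3.0),
            0.0,
        )
        bvn = np.where(small, t1 - t2, 0.0)
        # Gauss-Legendre correction on x in (0, a/2]
        ah = a / 2.0
        xs = (ah[..., None] * (1.0 + _GL_X)) ** 2
        rs = np.sqrt(np.maximum(1.0 - xs, 0.0))
        asr1 = -(bs[..., None] / np.maximum(xs, 1e-300) + hk[..., None]) / 2.0
        spn = 1.0 + c[..., None] * xs * (1.0 + d[..., None] * xs)
        ep = np.exp(-hk[..., None] * (1.0 - rs) / (2.0 * (1.0 + rs))) / np.maximum(rs, 1e-300)
        fint = np.where(asr1 > -100.0, np.exp(asr1) * (ep - spn), 0.0)
        bvn = bvn + np.where(small, ah * (fint @ _GL_W), 0.0)
        bvn = -bvn / (2.0 * np.pi)
        pos = sgn > 0
        res = bvn + _phid(-np.maximum(h, k))
        # for r < 0: bvn = -bvn + max(0, Phi(-h) - Phi(-k)); k already sign-flipped
        res_neg = -bvn + np.maximum(0.0, _phid(-h) - _phid(-k))
        out[far] = np.where(pos, res, res_neg)

    return np.clip(out, 0.0, 1.0)


def bvn_cdf(h, k, r):
    """P(X <= h, Y <= k) for a standard bivariate normal with correlation r."""
    return _bvnu(-np.asarray(h, float), -np.asarray(k, float), r)


def bvn_pdf(h, k, r):
    """Standard bivariate normal density at (h, k) with correlation r."""
    h = np.clip(np.asarray(h, float), -_ZLIM, _ZLIM)
    k = np.clip(np.asarray(k, float), -_ZLIM, _ZLIM)
    r = np.asarray(r, float)
    om = 1.0 - r * r
    return np.exp(-(h * h - 2.0 * r * h * k + k * k) / (2.0 * om)) / (
        2.0 * np.pi * np.sqrt(om)
    )


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------

def estimate_thresholds(codes, n_categories, *, min_code=None):
    """Estimate normal cut-points for one item from observed category codes.

    Parameters
    ----------
    codes : array of int
        Observed codes (missing values already removed).  Binary items are
        coded 0/1 (so the single cut-point is ``Phi^-1(1 - p_hat)`` with
        p_hat the endorsement rate); K-category ordinal items are coded
        ``min_code .. min_code+K-1`` (``min_code`` defaults to 1 for
        ordinal, 0 for binary).
    n_categories : int

    Returns
    -------
    ndarray of shape (n_categories - 1,), strictly increasing.
    """
    codes = np.asarray(codes)
    if codes.size == 0:
        raise DegenerateItemError("no observed responses")
    if min_code is None:
        min_code = 0 if n_categories == 2 else 1
    counts = np.bincount(codes - min_code, minlength=n_categories)
    if np.count_nonzero(counts) < 2:
        raise DegenerateItemError(
            "item has a single observed category; threshold is infinite"
        )
    cum = np.cumsum(counts)[:-1] / codes.size
    if np.any(cum <= 0.0) or np.any(cum >= 1.0):
        # interior categories may be empty; clamp the cumulative proportions
        eps = 0.5 / codes.size
        cum = np.clip(cum, eps, 1.0 - eps)
    return ndtri(cum)


# ---------------------------------------------------------------------------
# Pairwise correlations
# ---------------------------------------------------------------------------

def estimate_tetrachoric(table):
    """Tetrachoric correlation from a 2x2 count table.

    ``table[a, b]`` counts observations with item1 = a, item2 = b
    (a, b in {0, 1}).  Thresholds are taken from the table margins
    (two-stage estimation); the ML correlation given the thresholds
    then solves ``P(y1 > tau1, y2 > tau2; rho) = p11``.

    A zero cell triggers the continuity correction (+0.5 to every cell).
    A zero margin is an error.
    """
    table = np.asarray(table, float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table.sum(axis=0) == 0.0) or np.any(table.sum(axis=1) == 0.0):
        raise DegenerateItemError("zero margin in 2x2 table")
    if np.any(table == 0.0):
        table = table + 0.5
    n = table.sum()
    p1 = table[1].sum() / n
    p2 = table[:, 1].sum() / n
    tau1 = ndtri(1.0 - p1)
    tau2 = ndtri(1.0 - p2)
    p11 = table[1, 1] / n
    rho = _solve_binary_pairs(
        np.array([tau1]), np.array([tau2]), np.array([p11])
    )[0]
    if abs(rho) >= _CLAMP - 1e-9:
        warnings.warn("tetrachoric correlation at clamp boundary", stacklevel=2)
    return float(rho)


def _solve_binary_pairs(tau1, tau2, p11):
    """Vectorised safeguarded Newton for binary-binary pairs.

    Solves bvnu(tau1, tau2; rho) = p11 for each element.  The left side is
    strictly increasing in rho, so bisection brackets guarantee progress.
    """
    lo = np.full(p11.shape, -_CLAMP)
    hi = np.full(p11.shape, _CLAMP)
    rho = np.zeros(p11.shape)
    for _ in range(60):
        f = _bvnu(tau1, tau2, rho) - p11
        lo = np.where(f < 0.0, rho, lo)
        hi = np.where(f > 0.0, rho, hi)
        grad = bvn_pdf(tau1, tau2, rho)
        step = np.where(grad > 1e-300, f / np.maximum(grad, 1e-300), 0.0)
        cand = rho - step
        bad = (cand <= lo) | (cand >= hi) | ~np.isfinite(cand)
        cand = np.where(bad, (lo + hi) / 2.0, cand)
        if np.max(np.abs(cand - rho)) < 1e-12:
            rho = cand
            break
        rho = cand
    return np.clip(rho, -_CLAMP, _CLAMP)


def _cell_probs(cuts1, cuts2, rho):
    """Rectangle probabilities for an ordinal pair.

    cuts are the interior cut-points; the returned array has shape
    (K1, K2) and sums to 1.
    """
    t1 = np.concatenate(([-np.inf], cuts1, [np.inf]))
    t2 = np.concatenate(([-np.inf], cuts2, [np.inf]))
    upper = bvn_cdf(t1[1:, None], t2[None, 1:], rho)
    low1 = bvn_cdf(t1[:-1, None], t2[None, 1:], rho)
    low2 = bvn_cdf(t1[1:, None], t2[None, :-1], rho)
    both = bvn_cdf(t1[:-1, None], t2[None, :-1], rho)
    pi = upper - low1 - low2 + both
    return np.clip(pi, 1e-12, 1.0)


def _dpi_drho(cuts1, cuts2, rho):
    """d pi_ab / d rho via the bivariate density at the four cell corners."""
    t1 = np.concatenate(([-np.inf], cuts1, [np.inf]))
    t2 = np.concatenate(([-np.inf], cuts2, [np.inf]))

    def f(a, b):
        fin = np.isfinite(a) & np.isfinite(b)
        v = np.zeros(np.broadcast_shapes(a.shape, b.shape))
        if np.any(fin):
            aa, bb = np.broadcast_arrays(a, b)
            v[fin] = bvn_pdf(aa[fin], bb[fin], rho)
        return v

    return (
        f(t1[1:, None], t2[None, 1:])
        - f(t1[:-1, None], t2[None, 1:])
        - f(t1[1:, None], t2[None, :-1])
        + f(t1[:-1, None], t2[None, :-1])
    )


def _dpi_dcut(cuts1, cuts2, rho, which, c):
    """d pi_ab / d t, where t is interior cut-point index c (0-based) of
    item ``which`` (0 or 1)."""
    if which == 1:
        return _dpi_dcut(cuts2, cuts1, rho, 0, c).T
    t = cuts1[c]
    t2 = np.concatenate(([-np.inf], cuts2, [np.inf]))
    s = np.sqrt(1.0 - rho * rho)
    cond = ndtr((np.clip(t2, -_ZLIM, _ZLIM) - rho * t) / s)
    cond[0], cond[-1] = 0.0, 1.0
    w = norm.pdf(t) * (cond[1:] - cond[:-1])  # length K2
    K1 = len(cuts1) + 1
    out = np.zeros((K1, len(w)))
    out[c, :] = w       # cell row c has t as its upper limit
    out[c + 1, :] = -w  # cell row c+1 has t as its lower limit
    return out


def _polychoric_ml(counts, cuts1, cuts2):
    """Two-stage ML polychoric for a general ordinal pair (Brent search)."""

    def nll(r):
        pi = _cell_probs(cuts1, cuts2, r)
        return -np.sum(counts * np.log(pi))

    res = minimize_scalar(nll, bounds=(-_CLAMP, _CLAMP), method="bounded",
                          options={"xatol": 1e-9})
    return float(np.clip(res.x, -_CLAMP, _CLAMP))


# ---------------------------------------------------------------------------
# Summary container + full estimation
# ---------------------------------------------------------------------------

@dataclass
class TetrachoricSummary:
    """First-stage summary: thresholds, correlations and asymptotic covariance.

    Statistic vector order: all thresholds item-by-item (each item
    contributing K_j - 1 cut-points), followed by correlations rho_jk for
    pairs (j, k) with j < k in row-major order.  ``gamma`` is the
    per-observation covariance of the influence functions, so the
    asymptotic covariance of the statistics is ``gamma / n``.
    """

    item_names: list[str]
    n_categories: np.ndarray
    thresholds: list[np.ndarray]
    rho: np.ndarray
    gamma: np.ndarray
    n: int
    clamped_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_items(self) -> int:
        return len(self.item_names)

    @property
    def n_thresholds(self) -> int:
        return int(np.sum(self.n_categories - 1))

    @property
    def pairs(self) -> list[tuple[int, int]]:
        J = self.n_items
        return [(j, k) for j in range(J) for k in range(j + 1, J)]

    @property
    def threshold_vector(self) -> np.ndarray:
        return np.concatenate(self.thresholds)

    @property
    def corr_vector(self) -> np.ndarray:
        return np.array([self.rho[j, k] for j, k in self.pairs])

    @property
    def stat_vector(self) -> np.ndarray:
        return np.concatenate([self.threshold_vector, self.corr_vector])

    @property
    def asy_cov(self) -> np.ndarray:
        """Asymptotic covariance of the statistic vector (includes 1/n)."""
        return self.gamma / self.n

    @property
    def asy_var(self) -> np.ndarray:
        return np.diag(self.gamma) / self.n

    def threshold_offset(self, j: int) -> int:
        return int(np.sum(self.n_categories[:j] - 1))

    def to_json(self) -> str:
        return json.dumps(
            {
                "item_names": self.item_names,
                "n_categories": self.n_categories.tolist(),
                "thresholds": [t.tolist() for t in self.thresholds],
                "rho": self.rho.tolist(),
                "gamma": self.gamma.tolist(),
                "n": self.n,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "TetrachoricSummary":
        d = json.loads(s)
        return cls(
            item_names=d["item_names"],
            n_categories=np.asarray(d["n_categories"]),
            thresholds=[np.asarray(t, float) for t in d["thresholds"]],
            rho=np.asarray(d["rho"], float),
            gamma=np.asarray(d["gamma"], float),
            n=int(d["n"]),
        )


def estimate_summary(codes, n_categories, item_names=None, *, compute_gamma=True):
    """Estimate the full first-stage summary from complete categorical data.

    Parameters
    ----------
    codes : (N, J) int array
        Complete (no missing) category codes; binary items 0/1, ordinal
        items 1..K.
    n_categories : sequence of int per item.
    compute_gamma : bool
        Skip the influence-function covariance when only point estimates
        are needed (e.g. inside bootstrap loops).
    """
    codes = np.asarray(codes)
    N, J = codes.shape
    n_categories = np.asarray(n_categories, int)
    if item_names is None:
        item_names = [f"item{j+1}" for j in range(J)]

    cuts = [estimate_thresholds(codes[:, j], n_categories[j]) for j in range(J)]
    min_code = np.where(n_categories == 2, 0, 1)
    zero_based = codes - min_code[None, :]

    rho = np.eye(J)
    clamped: list[tuple[int, int]] = []

    # fast path: all binary-binary pairs at once
    bin_idx = np.flatnonzero(n_categories == 2)
    if bin_idx.size >= 2:
        Xb = (zero_based[:, bin_idx] == 1).astype(float)
        P11 = (Xb.T @ Xb) / N
        tau = np.array([cuts[j][0] for j in bin_idx])
        iu = np.triu_indices(bin_idx.size, k=1)
        p11 = P11[iu]
        p1 = Xb.mean(axis=0)
        # continuity correction for tables with an empty cell
        p11c = p11.copy()
        t1c = tau[iu[0]].copy()
        t2c = tau[iu[1]].copy()
        for m, (a, b) in enumerate(zip(*iu)):
            tab = np.array(
                [
                    [np.sum((Xb[:, a] == 0) & (Xb[:, b] == 0)),
                     np.sum((Xb[:, a] == 0) & (Xb[:, b] == 1))],
                    [np.sum((Xb[:, a] == 1) & (Xb[:, b] == 0)),
                     np.sum((Xb[:, a] == 1) & (Xb[:, b] == 1))],
                ],
                float,
            )
            if np.any(tab == 0.0):
                tab += 0.5
                nn = tab.sum()
                p11c[m] = tab[1, 1] / nn
                t1c[m] = ndtri(1.0 - tab[1].sum() / nn)
                t2c[m] = ndtri(1.0 - tab[:, 1].sum() / nn)
        r = _solve_binary_pairs(t1c, t2c, p11c)
        for m, (a, b) in enumerate(zip(*iu)):
            ja, jb = bin_idx[a], bin_idx[b]
            rho[ja, jb] = rho[jb, ja] = r[m]
            if abs(r[m]) >= _CLAMP - 1e-9:
                clamped.append((ja, jb))

    # general pairs involving an ordinal item
    for j in range(J):
        for k in range(j + 1, J):
            if n_categories[j] == 2 and n_categories[k] == 2:
                continue
            counts = np.zeros((n_categories[j], n_categories[k]))
            np.add.at(counts, (zero_based[:, j], zero_based[:, k]), 1.0)
            if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
                raise DegenerateItemError(
                    f"pair ({item_names[j]}, {item_names[k]}) has a zero margin"
                )
            r = _polychoric_ml(counts, cuts[j], cuts[k])
            rho[j, k] = rho[k, j] = r
            if abs(r) >= _CLAMP - 1e-9:
                clamped.append((j, k))

    if clamped:
        warnings.warn(
            f"{len(clamped)} correlation(s) at the clamp boundary", stacklevel=2
        )

    summ = TetrachoricSummary(
        item_names=list(item_names),
        n_categories=n_categories,
        thresholds=cuts,
        rho=rho,
        gamma=np.empty((0, 0)),
        n=N,
    )
    summ.clamped_pairs = clamped
    if compute_gamma:
        summ.gamma = _influence_gamma(zero_based, summ)
    return summ


def _influence_gamma(zero_based, summ: TetrachoricSummary) -> np.ndarray:
    """Per-observation covariance of the influence functions of all statistics."""
    N, J = zero_based.shape
    nthr = summ.n_thresholds
    pairs = summ.pairs
    nstat = nthr + len(pairs)
    psi = np.empty((N, nstat))

    # thresholds: psi = (1{x <= c} - Phi(t)) / phi(t)
    col = 0
    thr_cols: list[list[int]] = []
    for j in range(J):
        cols_j = []
        for c, t in enumerate(summ.thresholds[j]):
            ind = (zero_based[:, j] <= c).astype(float)
            psi[:, col] = (ind - ndtr(t)) / norm.pdf(t)
            cols_j.append(col)
            col += 1
        thr_cols.append(cols_j)

    # correlations
    for m, (j, k) in enumerate(pairs):
        cj, ck = summ.thresholds[j], summ.thresholds[k]
        r = summ.rho[j, k]
        pi = _cell_probs(cj, ck, r)
        dr = _dpi_drho(cj, ck, r)
        score_tab = dr / pi
        g = score_tab[zero_based[:, j], zero_based[:, k]]
        i_rr = np.sum(dr * dr / pi)
        corr = np.zeros(N)
        for which, (jj, cc) in ((0, (j, cj)), (1, (k, ck))):
            for c in range(len(cc)):
                dt = _dpi_dcut(cj, ck, r, which, c)
                i_rt = np.sum(dr * dt / pi)
                corr += i_rt * psi[:, thr_cols[jj][c]]
        psi[:, nthr + m] = (g - corr) / i_rr

    psi -= psi.mean(axis=0, keepdims=True)
    return (psi.T @ psi) / N


def bootstrap_asy_var(codes, n_categories, n_boot=200, seed=0):
    """Nonparametric-bootstrap variance of thresholds and correlations.

    Validation oracle for the delta-method asymptotic variances; returns
    the bootstrap variance of the stacked statistic vector.
    """
    rng = np.random.default_rng(seed)
    codes = np.asarray(codes)
    N = codes.shape[0]
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, N, N)
        s = estimate_summary(codes[idx], n_categories, compute_gamma=False)
        stats.append(s.stat_vector)
    return np.var(np.asarray(stats), axis=0, ddof=1)
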