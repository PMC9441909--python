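"""Multigroup categorical CFA and the measurement-invariance ladder.

Groups (gender, age classes, or their crossing) are compared with a
one-factor model for the nine binary items under increasingly strict
equality constraints:

* configural - same pattern, all parameters group-specific, every group's
  latent mean fixed at 0 and variance at 1;
* metric     - loadings equal across groups, group factor variances free
  (reference group anchored at 1);
* scalar     - thresholds also equal (possibly partially: individual
  item thresholds may vary over a declared partition of the groups),
  latent means free (reference group at 0);
* latent_means - additionally all latent means equal.

Throughout, latent response variables keep unit variance and zero
intercepts in every group (delta parametrization), so the group-g
threshold statistic implied for item j is ``tau_j - lambda_j * alpha_g``
and the implied polychoric correlation is ``lambda_j lambda_k psi_g``.

Each step is judged against the previous one with the categorical-data
criteria: metric invariance holds if dRMSEA <= 0.05 and dCFI >= -0.004;
scalar and latent-means invariance if dRMSEA <= 0.01 and dCFI >= -0.004.
When full invariance fails, threshold constraints are freed one at a time
in order of their (robust score) modification indices until the criteria
are met.  Group latent means can be reported against a reference group or
in the standardized parametrization (grand mean 0, average variance 1)
whose mean differences are Cohen's d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cfa import FitResult, baseline_t, fit_result_from_dwls, _assemble_fit
from .data import ItemResponseMatrix
from .dwls import DwlsFit, dwls_fit, robust_score_test, scaled_difference
from .polychoric import TetrachoricSummary, estimate_summary

__all__ = [
    "LEVELS",
    "InvarianceCriteria",
    "InvarianceComparison",
    "MultigroupFit",
    "GroupMeansResult",
    "group_summaries",
    "fit_multigroup",
    "compare_levels",
    "decide",
    "modification_indices",
    "partial_invariance_search",
    "estimate_group_means",
]

LEVELS = ("configural", "metric", "scalar", "latent_means")


@dataclass(frozen=True)
class InvarianceCriteria:
    metric_rmsea: float = 0.05
    scalar_rmsea: float = 0.01
    cfi: float = -0.004


def decide(level: str, d_cfi: float, d_rmsea: float,
           criteria: InvarianceCriteria = InvarianceCriteria()) -> str:
    """Accept/Reject verdict, a pure function of the declared criteria."""
    if level == "metric":
        ok = (d_rmsea <= criteria.metric_rmsea) and (d_cfi >= criteria.cfi)
    elif level in ("scalar", "latent_means"):
        ok = (d_rmsea <= criteria.scalar_rmsea) and (d_cfi >= criteria.cfi)
    else:
        raise ValueError(f"no decision rule for level {level!r}")
    return "accept" if ok else "reject"


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

def group_summaries(matrix: ItemResponseMatrix, by=("gender",)):
    """Per-group tetrachoric summaries from listwise-complete rows.

    Returns (labels, summaries, ns), groups ordered by sorted label.
    """
    keys = []
    for b in by:
        arr = getattr(matrix, b if b != "age_class" else "age")
        if arr is None:
            raise ValueError(f"matrix lacks {b} labels")
        keys.append(arr)
    combo = list(zip(*keys))
    labels = sorted(set(combo))
    summaries, ns = [], []
    for lab in labels:
        rows = np.array([c == lab for c in combo])
        sub = matrix.select_rows(np.flatnonzero(rows))
        vals = sub.complete_values()
        summaries.append(estimate_summary(vals, sub.n_categories, sub.item_names))
        ns.append(vals.shape[0])
    nice = [lab[0] if len(lab) == 1 else "_".join(str(x) for x in lab)
            for lab in labels]
    return nice, summaries, ns


# ---------------------------------------------------------------------------
# Multigroup model structure
# ---------------------------------------------------------------------------

def _default_partition(G):
    return [tuple(range(G))]


def _normalize_freed(freed, J, G):
    """freed: dict item_index -> partition (list of group tuples).

    The shorthand ``item -> "all"`` splits every group into its own block.
    """
    out = {}
    for j, part in (freed or {}).items():
        if part == "all":
            part = [(g,) for g in range(G)]
        blocks = [tuple(sorted(b)) for b in part]
        seen = [g for b in blocks for g in b]
        if sorted(seen) != list(range(G)):
            raise ValueError(f"partition for item {j} must cover all groups")
        out[int(j)] = blocks
    return out


class MultigroupOneFactorModel:
    """Stacked implied statistics [tau*(J), rho*(J(J-1)/2)] x G."""

    def __init__(self, J, G, level, freed=None, ref=0):
        if level not in LEVELS:
            raise ValueError(f"unknown level {level!r}")
        self.J, self.G, self.level, self.ref = J, G, level, ref
        freed = _normalize_freed(freed, J, G)
        if freed and level in ("configural", "metric"):
            raise ValueError("threshold partitions only apply at scalar level and above")

        # parameter-block maps
        lam_blocks = np.zeros((J, G), int)
        tau_blocks = np.zeros((J, G), int)
        if level == "configural":
            lam_blocks = np.arange(J * G).reshape(G, J).T
            tau_blocks = np.arange(J * G).reshape(G, J).T
            n_lam, n_tau = J * G, J * G
            alpha_free = []
            psi_free = []
        elif level == "metric":
            lam_blocks = np.tile(np.arange(J)[:, None], (1, G))
            tau_blocks = np.arange(J * G).reshape(G, J).T
            n_lam, n_tau = J, J * G
            alpha_free = []
            psi_free = [g for g in range(G) if g != ref]
        else:  # scalar / latent_means
            lam_blocks = np.tile(np.arange(J)[:, None], (1, G))
            n_lam = J
            tau_blocks = np.zeros((J, G), int)
            blk = 0
            for j in range(J):
                part = freed.get(j, _default_partition(G))
                for b in part:
                    for g in b:
                        tau_blocks[j, g] = blk
                    blk += 1
            n_tau = blk
            alpha_free = [] if level == "latent_means" else [g for g in range(G)
                                                             if g != ref]
            psi_free = [g for g in range(G) if g != ref]

        self.lam_blocks, self.tau_blocks = lam_blocks, tau_blocks
        self.n_lam, self.n_tau = n_lam, n_tau
        self.alpha_free, self.psi_free = alpha_free, psi_free
        self.freed = freed
        self.pairs = [(j, k) for j in range(J) for k in range(j + 1, J)]
        self.per_group = J + len(self.pairs)

        names = [f"lam_b{i}" for i in range(n_lam)]
        names += [f"tau_b{i}" for i in range(n_tau)]
        names += [f"alpha_g{g}" for g in alpha_free]
        names += [f"psi_g{g}" for g in psi_free]
        self.param_names = names
        self._o_tau = n_lam
        self._o_alpha = n_lam + n_tau
        self._o_psi = self._o_alpha + len(alpha_free)

    # -- parameter access ---------------------------------------------------
    def unpack(self, theta):
        lam = theta[: self.n_lam][self.lam_blocks]            # (J, G)
        tau = theta[self._o_tau: self._o_tau + self.n_tau][self.tau_blocks]
        alpha = np.zeros(self.G)
        for i, g in enumerate(self.alpha_free):
            alpha[g] = theta[self._o_alpha + i]
        psi = np.ones(self.G)
        for i, g in enumerate(self.psi_free):
            psi[g] = theta[self._o_psi + i]
        return lam, tau, alpha, psi

    def implied(self, theta):
        lam, tau, alpha, psi = self.unpack(theta)
        out = np.empty(self.G * self.per_group)
        for g in range(self.G):
            o = g * self.per_group
            out[o: o + self.J] = tau[:, g] - lam[:, g] * alpha[g]
            lg = lam[:, g]
            rho = np.outer(lg, lg) * psi[g]
            out[o + self.J: o + self.per_group] = rho[np.triu_indices(self.J, 1)]
        return out

    def jacobian(self, theta):
        lam, tau, alpha, psi = self.unpack(theta)
        n_par = len(self.param_names)
        out = np.zeros((self.G * self.per_group, n_par))
        iu = np.triu_indices(self.J, 1)
        for g in range(self.G):
            o = g * self.per_group
            ag, pg = alpha[g], psi[g]
            for j in range(self.J):
                out[o + j, self.lam_blocks[j, g]] += -ag
                out[o + j, self._o_tau + self.tau_blocks[j, g]] += 1.0
            if g in self.alpha_free:
                ia = self._o_alpha + self.alpha_free.index(g)
                out[o: o + self.J, ia] = -lam[:, g]
            for r, (j, k) in enumerate(self.pairs):
                row = o + self.J + r
                out[row, self.lam_blocks[j, g]] += lam[k, g] * pg
                out[row, self.lam_blocks[k, g]] += lam[j, g] * pg
                if g in self.psi_free:
                    out[row, self._o_psi + self.psi_free.index(g)] = lam[j, g] * lam[k, g]
        return out

    def start(self, stats):
        theta = np.zeros(len(self.param_names))
        theta[: self.n_lam] = 0.6
        # thresholds: average the relevant group sample thresholds
        acc = np.zeros(self.n_tau)
        cnt = np.zeros(self.n_tau)
        for g in range(self.G):
            o = g * self.per_group
            for j in range(self.J):
                b = self.tau_blocks[j, g]
                acc[b] += stats[o + j]
                cnt[b] += 1.0
        theta[self._o_tau: self._o_tau + self.n_tau] = acc / np.maximum(cnt, 1.0)
        theta[self._o_psi: self._o_psi + len(self.psi_free)] = 1.0
        return theta

    def bounds(self):
        b = [(-0.995, 0.995)] * self.n_lam
        b += [(-5.0, 5.0)] * self.n_tau
        b += [(-3.0, 3.0)] * len(self.alpha_free)
        b += [(0.05, 5.0)] * len(self.psi_free)
        return b

    def corr_rows(self):
        rows = []
        for g in range(self.G):
            o = g * self.per_group
            rows.extend(range(o + self.J, o + self.per_group))
        return np.asarray(rows, int)


# ---------------------------------------------------------------------------
# Fitting and comparison
# ---------------------------------------------------------------------------

@dataclass
class MultigroupFit:
    level: str
    labels: list[str]
    loadings: np.ndarray            # (J, G)
    thresholds: np.ndarray          # (J, G)
    alpha: np.ndarray               # (G,)
    psi: np.ndarray                 # (G,)
    dwls: DwlsFit
    fit: FitResult
    model: MultigroupOneFactorModel
    freed: dict

    def se_for(self, kind: str) -> np.ndarray:
        m, se = self.model, self.dwls.se
        if kind == "alpha":
            out = np.zeros(m.G)
            for i, g in enumerate(m.alpha_free):
                out[g] = se[m._o_alpha + i]
            return out
        if kind == "psi":
            out = np.zeros(m.G)
            for i, g in enumerate(m.psi_free):
                out[g] = se[m._o_psi + i]
            return out
        raise ValueError(kind)


def fit_multigroup(summaries, ns, level, *, freed=None, ref=0,
                   labels=None) -> MultigroupFit:
    """Joint DWLS fit of the multigroup one-factor model at a given level."""
    G = len(summaries)
    if G < 2:
        raise ValueError("need at least two groups")
    if any(n < 1 for n in ns):
        raise ValueError("empty group")
    J = summaries[0].n_items
    for s in summaries:
        if s.n_items != J:
            raise ValueError("summaries have differing item counts")
    if labels is None:
        labels = [f"g{g}" for g in range(G)]

    model = MultigroupOneFactorModel(J, G, level, freed=freed, ref=ref)
    s_stacked = np.concatenate([np.concatenate([s.threshold_vector, s.corr_vector])
                                for s in summaries])
    nstat = model.per_group
    xi = np.zeros((G * nstat, G * nstat))
    for g, s in enumerate(summaries):
        o = g * nstat
        xi[o: o + nstat, o: o + nstat] = s.asy_cov
    n_total = int(np.sum(ns))

    if len(model.param_names) > s_stacked.size:
        raise ValueError("model not identified: more parameters than statistics")

    fit = dwls_fit(s_stacked, xi, model, n=n_total)
    if not fit.converged:
        warnings.warn(f"{level} multigroup fit did not converge", stacklevel=2)
    lam, tau, alpha, psi = model.unpack(fit.theta)
    corr_rows = model.corr_rows()
    fitres = fit_result_from_dwls(fit, corr_rows)
    fitres.n_groups = G
    # recompute RMSEA with the multiple-group convention
    fitres = _assemble_fit_multigroup(fit, fitres, corr_rows, G)
    return MultigroupFit(level=level, labels=list(labels), loadings=lam,
                         thresholds=tau, alpha=alpha, psi=psi, dwls=fit,
                         fit=fitres, model=model,
                         freed=_normalize_freed(freed, J, G))


def _assemble_fit_multigroup(fit, fitres, corr_rows, G):
    sb = fit.stats[corr_rows]
    xib = fit.asy_cov[np.ix_(corr_rows, corr_rows)]
    tb, dfb = baseline_t(sb, xib)
    fit2 = fit
    fit2.n_groups = G
    return _assemble_fit(fit2, tb, dfb, corr_rows)


@dataclass
class InvarianceComparison:
    level: str
    d_chi2: float
    d_df: int
    d_chi2_p: float
    d_chi2_plain: float
    d_cfi: float
    d_rmsea: float
    d_srmr: float
    verdict: str


def compare_levels(fit_general: MultigroupFit, fit_restricted: MultigroupFit,
                   level=None,
                   criteria: InvarianceCriteria = InvarianceCriteria()) -> InvarianceComparison:
    """Scaled difference test and delta fit indices, restricted minus general."""
    if fit_restricted.dwls.df <= fit_general.dwls.df:
        raise ValueError("restricted model must be nested in the general model")
    level = level or fit_restricted.level
    stat, d_df, p, _sf = scaled_difference(fit_restricted.dwls, fit_general.dwls)
    d_cfi = fit_restricted.fit.cfi - fit_general.fit.cfi
    d_rmsea = fit_restricted.fit.rmsea - fit_general.fit.rmsea
    d_srmr = fit_restricted.fit.srmr - fit_general.fit.srmr
    return InvarianceComparison(
        level=level, d_chi2=stat, d_df=d_df, d_chi2_p=p,
        d_chi2_plain=fit_restricted.dwls.t0 - fit_general.dwls.t0,
        d_cfi=d_cfi, d_rmsea=d_rmsea, d_srmr=d_srmr,
        verdict=decide(level, d_cfi, d_rmsea, criteria),
    )


# ---------------------------------------------------------------------------
# Modification indices and partial invariance
# ---------------------------------------------------------------------------

def modification_indices(fit: MultigroupFit) -> pd.DataFrame:
    """Robust score tests for freeing one group's threshold from its block.

    Candidates are (item, group) cells sharing their threshold block with
    at least one other group.  Sorted by decreasing statistic.
    """
    m = fit.model
    rows = []
    for j in range(m.J):
        for g in range(m.G):
            blk = m.tau_blocks[j, g]
            if np.sum(m.tau_blocks[j] == blk) < 2:
                continue  # already alone in its block
            direction = np.zeros(m.G * m.per_group)
            direction[g * m.per_group + j] = 1.0
            stat, p = robust_score_test(fit.dwls, direction)
            rows.append({"item": j, "group": g, "mi": stat, "p": p})
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("mi", ascending=False, ignore_index=True)
    return df


def _free_cell(freed, j, g, G):
    """Split group g out of item j's threshold partition."""
    part = freed.get(j, _default_partition(G))
    new = []
    for b in part:
        if g in b:
            rest = tuple(x for x in b if x != g)
            if rest:
                new.append(rest)
            new.append((g,))
        else:
            new.append(b)
    freed = dict(freed)
    freed[j] = new
    return freed


@dataclass
class PartialSearchResult:
    freed: dict
    fit: MultigroupFit
    comparisons: list[InvarianceComparison]
    succeeded: bool


def partial_invariance_search(summaries, ns, fit_general: MultigroupFit,
                              level="scalar", *, ref=0, labels=None,
                              criteria: InvarianceCriteria = InvarianceCriteria(),
                              max_freed=None) -> PartialSearchResult:
    """Free thresholds one at a time (largest MI first) until the level's
    criteria are met against ``fit_general``.

    Fails (``succeeded=False``) when more than J - 2 items would need
    freeing, which would leave too few anchors for identification.
    """
    J = summaries[0].n_items
    if max_freed is None:
        max_freed = J - 2
    freed: dict = {}
    comparisons = []
    while True:
        fit_r = fit_multigroup(summaries, ns, level, freed=freed, ref=ref,
                               labels=labels)
        comp = compare_levels(fit_general, fit_r, level, criteria)
        comparisons.append(comp)
        if comp.verdict == "accept":
            return PartialSearchResult(freed=freed, fit=fit_r,
                                       comparisons=comparisons, succeeded=True)
        if len(freed) >= max_freed:
            warnings.warn("partial invariance not reached within anchor budget",
                          stacklevel=2)
            return PartialSearchResult(freed=freed, fit=fit_r,
                                       comparisons=comparisons, succeeded=False)
        mi = modification_indices(fit_r)
        if mi.empty:
            return PartialSearchResult(freed=freed, fit=fit_r,
                                       comparisons=comparisons, succeeded=False)
        top = mi.iloc[0]
        freed = _free_cell(freed, int(top["item"]), int(top["group"]),
                           fit_r.model.G)


# ---------------------------------------------------------------------------
# Group means and effect sizes
# ---------------------------------------------------------------------------

@dataclass
class GroupMeansResult:
    table: pd.DataFrame              # per group: mean, sd, CIs
    contrasts: pd.DataFrame          # pairwise standardized differences
    parametrization: str
    ci_level: float


def estimate_group_means(fit: MultigroupFit, parametrization="reference",
                         ci_level=0.995, contrasts=None) -> GroupMeansResult:
    """Latent group means/SDs with CIs, and standardized pairwise contrasts.

    reference: the fitted anchoring (reference group mean 0, variance 1).
    cohens_d:  reparametrized so the grand mean is 0 and the average latent
    variance is 1; mean differences are then Cohen's d.  Standard errors
    come from the delta method on the fitted (alpha, psi) covariance, so
    standardized contrasts are identical under both parametrizations.
    """
    if fit.level in ("configural", "metric"):
        raise ValueError("group means require a (partial) scalar model")
    m = fit.model
    G = m.G
    free_idx = ([m._o_alpha + i for i in range(len(m.alpha_free))]
                + [m._o_psi + i for i in range(len(m.psi_free))])
    acov = fit.dwls.acov[np.ix_(free_idx, free_idx)] if free_idx else np.zeros((0, 0))

    def build(vec):
        alpha = np.zeros(G)
        psi = np.ones(G)
        for i, g in enumerate(m.alpha_free):
            alpha[g] = vec[i]
        na = len(m.alpha_free)
        for i, g in enumerate(m.psi_free):
            psi[g] = vec[na + i]
        return alpha, psi

    def transform(vec):
        alpha, psi = build(vec)
        if parametrization == "reference":
            return np.concatenate([alpha, np.sqrt(psi)])
        if parametrization == "cohens_d":
            c = np.sqrt(np.mean(psi))
            return np.concatenate([(alpha - alpha.mean()) / c, np.sqrt(psi) / c])
        raise ValueError(f"unknown parametrization {parametrization!r}")

    x0 = np.concatenate([fit.alpha[m.alpha_free], fit.psi[m.psi_free]])
    est = transform(x0)
    if x0.size:
        h = 1e-6
        Jt = np.empty((est.size, x0.size))
        for i in range(x0.size):
            xp, xm = x0.copy(), x0.copy()
            xp[i] += h
            xm[i] -= h
            Jt[:, i] = (transform(xp) - transform(xm)) / (2 * h)
        se = np.sqrt(np.maximum(np.diag(Jt @ acov @ Jt.T), 0.0))
    else:
        se = np.zeros(est.size)

    z = norm.ppf(0.5 + ci_level / 2.0)
    means, sds = est[:G], est[G:]
    se_m, se_s = se[:G], se[G:]
    table = pd.DataFrame({
        "mean": means, "mean_se": se_m,
        "mean_lo": means - z * se_m, "mean_hi": means + z * se_m,
        "sd": sds, "sd_se": se_s,
        "sd_lo": sds - z * se_s, "sd_hi": sds + z * se_s,
    }, index=fit.labels)

    if contrasts is None:
        contrasts = [(a, b) for a in range(G) for b in range(G) if a < b]
    rows = []
    for a, b in contrasts:
        def d_fn(vec, a=a, b=b):
            alpha, psi = build(vec)
            return np.array([(alpha[a] - alpha[b]) / np.sqrt(np.mean(psi))])

        d = float(d_fn(x0)[0])
        if x0.size:
            h = 1e-6
            gvec = np.empty(x0.size)
            for i in range(x0.size):
                xp, xm = x0.copy(), x0.copy()
                xp[i] += h
                xm[i] -= h
                gvec[i] = (d_fn(xp)[0] - d_fn(xm)[0]) / (2 * h)
            sd_d = float(np.sqrt(max(gvec @ acov @ gvec, 0.0)))
        else:
            sd_d = 0.0
        rows.append({"group_a": fit.labels[a], "group_b": fit.labels[b],
                     "d": d, "se": sd_d, "lo": d - z * sd_d, "hi": d + z * sd_d})
    return GroupMeansResult(table=table, contrasts=pd.DataFrame(rows),
                            parametrization=parametrization, ci_level=ci_level)
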