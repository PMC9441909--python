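"""Multiple imputation by fully conditional specification, and Rubin pooling.

Missing item responses are imputed m times by chained equations: binary
symptom items by Bayesian logistic regression draws, ordinal items by
predictive mean matching (PMM, so imputed values are always observed donor
values).  Predictors are gender, age class, and the per-scale total scores
computed over each respondent's observed items (fixed during the
iterations).  Downstream estimates computed on each completed dataset are
pooled by Rubin's rules: total variance = within + (1 + 1/m) * between,
with Barnard-Rubin degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, t as t_dist

from .data import ItemResponseMatrix

__all__ = ["ImputationSpec", "PoolingResult", "fcs_impute", "pool_rubin"]


@dataclass
class ImputationSpec:
    m: int = 10
    iterations: int = 10
    pmm_donors: int = 5
    scale_of: dict = field(default_factory=dict)   # item name -> scale name
    ridge: float = 1e-6

    def __post_init__(self):
        if self.m < 1 or self.iterations < 1 or self.pmm_donors < 1:
            raise ValueError("m, iterations and donor count must be >= 1")


def _scale_totals(matrix: ItemResponseMatrix, scale_of: dict) -> np.ndarray:
    """Per-scale mean of observed items (zero when a scale is fully missing)."""
    scales = sorted(set(scale_of.values())) if scale_of else []
    if not scales:
        # single implicit scale: all items
        scales = ["_all"]
        scale_of = {m.name: "_all" for m in matrix.items}
    out = np.zeros((matrix.n, len(scales)))
    for s_i, s in enumerate(scales):
        cols = [c for c, m in enumerate(matrix.items) if scale_of.get(m.name) == s]
        vals = matrix.values[:, cols].astype(float)
        obs = ~matrix.missing_mask[:, cols]
        cnt = obs.sum(axis=1)
        tot = np.where(obs, vals, 0.0).sum(axis=1)
        out[:, s_i] = np.where(cnt > 0, tot / np.maximum(cnt, 1), 0.0)
    return out


def _design(matrix: ItemResponseMatrix, totals: np.ndarray, target_col: int,
            scale_of: dict, scales: list[str]) -> np.ndarray:
    """Predictors for one target item: gender, age, all instrument totals.

    The target's own-scale total is recomputed over the *other* observed
    items of that scale, so the target never predicts itself.
    """
    cols = [np.ones(matrix.n)]
    if matrix.gender is not None:
        cols.append((matrix.gender == "girl").astype(float))
    if matrix.age is not None:
        cols.append((matrix.age - 13.0) / 2.0)
    own = scale_of.get(matrix.items[target_col].name)
    for s_i, s in enumerate(scales):
        if s == own:
            sib = [c for c, m in enumerate(matrix.items)
                   if scale_of.get(m.name) == s and c != target_col]
            if not sib:
                continue
            vals = matrix.values[:, sib].astype(float)
            obs = ~matrix.missing_mask[:, sib]
            cnt = obs.sum(axis=1)
            tot = np.where(obs, vals, 0.0).sum(axis=1)
            cols.append(np.where(cnt > 0, tot / np.maximum(cnt, 1), 0.0))
        else:
            cols.append(totals[:, s_i])
    return np.column_stack(cols)


def _logistic_irls(X, y, ridge=1e-6, max_iter=50):
    """Ridge-stabilised IRLS; returns (beta, cov)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        z = eta + (y - mu) / w
        A = X.T @ (w[:, None] * X) + ridge * np.eye(p)
        new = np.linalg.solve(A, X.T @ (w * z))
        if np.max(np.abs(new - beta)) < 1e-8:
            beta = new
            break
        beta = new
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    cov = np.linalg.inv(X.T @ (w[:, None] * X) + ridge * np.eye(p))
    return beta, cov


def _impute_logistic(X_obs, y_obs, X_mis, rng, ridge):
    if y_obs.min() == y_obs.max():
        # degenerate: all observed values equal; impute that value
        return np.full(X_mis.shape[0], int(y_obs[0]))
    try:
        beta, cov = _logistic_irls(X_obs, y_obs, ridge)
    except np.linalg.LinAlgError:
        beta, cov = _logistic_irls(X_obs, y_obs, ridge * 1e3)
        warnings.warn("separation in logistic imputation; penalised fit used",
                      stacklevel=3)
    # approximate Bayesian draw of coefficients, then of outcomes
    L = np.linalg.cholesky((cov + cov.T) / 2.0 + 1e-12 * np.eye(cov.shape[0]))
    bstar = beta + L @ rng.standard_normal(beta.size)
    p = 1.0 / (1.0 + np.exp(-np.clip(X_mis @ bstar, -30, 30)))
    return (rng.random(X_mis.shape[0]) < p).astype(int)


def _impute_pmm(X_obs, y_obs, X_mis, rng, donors, ridge):
    n, p = X_obs.shape
    A = X_obs.T @ X_obs + ridge * np.eye(p)
    beta = np.linalg.solve(A, X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    # Bayesian draws of (sigma2, beta)
    sigma2_star = sigma2 * dof / max(rng.chisquare(dof), 1e-10)
    Ainv = np.linalg.inv(A)
    L = np.linalg.cholesky(sigma2_star * (Ainv + Ainv.T) / 2.0
                           + 1e-12 * np.eye(p))
    bstar = beta + L @ rng.standard_normal(p)
    pred_obs = X_obs @ beta
    pred_mis = X_mis @ bstar
    out = np.empty(X_mis.shape[0], int)
    k = min(donors, n)
    for i, pm in enumerate(pred_mis):
        d = np.abs(pred_obs - pm)
        cand = np.argpartition(d, k - 1)[:k]
        out[i] = int(y_obs[cand[rng.integers(0, cand.size)]])
    return out


def fcs_impute(matrix: ItemResponseMatrix, spec: ImputationSpec,
               seed=0) -> list[ItemResponseMatrix]:
    """Chained-equation imputation; returns m completed matrices.

    Complete input data are returned as m identical copies.  An all-missing
    column is an error.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mask = matrix.missing_mask
    for c, meta in enumerate(matrix.items):
        if mask[:, c].all():
            raise ValueError(f"item {meta.name!r} entirely missing")

    if not mask.any():
        return [
            ItemResponseMatrix(values=matrix.values.copy(),
                               missing_mask=np.zeros_like(mask),
                               items=list(matrix.items), gender=matrix.gender,
                               age=matrix.age)
            for _ in range(spec.m)
        ]

    scale_of = spec.scale_of or {m.name: "_all" for m in matrix.items}
    scales = sorted(set(scale_of.values()))
    totals = _scale_totals(matrix, scale_of)
    target_cols = [c for c in range(matrix.n_items) if mask[:, c].any()]

    out = []
    for _ in range(spec.m):
        vals = matrix.values.copy()
        # initialise missing entries with random observed draws
        for c in target_cols:
            obs = vals[~mask[:, c], c]
            vals[mask[:, c], c] = rng.choice(obs, size=int(mask[:, c].sum()))
        for _it in range(spec.iterations):
            for c in target_cols:
                meta = matrix.items[c]
                mis = mask[:, c]
                X = _design(matrix, totals, c, scale_of, scales)
                if meta.kind == "binary":
                    vals[mis, c] = _impute_logistic(
                        X[~mis], vals[~mis, c].astype(float), X[mis], rng,
                        spec.ridge)
                else:
                    vals[mis, c] = _impute_pmm(
                        X[~mis], vals[~mis, c].astype(float), X[mis], rng,
                        spec.pmm_donors, spec.ridge)
        out.append(ItemResponseMatrix(values=vals,
                                      missing_mask=np.zeros_like(mask),
                                      items=list(matrix.items),
                                      gender=matrix.gender, age=matrix.age))
    return out


@dataclass
class PoolingResult:
    estimate: np.ndarray        # pooled Q-bar
    within: np.ndarray          # W-bar
    between: np.ndarray         # B
    total: np.ndarray           # T = W + (1 + 1/m) B
    df: np.ndarray              # Barnard-Rubin degrees of freedom
    m: int

    def ci(self, level: float = 0.995) -> np.ndarray:
        q = np.where(np.isfinite(self.df),
                     t_dist.ppf(0.5 + level / 2.0, np.maximum(self.df, 1.0)),
                     norm.ppf(0.5 + level / 2.0))
        half = q * np.sqrt(self.total)
        return np.column_stack([self.estimate - half, self.estimate + half])


def pool_rubin(estimates, variances, *, df_complete=np.inf) -> PoolingResult:
    """Rubin's rules over per-imputation estimates and squared SEs.

    With m = 1 the between-imputation variance is undefined and the total
    variance falls back to the within variance (with a warning).
    """
    Q = np.asarray(estimates, float)
    U = np.asarray(variances, float)
    if Q.ndim == 1:                                   # m scalar estimates
        Q, U = Q[:, None], U[:, None]
    if Q.shape != U.shape:
        raise ValueError("estimates and variances have mismatched shapes")
    m = Q.shape[0]
    qbar = Q.mean(axis=0)
    wbar = U.mean(axis=0)
    if m == 1:
        warnings.warn("m = 1: between-imputation variance undefined",
                      stacklevel=2)
        b = np.zeros_like(qbar)
        total = wbar
        df = np.full_like(qbar, np.inf)
        return PoolingResult(qbar, wbar, b, total, df, m)
    b = Q.var(axis=0, ddof=1)
    total = wbar + (1.0 + 1.0 / m) * b
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1.0 + 1.0 / m) * b / wbar
        df_old = (m - 1) * (1.0 + 1.0 / np.where(r > 0, r, np.inf)) ** 2
        lam = (1.0 + 1.0 / m) * b / np.where(total > 0, total, np.inf)
        if np.isfinite(df_complete):
            df_obs = ((df_complete + 1.0) / (df_complete + 3.0)
                      * df_complete * (1.0 - lam))
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        else:
            df = df_old
    return PoolingResult(qbar, wbar, b, total, df, m)
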