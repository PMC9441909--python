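"""Symptom network models: residual partial-correlation and Ising networks.

Two complementary network analyses of the nine binary symptoms:

* Residual network model (RNM): a one-factor model whose item residuals
  carry a sparse partial-correlation network Omega, implied correlation
  matrix ``Lambda Lambda' + Delta (I - Omega)^-1 Delta`` with the diagonal
  scaling Delta chosen so latent responses keep unit variance.  Fitted by
  the same DWLS criterion as the plain factor model.

* Ising model on {0,1}^J: ``P(x) propto exp(sum_j t_j x_j +
  sum_{j<k} w_jk x_j x_k)`` fitted by exact maximum likelihood (the
  partition function is enumerated over the 2^J states, J <= 20).

Both families plug into the five-step stepwise structure search: candidate
edge removals need p > alpha, candidate additions need a modification
index with p < alpha, and moves are accepted greedily by BIC improvement.

Centrality (strength, closeness, betweenness on distances 1/|w|) and a
row-resampling bootstrap of centrality ranks quantify node importance and
its stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .cfa import FitResult, fit_result_from_dwls
from .dwls import DwlsFit, dwls_fit, numeric_jacobian, robust_score_test
from .polychoric import TetrachoricSummary

__all__ = [
    "ResidualNetwork",
    "IsingModel",
    "SearchTrace",
    "fit_rnm",
    "fit_ising",
    "ising_loglik",
    "sample_ising",
    "stepwise_search",
    "RnmFamily",
    "IsingFamily",
    "centrality",
    "bootstrap_centrality",
    "SeparationError",
]


def all_pairs(J):
    return [(j, k) for j in range(J) for k in range(j + 1, J)]


# ---------------------------------------------------------------------------
# Residual network model
# ---------------------------------------------------------------------------

class RnmCorrelationModel:
    """Implied correlations of factor-plus-residual-network structure.

    theta = (lambda_1..J, omega_e for e in edges).
    """

    def __init__(self, J, edges):
        self.J = J
        self.edges = sorted(edges)
        self.param_names = [f"lambda_{j+1}" for j in range(J)] + [
            f"omega_{j+1}{k+1}" for j, k in self.edges
        ]
        self.pairs = all_pairs(J)
        self._iu = np.triu_indices(J, k=1)

    def _unpack(self, theta):
        lam = theta[: self.J]
        om = np.zeros((self.J, self.J))
        for m, (j, k) in enumerate(self.edges):
            om[j, k] = om[k, j] = theta[self.J + m]
        return lam, om

    def implied(self, theta):
        lam, om = self._unpack(theta)
        # eigenvalue-floored inverse keeps the objective finite when a line
        # search wanders into a non-PD I - Omega region (optimum is interior)
        evals, evecs = np.linalg.eigh(np.eye(self.J) - om)
        evals = np.maximum(evals, 1e-6)
        K = (evecs / evals) @ evecs.T
        dk = np.diag(K)
        delta = np.sqrt(np.maximum(1.0 - lam ** 2, 1e-6) / dk)
        sig = np.outer(lam, lam) + delta[:, None] * K * delta[None, :]
        return sig[self._iu]

    def jacobian(self, theta):
        return numeric_jacobian(self.implied, theta)

    def start(self, stats):
        return np.concatenate([np.full(self.J, 0.6), np.zeros(len(self.edges))])

    def bounds(self):
        return [(-0.99, 0.99)] * self.J + [(-0.9, 0.9)] * len(self.edges)


@dataclass
class ResidualNetwork:
    loadings: np.ndarray
    loadings_se: np.ndarray
    omega: np.ndarray
    omega_se: np.ndarray
    edges: list[tuple[int, int]]
    fit: FitResult
    dwls: DwlsFit

    def edge_pvalues(self) -> dict[tuple[int, int], float]:
        p = self.dwls.wald_pvalues()
        return {e: float(p[self.dwls.param_names.index(f"omega_{e[0]+1}{e[1]+1}")])
                for e in self.edges}


def fit_rnm(summary: TetrachoricSummary, edges=()) -> ResidualNetwork:
    """Fit the residual network model with a fixed edge set by DWLS."""
    J = summary.n_items
    edges = sorted(tuple(sorted(e)) for e in edges)
    nthr = summary.n_thresholds
    s = summary.corr_vector
    xi = summary.asy_cov[nthr:, nthr:]
    model = RnmCorrelationModel(J, edges)
    fit = dwls_fit(s, xi, model, n=summary.n)
    if not fit.converged:
        warnings.warn("residual network fit did not converge", stacklevel=2)
    lam = fit.theta[:J]
    om = np.zeros((J, J))
    om_se = np.zeros((J, J))
    for m, (j, k) in enumerate(model.edges):
        om[j, k] = om[k, j] = fit.theta[J + m]
        om_se[j, k] = om_se[k, j] = fit.se[J + m]
    return ResidualNetwork(
        loadings=lam, loadings_se=fit.se[:J], omega=om, omega_se=om_se,
        edges=model.edges, fit=fit_result_from_dwls(fit), dwls=fit,
    )


# ---------------------------------------------------------------------------
# Ising model (exact likelihood)
# ---------------------------------------------------------------------------

class SeparationError(ValueError):
    """A symptom is always (or never) present; its threshold diverges."""


_STATE_CACHE: dict[int, np.ndarray] = {}


def _states(J) -> np.ndarray:
    if J not in _STATE_CACHE:
        if J > 20:
            raise ValueError("exact enumeration limited to J <= 20")
        grid = np.indices((2,) * J).reshape(J, -1).T[:, ::-1]
        _STATE_CACHE[J] = grid.astype(float)
    return _STATE_CACHE[J]


@dataclass
class IsingModel:
    thresholds: np.ndarray                  # (J,)
    weights: np.ndarray                     # (J, J) symmetric, zero diagonal
    edges: list[tuple[int, int]] | None = None
    thresholds_se: np.ndarray | None = None
    weights_se: np.ndarray | None = None
    acov: np.ndarray | None = None          # over (t, w_edges)
    loglik: float = np.nan
    bic: float = np.nan
    n: int = 0
    converged: bool = True

    def __post_init__(self):
        if self.edges is None:
            J = self.thresholds.size
            self.edges = [(j, k) for j in range(J) for k in range(j + 1, J)
                          if self.weights[j, k] != 0.0]

    @property
    def J(self) -> int:
        return self.thresholds.size

    def state_logweights(self) -> np.ndarray:
        S = _states(self.J)
        return S @ self.thresholds + 0.5 * np.einsum("sj,jk,sk->s", S,
                                                     self.weights, S)

    def log_partition(self) -> float:
        lw = self.state_logweights()
        m = lw.max()
        return float(m + np.log(np.exp(lw - m).sum()))

    def state_probs(self) -> np.ndarray:
        lw = self.state_logweights()
        lw = lw - lw.max()
        p = np.exp(lw)
        return p / p.sum()

    def edge_pvalues(self) -> dict[tuple[int, int], float]:
        out = {}
        for j, k in self.edges:
            se = self.weights_se[j, k]
            z = self.weights[j, k] / se if se > 0 else np.inf
            out[(j, k)] = float(2.0 * norm.sf(abs(z)))
        return out


def ising_loglik(thresholds, weights, X) -> float:
    """Exact log-likelihood of binary data under an Ising model."""
    X = np.asarray(X, float)
    t = np.asarray(thresholds, float)
    W = np.asarray(weights, float)
    model = IsingModel(thresholds=t, weights=W)
    logz = model.log_partition()
    e = X @ t + 0.5 * np.einsum("ij,jk,ik->i", X, W, X)
    return float(np.sum(e) - X.shape[0] * logz)


def sample_ising(model: IsingModel, n, seed=0) -> np.ndarray:
    """Exact sampling by enumeration of the 2^J state distribution."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = model.state_probs()
    idx = rng.choice(p.size, size=n, p=p)
    return _states(model.J)[idx].astype(int)


def fit_ising(X, edges=None, *, max_iter=200, tol=1e-9) -> IsingModel:
    """Exact-likelihood Newton fit of an Ising model with fixed structure.

    ``edges=None`` fits the saturated (fully connected) network.  Raises
    :class:`SeparationError` when a symptom shows no variation.
    """
    X = np.asarray(X, float)
    N, J = X.shape
    if np.any((X != 0) & (X != 1)):
        raise ValueError("Ising data must be binary 0/1")
    col_means = X.mean(axis=0)
    if np.any(col_means == 0.0) or np.any(col_means == 1.0):
        raise SeparationError("a symptom is constant; threshold is infinite")
    if edges is None:
        edges = all_pairs(J)
    edges = sorted(tuple(sorted(e)) for e in edges)
    E = len(edges)

    S = _states(J)
    # sufficient statistics: per-state features (J thresholds + E pairwise)
    feat = np.empty((S.shape[0], J + E))
    feat[:, :J] = S
    for m, (j, k) in enumerate(edges):
        feat[:, J + m] = S[:, j] * S[:, k]
    obs = np.empty(J + E)
    obs[:J] = X.sum(axis=0)
    for m, (j, k) in enumerate(edges):
        obs[J + m] = np.sum(X[:, j] * X[:, k])

    theta = np.zeros(J + E)
    theta[:J] = np.log(col_means / (1.0 - col_means))  # independence start

    def log_probs(th):
        lw = feat @ th
        lw = lw - lw.max()
        p = np.exp(lw)
        return p / p.sum()

    def nll(th):
        lw = feat @ th
        m = lw.max()
        logz = m + np.log(np.exp(lw - m).sum())
        return -(obs @ th - N * logz)

    cur = nll(theta)
    converged = False
    for _ in range(max_iter):
        p = log_probs(theta)
        mu = feat.T @ p
        grad = obs - N * mu
        cov = (feat.T * p) @ feat - np.outer(mu, mu)
        info = N * cov
        try:
            step = np.linalg.solve(info + 1e-10 * np.eye(info.shape[0]), grad)
        except np.linalg.LinAlgError:
            step = grad / N
        # damped Newton
        lam_step = 1.0
        for _ in range(30):
            new = theta + lam_step * step
            val = nll(new)
            if val <= cur + 1e-12:
                break
            lam_step /= 2.0
        theta, improved = new, cur - val
        cur = val
        if np.max(np.abs(grad)) / N < tol or improved < 1e-12:
            converged = True
            break

    p = log_probs(theta)
    mu = feat.T @ p
    cov = (feat.T * p) @ feat - np.outer(mu, mu)
    info = N * cov
    acov = np.linalg.pinv(info)
    se = np.sqrt(np.maximum(np.diag(acov), 0.0))

    W = np.zeros((J, J))
    W_se = np.zeros((J, J))
    for m, (j, k) in enumerate(edges):
        W[j, k] = W[k, j] = theta[J + m]
        W_se[j, k] = W_se[k, j] = se[J + m]
    ll = -cur
    k_par = J + E
    model = IsingModel(
        thresholds=theta[:J], weights=W, edges=edges,
        thresholds_se=se[:J], weights_se=W_se, acov=acov,
        loglik=ll, bic=-2.0 * ll + k_par * np.log(N), n=N, converged=converged,
    )
    if not converged:
        warnings.warn("Ising fit did not converge", stacklevel=2)
    return model


def _ising_mi_pvalues(model: IsingModel, X, candidates) -> dict[tuple[int, int], float]:
    """Score (modification-index) tests for absent edges at the fitted model."""
    X = np.asarray(X, float)
    N, J = X.shape
    S = _states(J)
    E = len(model.edges)
    feat = np.empty((S.shape[0], J + E))
    feat[:, :J] = S
    for m, (j, k) in enumerate(model.edges):
        feat[:, J + m] = S[:, j] * S[:, k]
    p = model.state_probs()
    mu = feat.T @ p
    cov_rr = (feat.T * p) @ feat - np.outer(mu, mu)
    inv_rr = np.linalg.pinv(cov_rr)
    out = {}
    for j, k in candidates:
        f_new = S[:, j] * S[:, k]
        mu_new = f_new @ p
        u = np.sum(X[:, j] * X[:, k]) - N * mu_new
        c_nr = (feat.T * p) @ f_new - mu * mu_new
        c_nn = (f_new * p) @ f_new - mu_new ** 2
        var = N * (c_nn - c_nr @ inv_rr @ c_nr)
        if var <= 0:
            out[(j, k)] = 1.0
            continue
        stat = u * u / var
        out[(j, k)] = float(chi2.sf(stat, 1))
    return out


# ---------------------------------------------------------------------------
# Five-step stepwise BIC structure search
# ---------------------------------------------------------------------------

@dataclass
class SearchStep:
    action: str                      # "add" | "remove"
    edge: tuple[int, int]
    bic_before: float
    bic_after: float
    pvalue: float                    # edge p (removal) or MI p (addition)


@dataclass
class SearchTrace:
    steps: list[SearchStep] = field(default_factory=list)
    terminated_early: bool = False

    def bic_path(self) -> list[float]:
        return [s.bic_after for s in self.steps]

    def to_records(self) -> list[dict]:
        return [vars(s) for s in self.steps]


class RnmFamily:
    """Residual-network candidates over a fixed tetrachoric summary."""

    def __init__(self, summary: TetrachoricSummary):
        self.summary = summary
        self.J = summary.n_items
        self._cache: dict[frozenset, ResidualNetwork] = {}

    def fit(self, edges: frozenset) -> ResidualNetwork:
        key = frozenset(edges)
        if key not in self._cache:
            self._cache[key] = fit_rnm(self.summary, sorted(edges))
        return self._cache[key]

    def bic(self, fitted: ResidualNetwork) -> float:
        return fitted.fit.bic

    def edge_pvalues(self, fitted: ResidualNetwork):
        return fitted.edge_pvalues()

    def mi_pvalues(self, fitted: ResidualNetwork, candidates):
        out = {}
        fit = fitted.dwls
        theta = fit.theta
        for j, k in candidates:
            model2 = RnmCorrelationModel(self.J, fitted.edges + [(j, k)])
            th2 = np.concatenate([theta, [0.0]])
            h = 1e-5
            tp, tm = th2.copy(), th2.copy()
            tp[-1] += h
            tm[-1] -= h
            direction = (model2.implied(tp) - model2.implied(tm)) / (2 * h)
            _, p = robust_score_test(fit, direction)
            out[(j, k)] = p
        return out

    def all_edges(self):
        return all_pairs(self.J)


class IsingFamily:
    """Ising-model candidates over fixed raw binary data."""

    def __init__(self, X):
        self.X = np.asarray(X, float)
        self.J = self.X.shape[1]
        self._cache: dict[frozenset, IsingModel] = {}

    def fit(self, edges: frozenset) -> IsingModel:
        key = frozenset(edges)
        if key not in self._cache:
            self._cache[key] = fit_ising(self.X, sorted(edges))
        return self._cache[key]

    def bic(self, fitted: IsingModel) -> float:
        return fitted.bic

    def edge_pvalues(self, fitted: IsingModel):
        return fitted.edge_pvalues()

    def mi_pvalues(self, fitted: IsingModel, candidates):
        return _ising_mi_pvalues(fitted, self.X, candidates)

    def all_edges(self):
        return all_pairs(self.J)


def stepwise_search(family, initial_edges=(), alpha=0.005,
                    max_steps=200) -> tuple[list[tuple[int, int]], SearchTrace, object]:
    """Greedy BIC structure search with significance screening.

    Each round: candidate moves are removals of edges with p > alpha and
    additions of absent edges whose modification index has p < alpha; all
    candidates are fitted and the move with the greatest BIC improvement is
    accepted (lexicographic edge order breaks exact ties); remaining
    candidates are then re-evaluated against the updated model and applied
    while they keep improving the BIC, after which screening starts afresh.
    Stops when no candidate improves the BIC.
    """
    edges = frozenset(tuple(sorted(e)) for e in initial_edges)
    current = family.fit(edges)
    trace = SearchTrace()
    toggles: dict[tuple[int, int], int] = {}

    for _ in range(max_steps):
        present = sorted(edges)
        absent = sorted(set(family.all_edges()) - edges)
        edge_p = family.edge_pvalues(current)
        mi_p = family.mi_pvalues(current, absent) if absent else {}

        moves = [("remove", e, edge_p[e]) for e in present if edge_p[e] > alpha]
        moves += [("add", e, mi_p[e]) for e in absent if mi_p[e] < alpha]
        if not moves:
            break

        improved_any = False
        while moves:
            bic_cur = family.bic(current)
            scored = []
            for action, e, p in moves:
                new_edges = edges - {e} if action == "remove" else edges | {e}
                cand = family.fit(frozenset(new_edges))
                scored.append((family.bic(cand) - bic_cur, action, e, p, new_edges))
            scored.sort(key=lambda z: (z[0], z[2]))  # improvement, then edge order
            best = scored[0]
            if best[0] >= -1e-9:
                break
            _, action, e, p, new_edges = best
            trace.steps.append(SearchStep(action=action, edge=e,
                                          bic_before=bic_cur,
                                          bic_after=family.bic(family.fit(frozenset(new_edges))),
                                          pvalue=p))
            edges = frozenset(new_edges)
            current = family.fit(edges)
            improved_any = True
            toggles[e] = toggles.get(e, 0) + 1
            if toggles[e] > 3:
                warnings.warn(f"edge {e} oscillating; search terminated",
                              stacklevel=2)
                trace.terminated_early = True
                return sorted(edges), trace, current
            moves = [(a, ee, pp) for a, ee, pp in moves if ee != e]
        if not improved_any:
            break

    return sorted(edges), trace, current


# ---------------------------------------------------------------------------
# Centrality
# ---------------------------------------------------------------------------

def centrality(weights, node_names=None) -> pd.DataFrame:
    """Strength, closeness and betweenness centrality of a weighted network.

    Edge distances are 1/|w|.  Closeness is the inverse of the summed
    shortest-path distances to all other nodes; for nodes with unreachable
    partners it is computed over the reachable set and flagged, and the
    harmonic variant (sum of inverse distances) is reported alongside.
    Betweenness counts shortest paths with fractional tie-splitting.
    """
    W = np.asarray(weights, float)
    J = W.shape[0]
    if node_names is None:
        node_names = [f"node{j+1}" for j in range(J)]
    strength = np.sum(np.abs(W), axis=1)

    G = nx.Graph()
    G.add_nodes_from(range(J))
    for j in range(J):
        for k in range(j + 1, J):
            if W[j, k] != 0.0:
                G.add_edge(j, k, distance=1.0 / abs(W[j, k]))
    dist = dict(nx.all_pairs_dijkstra_path_length(G, weight="distance"))
    closeness = np.zeros(J)
    harmonic = np.zeros(J)
    disconnected = np.zeros(J, bool)
    for j in range(J):
        d = [dist[j][k] for k in dist.get(j, {}) if k != j]
        if len(d) < J - 1:
            disconnected[j] = True
        closeness[j] = 1.0 / np.sum(d) if d else 0.0
        harmonic[j] = float(np.sum([1.0 / x for x in d])) if d else 0.0
    btw = nx.betweenness_centrality(G, weight="distance", normalized=False)
    betweenness = np.array([btw[j] for j in range(J)])

    return pd.DataFrame(
        {"strength": strength, "closeness": closeness,
         "harmonic_closeness": harmonic, "betweenness": betweenness,
         "disconnected": disconnected},
        index=node_names,
    )


def _ranks_desc(values) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(-np.asarray(values, float), method="average")


def bootstrap_centrality(X, edges, B=1000, level=0.995, seed=0,
                         node_names=None):
    """Percentile bootstrap of centrality ranks under a fixed structure.

    Rows are resampled, the Ising model is refitted with the same edge set,
    centralities are ranked (1 = most central) and percentile intervals of
    the ranks are formed at ``level``.  Replicates causing separation are
    dropped and counted.
    """
    X = np.asarray(X)
    rng = np.random.default_rng(seed)
    N, J = X.shape
    if node_names is None:
        node_names = [f"node{j+1}" for j in range(J)]
    indices = ("strength", "closeness", "betweenness")
    ranks = {ix: [] for ix in indices}
    dropped = 0
    for _ in range(B):
        idx = rng.integers(0, N, N)
        try:
            m = fit_ising(X[idx], edges)
        except SeparationError:
            dropped += 1
            continue
        cent = centrality(m.weights, node_names)
        for ix in indices:
            ranks[ix].append(_ranks_desc(cent[ix].to_numpy()))
    alpha = 1.0 - level
    out = {}
    for ix in indices:
        R = np.asarray(ranks[ix])
        lo = np.floor(np.quantile(R, alpha / 2.0, axis=0)).astype(int)
        hi = np.ceil(np.quantile(R, 1.0 - alpha / 2.0, axis=0)).astype(int)
        out[ix] = pd.DataFrame({"rank_lo": np.clip(lo, 1, J),
                                "rank_hi": np.clip(hi, 1, J)}, index=node_names)
    return out, dropped
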