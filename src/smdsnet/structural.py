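"""Construct validity: latent correlations between the symptom factor and
auxiliary constructs.

A joint measurement-plus-structural model: the nine binary symptom items
measure one factor; each auxiliary scale (psychological symptoms, online
communication frequency, preference for online interaction, screen time,
gaming frequency, late sleep, well-being) measures its own factor through
ordinal probit items.  All factors are standardized and their correlation
matrix Psi is free (correlated-factors model, no directional paths).  The
whole system is fitted by DWLS to the polychoric summary of all item
blocks at once, so the reported correlations are disattenuated for
measurement error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cfa import (
    FactorCorrelationModel,
    FactorModelSpec,
    FitResult,
    fit_result_from_dwls,
)
from .dwls import DwlsFit, dwls_fit
from .polychoric import TetrachoricSummary

__all__ = ["BlockSpec", "StructuralResult", "fit_structural", "attenuation_check"]


@dataclass
class BlockSpec:
    """Assignment of items to construct blocks, in summary column order."""

    names: list[str]              # construct names, in factor order
    item_factor: np.ndarray       # (J,) factor index per item

    @classmethod
    def from_counts(cls, names, counts) -> "BlockSpec":
        item_factor = np.concatenate(
            [np.full(c, i, int) for i, c in enumerate(counts)]
        )
        return cls(names=list(names), item_factor=item_factor)


@dataclass
class StructuralResult:
    psi: np.ndarray               # latent correlation matrix
    psi_se: np.ndarray
    loadings: np.ndarray
    loadings_se: np.ndarray
    construct_names: list[str]
    fit: FitResult
    dwls: DwlsFit
    ci_level: float = 0.995

    def psi_ci(self) -> tuple[np.ndarray, np.ndarray]:
        z = norm.ppf(0.5 + self.ci_level / 2.0)
        return self.psi - z * self.psi_se, self.psi + z * self.psi_se

    def corr(self, a: str, b: str) -> tuple[float, float, float]:
        """(estimate, lo, hi) for a construct pair."""
        i, j = self.construct_names.index(a), self.construct_names.index(b)
        lo, hi = self.psi_ci()
        return float(self.psi[i, j]), float(lo[i, j]), float(hi[i, j])

    def table(self) -> pd.DataFrame:
        lo, hi = self.psi_ci()
        rows = []
        k = len(self.construct_names)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append({
                    "construct_a": self.construct_names[i],
                    "construct_b": self.construct_names[j],
                    "r": self.psi[i, j], "se": self.psi_se[i, j],
                    "lo": lo[i, j], "hi": hi[i, j],
                })
        return pd.DataFrame(rows)


def fit_structural(summary: TetrachoricSummary, blocks: BlockSpec,
                   *, ci_level: float = 0.995) -> StructuralResult:
    """DWLS fit of the correlated-factors model over all item blocks."""
    J = summary.n_items
    if blocks.item_factor.size != J:
        raise ValueError("block spec does not match summary items")
    counts = np.bincount(blocks.item_factor)
    if np.any(counts < 2):
        bad = blocks.names[int(np.argmin(counts))]
        raise ValueError(f"construct {bad!r} has fewer than 2 items")

    spec = FactorModelSpec(item_factor=blocks.item_factor,
                           factor_names=blocks.names)
    nthr = summary.n_thresholds
    s = summary.corr_vector
    xi = summary.asy_cov[nthr:, nthr:]
    model = FactorCorrelationModel(spec, summary.pairs)
    fit = dwls_fit(s, xi, model, n=summary.n)

    nf = spec.n_factors
    psi = np.eye(nf)
    psi_se = np.zeros((nf, nf))
    for m, (f, g) in enumerate(model.psi_pairs):
        psi[f, g] = psi[g, f] = fit.theta[J + m]
        psi_se[f, g] = psi_se[g, f] = fit.se[J + m]
    # shrink a slightly indefinite estimate back to the PSD cone
    evals = np.linalg.eigvalsh(psi)
    if evals.min() < -1e-8:
        lam_min = evals.min()
        shrink = lam_min / (lam_min - 1e-6)
        psi = (1 - shrink) * psi + shrink * np.eye(nf)

    return StructuralResult(
        psi=psi, psi_se=psi_se,
        loadings=fit.theta[:J], loadings_se=fit.se[:J],
        construct_names=list(blocks.names),
        fit=fit_result_from_dwls(fit), dwls=fit, ci_level=ci_level,
    )


def attenuation_check(latent_r: float, omega1: float, omega2: float) -> float:
    """Expected sum-score correlation implied by a latent correlation.

    Observed-score correlations are attenuated by measurement error:
    r_obs = r_latent * sqrt(omega1 * omega2).
    """
    if not (0.0 < omega1 <= 1.0 and 0.0 < omega2 <= 1.0):
        raise ValueError("omegas must be in (0, 1]")
    if abs(latent_r) > 1.0:
        raise ValueError("|latent_r| must be <= 1")
    return float(latent_r * np.sqrt(omega1 * omega2))
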