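"""Synthetic item-response generator emulating the study's data structure.

All downstream stages are exercised on data from a one-factor probit model
(delta parametrization): item j of respondent i is endorsed when

    lambda_j * eta_i + eps_ij > tau_j,     eta ~ N(M_g, s_g^2),
    eps_j ~ N(0, 1 - lambda_j^2),

so the latent response has unit variance in the reference group, marginal
endorsement is 1 - Phi(tau_j) at zero latent mean, and the population
tetrachoric correlation of items j, k is lambda_j * lambda_k.  Optional
extensions: group-specific latent means/SDs and threshold offsets
(measurement non-invariance), residual dependence with a given partial
correlation structure on the item residuals, correlated auxiliary ordinal
scales, and MCAR/MAR missingness.

Defaults encode the emulated study's conditions: N = 13,377 split over
gender (50.9% boys) x age (11/13/15) groups, the published nine-item
loading/threshold profile, and auxiliary scales with the reported
reliabilities and construct correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri

from .data import (
    AGE_CLASSES,
    GENDERS,
    SMDS_ITEM_NAMES,
    ItemMeta,
    ItemResponseMatrix,
)

__all__ = [
    "SMDS_LOADINGS",
    "SMDS_THRESHOLDS",
    "AUX_BLOCKS",
    "CONSTRUCT_CORR",
    "CONSTRUCT_NAMES",
    "GroupDesign",
    "AuxBlockSpec",
    "GeneratorSpec",
    "simulate_onefactor",
    "simulate_residual_dependence",
    "simulate_multigroup",
    "simulate_auxiliary",
    "simulate_dataset",
    "spec_codebook",
    "scale_map",
    "impose_missingness",
    "default_spec",
    "equal_loadings_for_omega",
]

#: Generating loadings/thresholds for the nine symptom items (the parameter
#: profile estimated for this scale in large adolescent samples).
SMDS_LOADINGS = np.array([0.75, 0.81, 0.75, 0.57, 0.68, 0.69, 0.74, 0.67, 0.74])
SMDS_THRESHOLDS = np.array([0.97, 1.06, 0.90, 0.64, 1.10, 1.03, 1.24, 0.62, 1.14])

BOY_FRACTION = 0.509

#: Latent correlations among the eight constructs (symptom factor first).
CONSTRUCT_NAMES = ("smds", "mh", "ocf", "osp", "cst", "gf", "slp", "wb")
CONSTRUCT_CORR = np.array([
    [1.00, -0.38, 0.42, 0.29, 0.38, 0.17, 0.31, -0.28],
    [-0.38, 1.00, -0.19, -0.21, -0.26, -0.03, -0.28, 0.50],
    [0.42, -0.19, 1.00, 0.25, 0.52, 0.24, 0.46, 0.00],
    [0.29, -0.21, 0.25, 1.00, 0.22, 0.12, 0.24, -0.15],
    [0.38, -0.26, 0.52, 0.22, 1.00, 0.37, 0.47, -0.15],
    [0.17, -0.03, 0.24, 0.12, 0.37, 1.00, 0.31, -0.04],
    [0.31, -0.28, 0.46, 0.24, 0.47, 0.31, 1.00, -0.19],
    [-0.28, 0.50, 0.00, -0.15, -0.15, -0.04, -0.19, 1.00],
])


def equal_loadings_for_omega(omega: float, n_items: int) -> np.ndarray:
    """Equal loadings giving a target latent-scale McDonald's omega."""
    if not (0.0 < omega < 1.0):
        raise ValueError("omega must be in (0, 1)")
    lam = np.sqrt(omega / (n_items - (n_items - 1) * omega))
    return np.full(n_items, lam)


@dataclass
class AuxBlockSpec:
    """One auxiliary ordinal scale: unidimensional probit items."""

    name: str
    n_items: int
    n_categories: int
    loadings: np.ndarray
    cutpoints: np.ndarray | None = None  # shared item cut-points; default: equal mass

    def __post_init__(self):
        self.loadings = np.asarray(self.loadings, float)
        if self.loadings.size != self.n_items:
            raise ValueError(f"{self.name}: loadings length mismatch")
        if np.any(np.abs(self.loadings) >= 1.0):
            raise ValueError(f"{self.name}: |loading| must be < 1")
        if self.cutpoints is None:
            k = self.n_categories
            self.cutpoints = ndtri(np.arange(1, k) / k)

    @classmethod
    def from_omega(cls, name, n_items, n_categories, omega) -> "AuxBlockSpec":
        return cls(name, n_items, n_categories,
                   equal_loadings_for_omega(omega, n_items))

    @property
    def item_names(self) -> list[str]:
        return [f"{self.name}{i+1}" for i in range(self.n_items)]


#: Auxiliary scales with item counts, response categories and reliabilities
#: matching the emulated survey instruments.
AUX_BLOCKS = (
    ("mh", 4, 5, 0.71),    # psychological symptom checklist
    ("ocf", 4, 5, 0.72),   # online communication frequency
    ("osp", 3, 5, 0.92),   # preference for online social interaction
    ("cst", 2, 9, 0.93),   # computer screen time
    ("gf", 2, 9, 0.92),    # gaming frequency
    ("slp", 2, 8, 0.81),   # late sleep routine
    ("wb", 5, 6, 0.91),    # well-being
)


@dataclass
class GroupDesign:
    gender: str
    age: int
    n: int
    mean: float = 0.0
    sd: float = 1.0
    threshold_offsets: dict = field(default_factory=dict)  # item name -> shift

    def __post_init__(self):
        if self.gender not in GENDERS or self.age not in AGE_CLASSES:
            raise ValueError("unknown group label")
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        for item in self.threshold_offsets:
            if item not in SMDS_ITEM_NAMES:
                raise ValueError(f"offset references unknown item {item!r}")


@dataclass
class GeneratorSpec:
    """Full description of one synthetic dataset."""

    loadings: np.ndarray = field(default_factory=lambda: SMDS_LOADINGS.copy())
    thresholds: np.ndarray = field(default_factory=lambda: SMDS_THRESHOLDS.copy())
    groups: list[GroupDesign] = field(default_factory=list)
    residual_omega: np.ndarray | None = None
    aux_blocks: list[AuxBlockSpec] = field(default_factory=list)
    construct_corr: np.ndarray | None = None
    missing_rates: dict = field(default_factory=dict)   # item name -> rate
    missing_mechanism: str = "MCAR"                     # or "MAR_gender"

    def __post_init__(self):
        self.loadings = np.asarray(self.loadings, float)
        self.thresholds = np.asarray(self.thresholds, float)
        if np.any(np.abs(self.loadings) >= 1.0):
            raise ValueError("|loading| must be < 1 (delta parametrization)")
        if self.residual_omega is not None:
            om = np.asarray(self.residual_omega, float)
            if not np.allclose(om, om.T) or np.any(np.diag(om) != 0.0):
                raise ValueError("residual structure must be symmetric, zero diagonal")
            if np.any(np.linalg.eigvalsh(np.eye(om.shape[0]) - om) <= 0.0):
                raise ValueError("I - Omega must be positive definite")
            self.residual_omega = om
        for r in self.missing_rates.values():
            if not (0.0 <= r < 1.0):
                raise ValueError("missingness rates must be in [0, 1)")
        if self.construct_corr is not None:
            cc = np.asarray(self.construct_corr, float)
            if np.any(np.linalg.eigvalsh(cc) <= 0.0):
                raise ValueError("construct correlation matrix must be PD")
            self.construct_corr = cc


def default_spec() -> GeneratorSpec:
    """The emulated study conditions (defaults for the full pipeline)."""
    groups = _default_groups()
    blocks = [AuxBlockSpec.from_omega(nm, k, c, om) for nm, k, c, om in AUX_BLOCKS]
    rates = {nm: 0.02 for nm in SMDS_ITEM_NAMES}
    block_rates = {"mh": 0.08, "ocf": 0.19, "osp": 0.10, "cst": 0.0067,
                   "gf": 0.0067, "slp": 0.05, "wb": 0.19}
    for b in blocks:
        for it in b.item_names:
            rates[it] = block_rates[b.name]
    return GeneratorSpec(groups=groups, aux_blocks=blocks,
                         construct_corr=CONSTRUCT_CORR.copy(),
                         missing_rates=rates)


def _default_groups() -> list[GroupDesign]:
    # gender x age sizes consistent with the overall margins
    sizes = {(11, "boy"): 2229, (11, "girl"): 2151,
             (13, "boy"): 2369, (13, "girl"): 2285,
             (15, "boy"): 2210, (15, "girl"): 2133}
    # latent means: no gender gap at 11, widening to d = 0.26 / 0.36 at 13 / 15
    means = {(11, "boy"): 0.00, (11, "girl"): -0.01,
             (13, "boy"): 0.10, (13, "girl"): 0.36,
             (15, "boy"): 0.10, (15, "girl"): 0.46}
    # gender-variant thresholds (tolerance harder, persistence/escape easier
    # for girls) relative to the common profile
    offs = {"boy": {"tolerance": 1.09 - 1.06, "persistence": 0.82 - 0.64,
                    "escape": 0.80 - 0.62},
            "girl": {"tolerance": 1.21 - 1.06, "persistence": 0.59 - 0.64,
                     "escape": 0.60 - 0.62}}
    return [
        GroupDesign(gender=g, age=a, n=sizes[(a, g)], mean=means[(a, g)],
                    threshold_offsets=dict(offs[g]))
        for a in AGE_CLASSES for g in GENDERS
    ]


# ---------------------------------------------------------------------------
# Core samplers
# ---------------------------------------------------------------------------

def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _residual_cov(loadings, omega, sd=1.0):
    """Residual covariance Delta (I - Omega)^-1 Delta such that the latent
    responses have unit variance within the group (factor SD ``sd``)."""
    lam = np.asarray(loadings, float)
    J = lam.size
    resvar = 1.0 - (lam * sd) ** 2
    if np.any(resvar <= 0.0):
        raise ValueError("loading * group SD must stay below 1 for unit "
                         "latent-response variance")
    if omega is None:
        return np.diag(resvar)
    K = np.linalg.inv(np.eye(J) - omega)
    delta = np.sqrt(resvar / np.diag(K))
    return delta[:, None] * K * delta[None, :]


def _sample_binary(loadings, thresholds, n, rng, *, mean=0.0, sd=1.0,
                   residual_cov=None):
    lam = np.asarray(loadings, float)
    eta = mean + sd * rng.standard_normal(n)
    if residual_cov is None:
        residual_cov = _residual_cov(lam, None, sd)
    chol = np.linalg.cholesky(residual_cov)
    eps = rng.standard_normal((n, lam.size)) @ chol.T
    y = lam * eta[:, None] + eps
    return (y > np.asarray(thresholds, float)).astype(int)


def _binary_matrix(values, item_names=SMDS_ITEM_NAMES, gender=None, age=None):
    return ItemResponseMatrix(
        values=values,
        missing_mask=np.zeros_like(values, bool),
        items=[ItemMeta(nm, "binary") for nm in item_names],
        gender=gender, age=age,
    )


def simulate_onefactor(loadings=None, thresholds=None, n=13377, seed=0) -> ItemResponseMatrix:
    """Binary one-factor probit sample (single homogeneous group)."""
    rng = _as_rng(seed)
    lam = SMDS_LOADINGS if loadings is None else np.asarray(loadings, float)
    tau = SMDS_THRESHOLDS if thresholds is None else np.asarray(thresholds, float)
    vals = _sample_binary(lam, tau, n, rng)
    names = SMDS_ITEM_NAMES if lam.size == 9 else [f"item{j+1}" for j in range(lam.size)]
    return _binary_matrix(vals, names)


def simulate_residual_dependence(loadings, thresholds, omega, n, seed=0) -> ItemResponseMatrix:
    """One-factor sample with residual partial-correlation structure ``omega``.

    ``omega = 0`` reproduces :func:`simulate_onefactor` exactly (same seed,
    same draws): the residual covariance then reduces to the diagonal
    1 - lambda^2.
    """
    rng = _as_rng(seed)
    lam = np.asarray(loadings, float)
    J = lam.size
    om = None if omega is None else np.asarray(omega, float)
    if om is not None:
        if np.any(np.linalg.eigvalsh(np.eye(J) - om) <= 0.0):
            raise ValueError("I - Omega must be positive definite")
    cov = _residual_cov(lam, om)
    vals = _sample_binary(lam, thresholds, n, rng, residual_cov=cov)
    names = SMDS_ITEM_NAMES if J == 9 else [f"item{j+1}" for j in range(J)]
    return _binary_matrix(vals, names)


def simulate_multigroup(spec: GeneratorSpec, seed=0) -> ItemResponseMatrix:
    """Concatenated per-group samples with group-specific latent means/SDs
    and threshold offsets."""
    if not spec.groups:
        raise ValueError("group design is empty")
    rng = _as_rng(seed)
    blocks, genders, ages = [], [], []
    for g in spec.groups:
        tau = spec.thresholds.copy()
        for item, off in g.threshold_offsets.items():
            tau[list(SMDS_ITEM_NAMES).index(item)] += off
        cov = _residual_cov(spec.loadings, spec.residual_omega, g.sd)
        vals = _sample_binary(spec.loadings, tau, g.n, rng, mean=g.mean,
                              sd=g.sd, residual_cov=cov)
        blocks.append(vals)
        genders.extend([g.gender] * g.n)
        ages.extend([g.age] * g.n)
    return _binary_matrix(np.vstack(blocks), SMDS_ITEM_NAMES,
                          gender=np.array(genders), age=np.array(ages, int))


def simulate_auxiliary(spec: GeneratorSpec, n=13377, seed=0) -> ItemResponseMatrix:
    """Symptom items plus correlated auxiliary ordinal blocks.

    Construct scores are multivariate normal with ``spec.construct_corr``
    (symptom factor first); each block's items follow its own
    unidimensional probit model.
    """
    if spec.construct_corr is None or not spec.aux_blocks:
        raise ValueError("spec lacks construct correlations or aux blocks")
    rng = _as_rng(seed)
    ncon = spec.construct_corr.shape[0]
    if ncon != len(spec.aux_blocks) + 1:
        raise ValueError("construct matrix size must be n_blocks + 1")
    chol = np.linalg.cholesky(spec.construct_corr)
    scores = rng.standard_normal((n, ncon)) @ chol.T

    lam = spec.loadings
    eps = rng.standard_normal((n, lam.size)) * np.sqrt(1.0 - lam ** 2)
    smds_vals = ((lam * scores[:, [0]] + eps) > spec.thresholds).astype(int)

    cols = [smds_vals]
    items = [ItemMeta(nm, "binary") for nm in SMDS_ITEM_NAMES]
    for b, block in enumerate(spec.aux_blocks, start=1):
        lb = block.loadings
        epsb = rng.standard_normal((n, lb.size)) * np.sqrt(1.0 - lb ** 2)
        y = lb * scores[:, [b]] + epsb
        codes = 1 + np.sum(y[:, :, None] > block.cutpoints[None, None, :], axis=2)
        cols.append(codes.astype(int))
        items.extend(ItemMeta(nm, "ordinal", block.n_categories)
                     for nm in block.item_names)
    return ItemResponseMatrix(values=np.hstack(cols),
                              missing_mask=np.zeros((n, sum(c.shape[1] for c in cols)), bool),
                              items=items)


def simulate_dataset(spec: GeneratorSpec, seed=0, *, with_missing=True) -> ItemResponseMatrix:
    """Full study-like dataset: grouped symptom items plus auxiliary scales.

    Per group, construct scores are multivariate normal with the spec's
    correlation matrix; the symptom construct is then shifted/scaled by the
    group's latent mean and SD, symptom items are dichotomised at the
    group's (possibly offset) thresholds, and auxiliary ordinal items
    follow their block models.  Missingness is imposed last.
    """
    if not spec.groups:
        raise ValueError("group design is empty")
    rng = _as_rng(seed)
    use_aux = spec.construct_corr is not None and spec.aux_blocks
    ncon = spec.construct_corr.shape[0] if use_aux else 1
    chol = (np.linalg.cholesky(spec.construct_corr) if use_aux
            else np.ones((1, 1)))

    blocks, genders, ages = [], [], []
    for g in spec.groups:
        scores = rng.standard_normal((g.n, ncon)) @ chol.T
        eta = g.mean + g.sd * scores[:, 0]
        tau = spec.thresholds.copy()
        for item, off in g.threshold_offsets.items():
            tau[list(SMDS_ITEM_NAMES).index(item)] += off
        lam = spec.loadings
        resvar = 1.0 - (lam * g.sd) ** 2
        eps = rng.standard_normal((g.n, lam.size)) * np.sqrt(resvar)
        cols = [((lam * eta[:, None] + eps) > tau).astype(int)]
        for b, block in enumerate(spec.aux_blocks, start=1):
            lb = block.loadings
            epsb = rng.standard_normal((g.n, lb.size)) * np.sqrt(1.0 - lb ** 2)
            y = lb * scores[:, [b]] + epsb
            codes = 1 + np.sum(y[:, :, None] > block.cutpoints[None, None, :],
                               axis=2)
            cols.append(codes.astype(int))
        blocks.append(np.hstack(cols))
        genders.extend([g.gender] * g.n)
        ages.extend([g.age] * g.n)

    items = [ItemMeta(nm, "binary") for nm in SMDS_ITEM_NAMES]
    for block in spec.aux_blocks:
        items.extend(ItemMeta(nm, "ordinal", block.n_categories)
                     for nm in block.item_names)
    out = ItemResponseMatrix(values=np.vstack(blocks),
                             missing_mask=np.zeros((sum(g.n for g in spec.groups),
                                                    len(items)), bool),
                             items=items, gender=np.array(genders),
                             age=np.array(ages, int))
    if with_missing and spec.missing_rates:
        out = impose_missingness(out, spec, rng)
    return out


def spec_codebook(spec: GeneratorSpec):
    """Codebook matching the columns generated by :func:`simulate_dataset`."""
    from .data import Codebook

    items = [ItemMeta(nm, "binary") for nm in SMDS_ITEM_NAMES]
    for block in spec.aux_blocks:
        items.extend(ItemMeta(nm, "ordinal", block.n_categories)
                     for nm in block.item_names)
    return Codebook(items=items)


def scale_map(spec: GeneratorSpec) -> dict:
    """item name -> instrument name, for imputation predictor totals."""
    out = {nm: "smds" for nm in SMDS_ITEM_NAMES}
    for block in spec.aux_blocks:
        for nm in block.item_names:
            out[nm] = block.name
    return out


def impose_missingness(matrix: ItemResponseMatrix, spec: GeneratorSpec,
                       seed=0) -> ItemResponseMatrix:
    """Mask cells per the spec's per-item rates and mechanism.

    MCAR masks each cell independently at its item rate.  MAR_gender makes
    the masking probability depend on the (observed) gender label only:
    boys are masked at half the nominal rate and girls at the complementary
    rate so the overall fraction stays near nominal.
    """
    rng = _as_rng(seed)
    mask = matrix.missing_mask.copy()
    n = matrix.n
    for col, meta in enumerate(matrix.items):
        rate = spec.missing_rates.get(meta.name, 0.0)
        if rate == 0.0:
            continue
        if spec.missing_mechanism == "MCAR":
            p = np.full(n, rate)
        elif spec.missing_mechanism == "MAR_gender":
            if matrix.gender is None:
                raise ValueError("MAR_gender requires gender labels")
            boy = matrix.gender == "boy"
            frac_boy = boy.mean()
            # boys at half the nominal rate, girls compensating
            p_girl = min(rate * (1.0 - 0.5 * frac_boy) / max(1.0 - frac_boy, 1e-9), 0.99)
            p = np.where(boy, 0.5 * rate, p_girl)
        else:
            raise ValueError(f"unknown mechanism {spec.missing_mechanism!r}")
        mask[:, col] |= rng.random(n) < p
    out = ItemResponseMatrix(values=matrix.values.copy(), missing_mask=mask,
                             items=list(matrix.items), gender=matrix.gender,
                             age=matrix.age)
    return out
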