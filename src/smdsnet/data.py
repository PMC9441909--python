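"""Data model, file I/O, configuration and prevalence utilities.

The central container is :class:`ItemResponseMatrix`: an N x J matrix of
integer category codes with a missing-value mask, per-item metadata
(binary 0/1 or ordinal 1..K), and optional gender / age-class labels per
row.  Binary symptom items are coded "No" = 0, "Yes" = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SMDS_ITEM_NAMES",
    "ItemMeta",
    "ItemResponseMatrix",
    "Codebook",
    "read_responses",
    "classify_psmu",
    "PrevalenceTable",
    "summarize_prevalence",
    "AnalysisConfig",
    "write_edge_list",
]

#: The nine symptom items, in scale order.
SMDS_ITEM_NAMES = (
    "preoccupation",
    "tolerance",
    "withdrawal",
    "persistence",
    "displacement",
    "problem",
    "deception",
    "escape",
    "conflict",
)

GENDERS = ("boy", "girl")
AGE_CLASSES = (11, 13, 15)


@dataclass(frozen=True)
class ItemMeta:
    name: str
    kind: str  # "binary" | "ordinal"
    n_categories: int = 2

    def __post_init__(self):
        if self.kind not in ("binary", "ordinal"):
            raise ValueError(f"unknown item kind {self.kind!r}")
        if self.kind == "binary" and self.n_categories != 2:
            raise ValueError("binary items have 2 categories")
        if self.n_categories < 2:
            raise ValueError("items need at least 2 categories")

    @property
    def code_range(self) -> tuple[int, int]:
        if self.kind == "binary":
            return (0, 1)
        return (1, self.n_categories)


@dataclass
class ItemResponseMatrix:
    """Coded item responses with missing mask and group labels."""

    values: np.ndarray          # (N, J) int; entries under the mask are ignored
    missing_mask: np.ndarray    # (N, J) bool, True = missing
    items: list[ItemMeta]
    gender: np.ndarray | None = None   # (N,) of "boy"/"girl"
    age: np.ndarray | None = None      # (N,) of 11/13/15

    def __post_init__(self):
        self.values = np.asarray(self.values, int)
        self.missing_mask = np.asarray(self.missing_mask, bool)
        n, j = self.values.shape
        if n < 1:
            raise ValueError("empty response matrix")
        if self.missing_mask.shape != (n, j):
            raise ValueError("mask shape mismatch")
        if len(self.items) != j:
            raise ValueError("item metadata length mismatch")
        names = [m.name for m in self.items]
        if len(set(names)) != j:
            raise ValueError("item names must be unique")
        for col, meta in enumerate(self.items):
            lo, hi = meta.code_range
            obs = self.values[~self.missing_mask[:, col], col]
            bad = np.flatnonzero((obs < lo) | (obs > hi))
            if bad.size:
                raise ValueError(
                    f"item {meta.name!r}: code {obs[bad[0]]} out of range [{lo}, {hi}]"
                )
        for lab, allowed in (("gender", GENDERS), ("age", AGE_CLASSES)):
            arr = getattr(self, lab)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != (n,):
                    raise ValueError(f"{lab} labels length mismatch")
                if not set(np.unique(arr)).issubset(set(allowed)):
                    raise ValueError(f"unknown {lab} label")
                setattr(self, lab, arr)

    # -- shape helpers ------------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def item_names(self) -> list[str]:
        return [m.name for m in self.items]

    @property
    def n_categories(self) -> np.ndarray:
        return np.array([m.n_categories for m in self.items])

    def column(self, name: str) -> int:
        try:
            return self.item_names.index(name)
        except ValueError:
            raise KeyError(f"unknown item {name!r}") from None

    def select_items(self, names) -> "ItemResponseMatrix":
        idx = [self.column(nm) for nm in names]
        return replace(
            self,
            values=self.values[:, idx],
            missing_mask=self.missing_mask[:, idx],
            items=[self.items[i] for i in idx],
        )

    def select_rows(self, rows) -> "ItemResponseMatrix":
        rows = np.asarray(rows)
        return replace(
            self,
            values=self.values[rows],
            missing_mask=self.missing_mask[rows],
            gender=None if self.gender is None else self.gender[rows],
            age=None if self.age is None else self.age[rows],
        )

    def complete_rows(self) -> np.ndarray:
        return ~self.missing_mask.any(axis=1)

    def complete_values(self) -> np.ndarray:
        """Values of listwise-complete rows (raises if none)."""
        keep = self.complete_rows()
        if not keep.any():
            raise ValueError("no complete rows")
        return self.values[keep]

    # -- I/O ----------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values.astype(float), columns=self.item_names)
        df[self.missing_mask] = np.nan
        if self.gender is not None:
            df["gender"] = self.gender
        if self.age is not None:
            df["age_class"] = self.age
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class Codebook:
    """Column metadata for reading raw CSV item-response files."""

    items: list[ItemMeta]
    gender_column: str | None = "gender"
    age_column: str | None = "age_class"
    gender_map: dict = field(default_factory=lambda: {"boy": "boy", "girl": "girl",
                                                      "1": "boy", "2": "girl"})
    missing_sentinels: tuple = ("", "NA", "nan")

    @classmethod
    def smds(cls) -> "Codebook":
        return cls(items=[ItemMeta(nm, "binary") for nm in SMDS_ITEM_NAMES])


def read_responses(path, codebook: Codebook) -> ItemResponseMatrix:
    """Read and validate a CSV item-response file against a codebook.

    Empty cells and declared sentinels are missing.  Out-of-range codes and
    unknown columns raise with the offending row/column named.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    for meta in codebook.items:
        if meta.name not in df.columns:
            raise ValueError(f"{path}: missing item column {meta.name!r}")

    n = df.shape[0]
    j = len(codebook.items)
    values = np.zeros((n, j), int)
    mask = np.zeros((n, j), bool)
    for col, meta in enumerate(codebook.items):
        raw = df[meta.name].astype(str).str.strip()
        is_missing = raw.isin(codebook.missing_sentinels).to_numpy()
        mask[:, col] = is_missing
        lo, hi = meta.code_range
        for i, v in enumerate(raw):
            if is_missing[i]:
                continue
            try:
                code = int(float(v))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric code {v!r} in column {meta.name!r}, row {i}"
                ) from None
            if code < lo or code > hi:
                raise ValueError(
                    f"{path}: code {code} out of range [{lo}, {hi}] "
                    f"in column {meta.name!r}, row {i}"
                )
            values[i, col] = code

    gender = age = None
    if codebook.gender_column and codebook.gender_column in df.columns:
        raw = df[codebook.gender_column].astype(str).str.strip()
        try:
            gender = np.array([codebook.gender_map[v] for v in raw])
        except KeyError as e:
            raise ValueError(f"{path}: unmapped gender code {e}") from None
    if codebook.age_column and codebook.age_column in df.columns:
        age = df[codebook.age_column].astype(float).astype(int).to_numpy()

    return ItemResponseMatrix(values=values, missing_mask=mask,
                              items=list(codebook.items), gender=gender, age=age)


# ---------------------------------------------------------------------------
# Classification and prevalence
# ---------------------------------------------------------------------------

def classify_psmu(row, cutoff: int = 6) -> bool:
    """Problematic-use flag: at least ``cutoff`` of the 9 symptoms endorsed.

    All nine items must be observed; raises on missing input.
    """
    row = np.asarray(row, float)
    if row.size != 9:
        raise ValueError("expected 9 symptom responses")
    if np.any(~np.isfinite(row)):
        raise ValueError("classification undefined with missing symptoms")
    return bool(row.sum() >= cutoff)


@dataclass
class PrevalenceTable:
    item_rates: pd.Series          # available-case endorsement per item
    psmu_rate: float               # complete rows with >= cutoff symptoms
    n_complete: int
    cutoff: int
    by_group: pd.DataFrame | None = None


def summarize_prevalence(matrix: ItemResponseMatrix, by_group: bool = False,
                         cutoff: int = 6) -> PrevalenceTable:
    """Per-item endorsement and problematic-use rate.

    Item rates are available-case proportions over observed responses
    (pre-imputation convention); the problematic-use rate uses only rows
    with all nine symptom items observed.
    """
    smds = matrix.select_items([n for n in SMDS_ITEM_NAMES])
    rates = {}
    for col, meta in enumerate(smds.items):
        obs = smds.values[~smds.missing_mask[:, col], col]
        if obs.size == 0:
            raise ValueError(f"item {meta.name!r} entirely missing")
        rates[meta.name] = float(obs.mean())
    complete = smds.complete_rows()
    n_complete = int(complete.sum())
    if n_complete == 0:
        raise ValueError("no rows with all nine symptom items observed")
    sums = smds.values[complete].sum(axis=1)
    psmu = float((sums >= cutoff).mean())

    by = None
    if by_group and matrix.gender is not None:
        rows = []
        for g in GENDERS:
            sel = matrix.gender == g
            sub_complete = complete & sel
            if sub_complete.sum() == 0:
                continue
            gsums = smds.values[sub_complete].sum(axis=1)
            rows.append({"gender": g, "n_complete": int(sub_complete.sum()),
                         "psmu_rate": float((gsums >= cutoff).mean())})
        by = pd.DataFrame(rows)

    return PrevalenceTable(item_rates=pd.Series(rates), psmu_rate=psmu,
                           n_complete=n_complete, cutoff=cutoff, by_group=by)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Constants governing a full analysis run."""

    cutoff: int = 6
    m_imputations: int = 10
    fcs_iterations: int = 10
    pmm_donors: int = 5
    bootstrap_b: int = 1000
    ci_level: float = 0.995
    edge_alpha: float = 0.005
    metric_delta_rmsea: float = 0.05
    scalar_delta_rmsea: float = 0.01
    delta_cfi: float = -0.004
    seed: int = 0
    n: int = 13377
    input_path: str | None = None
    out_dir: str = "smdsnet-out"

    def __post_init__(self):
        if not (1 <= self.cutoff <= 9):
            raise ValueError("cutoff must be in 1..9")
        if self.m_imputations < 1 or self.bootstrap_b < 1:
            raise ValueError("m and B must be >= 1")
        if not (0.0 < self.edge_alpha < 1.0):
            raise ValueError("edge_alpha must be in (0, 1)")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        from dataclasses import asdict

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def write_edge_list(path, node_names, weights, se=None, pvalues=None) -> None:
    """TSV weighted edge list (node_i, node_j, weight[, se, p])."""
    weights = np.asarray(weights, float)
    rows = []
    J = weights.shape[0]
    for j in range(J):
        for k in range(j + 1, J):
            if weights[j, k] == 0.0:
                continue
            row = {"node_i": node_names[j], "node_j": node_names[k],
                   "weight": weights[j, k]}
            if se is not None:
                row["se"] = np.asarray(se)[j, k]
            if pvalues is not None:
                row["p"] = np.asarray(pvalues)[j, k]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
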