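"""Merging, quality control, normalization and data splitting for PK compound tables.

Pipeline order mirrors standard practice for small PK datasets:

1. merge CL and VD tables on whitespace-stripped (name, SMILES) keys;
2. drop compounds outside physiological ranges (VDss >= 5 L/kg or
   CL >= 20 mL/min/kg, inclusive);
3. winsorize numeric feature columns at the 1st/99th percentiles (pooled,
   pre-split);
4. split 60/20/20, either purely at random or by minimizing a
   Kolmogorov-Smirnov distribution-similarity criterion over many random
   candidates;
5. fit per-column transforms on the training partition only: log1p then
   standardize for targets and animal PK, standardize only for
   physicochemical covariates, with exact inverse transforms preserved
   for evaluation on the original scale.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from sklearn.base import BaseEstimator, TransformerMixin

TARGET_COLUMNS = ["human_CL_mL_min_kg", "human_VDss_L_kg"]
ANIMAL_PK_COLUMNS = [
    "rat_CL_mL_min_kg", "rat_VDss_L_kg",
    "dog_CL_mL_min_kg", "dog_VDss_L_kg",
    "monkey_CL_mL_min_kg", "monkey_VDss_L_kg",
]
PHYSCHEM_COLUMNS = [
    "human_fup", "rat_fup", "dog_fup", "monkey_fup", "pKa_Acid", "pKa_base",
]
EXCLUDED_PREFIXES = ("Caco_2", "water_solubility")

_WS = re.compile(r"\s+")


def _strip_ws(value: str) -> str:
    return _WS.sub("", str(value))


def merge_cl_vd(cl_rows: pd.DataFrame, vd_rows: pd.DataFrame) -> pd.DataFrame:
    """Merge a CL table and a VD table into one record per compound.

    The join key is the (name, SMILES) pair with *all* whitespace removed.
    A duplicate key within either input table raises; rows carrying neither
    target are dropped.
    """
    frames = []
    for label, df, target in (("cl", cl_rows, "human_CL_mL_min_kg"),
                              ("vd", vd_rows, "human_VDss_L_kg")):
        if df is None or len(df) == 0:
            continue
        if "name" not in df.columns or "smiles" not in df.columns:
            raise ValueError(f"{label} table must contain 'name' and 'smiles' columns")
        df = df.copy()
        df["_key_name"] = df["name"].map(_strip_ws)
        df["_key_smiles"] = df["smiles"].map(_strip_ws)
        dup = df.duplicated(subset=["_key_name", "_key_smiles"], keep=False)
        if dup.any():
            key = tuple(df.loc[dup, ["_key_name", "_key_smiles"]].iloc[0])
            raise ValueError(f"duplicate key in {label} table: {key}")
        frames.append(df.set_index(["_key_name", "_key_smiles"]))
    if not frames:
        return pd.DataFrame()
    if len(frames) == 1:
        merged = frames[0]
    else:
        left, right = frames
        shared = [c for c in right.columns if c in left.columns]
        merged = left.join(right.drop(columns=shared), how="outer")
        # metadata columns present only on one side: fill from the other
        for col in shared:
            if col in right.columns:
                merged[col] = merged[col].where(merged[col].notna(), right[col])
    merged = merged.reset_index(drop=True)
    has_target = pd.Series(False, index=merged.index)
    for t in TARGET_COLUMNS:
        if t in merged.columns:
            has_target |= merged[t].notna()
    return merged[has_target].reset_index(drop=True)


def filter_physiological(
    records: pd.DataFrame,
    cl_max: float = 20.0,
    vd_max: float = 5.0,
) -> tuple[pd.DataFrame, int]:
    """Drop compounds with CL >= 20 mL/min/kg or VDss >= 5 L/kg (inclusive).

    Values above these bounds are treated as biologically implausible.
    Returns (kept_records, removed_count).
    """
    bad = pd.Series(False, index=records.index)
    if "human_CL_mL_min_kg" in records.columns:
        cl = records["human_CL_mL_min_kg"]
        bad |= cl.notna() & (cl >= cl_max)
    if "human_VDss_L_kg" in records.columns:
        vd = records["human_VDss_L_kg"]
        bad |= vd.notna() & (vd >= vd_max)
    kept = records[~bad].reset_index(drop=True)
    return kept, int(bad.sum())


def winsorize(values: pd.Series, lower_q: float = 0.01, upper_q: float = 0.99) -> pd.Series:
    """Clip a numeric column to its empirical [lower_q, upper_q] quantiles.

    Quantiles use linear interpolation between order statistics; missing
    entries are ignored when computing the quantiles and preserved in the
    output.
    """
    finite = values.dropna()
    if finite.empty:
        warnings.warn("winsorize: all-missing column left unchanged")
        return values.copy()
    lo = float(np.quantile(finite, lower_q))
    hi = float(np.quantile(finite, upper_q))
    return values.clip(lower=lo, upper=hi)


def winsorize_features(df: pd.DataFrame, columns: list[str] | None = None,
                       lower_q: float = 0.01, upper_q: float = 0.99) -> pd.DataFrame:
    """Winsorize every numeric feature column (targets untouched)."""
    out = df.copy()
    if columns is None:
        columns = [c for c in ANIMAL_PK_COLUMNS + PHYSCHEM_COLUMNS if c in df.columns]
    for c in columns:
        out[c] = winsorize(out[c], lower_q, upper_q)
    return out


class PKColumnScaler(BaseEstimator, TransformerMixin):
    """Per-column transform: log1p+standardize, standardize-only, or excluded.

    Column roles are inferred from ``column_roles`` (a mapping column ->
    {'target', 'animal_pk', 'physicochemical', 'excluded'}).  Columns whose
    name starts with an excluded prefix are forced to 'excluded'.  Means and
    standard deviations are fitted on the rows passed to :meth:`fit` (the
    training partition); a zero-variance column gets sd 1 with a warning.
    The fitted parameters support an exact inverse transform.
    """

    def __init__(self, column_roles: dict[str, str] | None = None):
        self.column_roles = column_roles

    @staticmethod
    def default_roles(columns) -> dict[str, str]:
        roles = {}
        for c in columns:
            if c in TARGET_COLUMNS:
                roles[c] = "target"
            elif c in ANIMAL_PK_COLUMNS:
                roles[c] = "animal_pk"
            elif c in PHYSCHEM_COLUMNS:
                roles[c] = "physicochemical"
            else:
                roles[c] = "excluded"
        return roles

    def fit(self, X: pd.DataFrame, y=None):
        roles = self.column_roles or self.default_roles(X.columns)
        self.params_: dict[str, dict] = {}
        for col, role in roles.items():
            if col not in X.columns:
                continue
            if col.startswith(EXCLUDED_PREFIXES) or role == "excluded":
                self.params_[col] = {"kind": "excluded", "mean": 0.0, "sd": 1.0}
                continue
            vals = X[col].astype(float)
            if role in ("target", "animal_pk"):
                kind = "log1p_standardize"
                vals = np.log1p(vals)
            else:
                kind = "standardize_only"
            finite = vals.dropna()
            mean = float(finite.mean()) if len(finite) else 0.0
            sd = float(finite.std(ddof=0)) if len(finite) else 0.0
            if sd == 0.0:
                warnings.warn(f"zero-variance column '{col}': sd set to 1")
                sd = 1.0
            self.params_[col] = {"kind": kind, "mean": mean, "sd": sd}
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for col, p in self.params_.items():
            if col not in out.columns or p["kind"] == "excluded":
                continue
            v = out[col].astype(float)
            if p["kind"] == "log1p_standardize":
                v = np.log1p(v)
            out[col] = (v - p["mean"]) / p["sd"]
        return out

    def inverse_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for col, p in self.params_.items():
            if col not in out.columns or p["kind"] == "excluded":
                continue
            v = out[col].astype(float) * p["sd"] + p["mean"]
            if p["kind"] == "log1p_standardize":
                v = np.expm1(v)
            out[col] = v
        return out

    def transform_column(self, col: str, values: np.ndarray) -> np.ndarray:
        p = self.params_[col]
        v = np.asarray(values, float)
        if p["kind"] == "excluded":
            return v
        if p["kind"] == "log1p_standardize":
            v = np.log1p(v)
        return (v - p["mean"]) / p["sd"]

    def inverse_column(self, col: str, values: np.ndarray) -> np.ndarray:
        p = self.params_[col]
        v = np.asarray(values, float)
        if p["kind"] == "excluded":
            return v
        v = v * p["sd"] + p["mean"]
        if p["kind"] == "log1p_standardize":
            v = np.expm1(v)
        return v

    def to_json(self) -> str:
        return json.dumps(self.params_, indent=2, sort_keys=True)


@dataclass
class SplitPlan:
    """A disjoint, exhaustive train/val/test index partition."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    criterion: float = float("nan")

    def validate(self, n: int) -> None:
        allidx = np.concatenate([self.train_idx, self.val_idx, self.test_idx])
        if len(np.unique(allidx)) != n or len(allidx) != n:
            raise ValueError("split plan is not a disjoint exhaustive partition")

    def to_dict(self) -> dict:
        return {
            "train_idx": self.train_idx.tolist(),
            "val_idx": self.val_idx.tolist(),
            "test_idx": self.test_idx.tolist(),
            "ratios": list(self.ratios),
            "seed": int(self.seed),
            "criterion": None if np.isnan(self.criterion) else float(self.criterion),
        }


def _partition_sizes(n: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    n_val = int(round(ratios[1] * n))
    n_test = int(round(ratios[2] * n))
    return n - n_val - n_test, n_val, n_test


def _random_partition(n: int, ratios, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_train, n_val, n_test = _partition_sizes(n, ratios)
    perm = rng.permutation(n)
    return (np.sort(perm[:n_train]),
            np.sort(perm[n_train:n_train + n_val]),
            np.sort(perm[n_train + n_val:]))


def split_similarity_criterion(records: pd.DataFrame, parts,
                               target_columns: list[str] | None = None) -> float:
    """Mean pairwise two-sample KS statistic of log1p targets across partitions.

    Averaged over the target columns and the three partition pairs; missing
    target values are ignored.  Lower is better (more similar marginals).
    """
    if target_columns is None:
        target_columns = [c for c in TARGET_COLUMNS if c in records.columns]
    stats = []
    for col in target_columns:
        vals = np.log1p(records[col].to_numpy(float))
        groups = [vals[idx][~np.isnan(vals[idx])] for idx in parts]
        pair_stats = []
        for i in range(3):
            for j in range(i + 1, 3):
                if len(groups[i]) == 0 or len(groups[j]) == 0:
                    return float("inf")
                pair_stats.append(ks_2samp(groups[i], groups[j]).statistic)
        stats.append(np.mean(pair_stats))
    return float(np.mean(stats)) if stats else float("inf")


def optimize_split(records: pd.DataFrame, n_candidates: int = 10000,
                   ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
                   seed: int = 0) -> SplitPlan:
    """Pick, among ``n_candidates`` random partitions, the one whose
    train/val/test target marginals are most similar (minimum KS criterion).
    """
    n = len(records)
    if n < 10:
        raise ValueError("need at least 10 records to split")
    rng = np.random.default_rng(seed)
    best: SplitPlan | None = None
    for _ in range(n_candidates):
        parts = _random_partition(n, ratios, rng)
        if any(len(p) == 0 for p in parts):
            continue
        crit = split_similarity_criterion(records, parts)
        if best is None or crit < best.criterion:
            best = SplitPlan(*parts, ratios=ratios, seed=seed, criterion=crit)
    if best is None:
        raise ValueError("no valid candidate partition found")
    return best


def random_split(records: pd.DataFrame,
                 ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
                 seed: int = 0) -> SplitPlan:
    """Single random partition (no optimization).

    The KS criterion is left unset: a plain random split is a function of
    the row count and seed alone, and never reads any data values.
    """
    n = len(records)
    rng = np.random.default_rng(seed)
    parts = _random_partition(n, ratios, rng)
    return SplitPlan(*parts, ratios=ratios, seed=seed)


def repeated_splits(records: pd.DataFrame, k: int = 10,
                    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
                    base_seed: int = 0) -> list[SplitPlan]:
    """k independent random partitions from seeds base_seed .. base_seed+k-1."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return [random_split(records, ratios=ratios, seed=base_seed + i) for i in range(k)]
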