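"""Shadow-feature (Boruta-style) selection with Shapley-based importance.

Each iteration appends an independently permuted "shadow" copy of every
feature, fits a depth-capped gradient-boosted learner on the augmented
table, and scores every column by its mean absolute Shapley attribution.
A real feature scores a *hit* when its importance exceeds a percentile
(default the 80th) of that iteration's shadow importances.  After all
iterations, a two-sided binomial test against hit probability 0.5 labels
each feature accepted (more hits than chance, p < alpha), rejected (fewer,
p < alpha) or tentative.  Selection runs per target; the multi-task model
uses the union of the per-target accepted lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.base import BaseEstimator
import lightgbm as lgb

from .interpret import exact_shapley, kernel_shapley


@dataclass
class SelectionConfig:
    """Boruta-style selection settings (defaults follow the study setup:
    5,000 iterations, 80th-percentile shadow threshold, depth-5 learner)."""

    n_iterations: int = 5000
    shadow_percentile: float = 80.0
    max_depth: int = 5
    alpha: float = 0.05
    seed: int = 0
    n_estimators: int = 40           # learner boosting rounds per iteration
    subsample_frac: float = 0.5      # rows drawn (without replacement) per iteration
    feature_fraction: float = 0.7    # columns per tree in the learner
    importance_rows: int = 24        # rows sampled for Shapley scoring
    background_rows: int = 16        # background set for the value function
    shap_budget: int = 256           # coalition budget for the kernel estimator

    def validate(self) -> None:
        if not 0 < self.shadow_percentile <= 100:
            raise ValueError("shadow_percentile must lie in (0, 100]")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class FeatureDecision:
    """Per-feature selection outcome."""

    feature_names: list[str]
    status: dict[str, str] = field(default_factory=dict)       # accepted/rejected/tentative
    hit_count: dict[str, int] = field(default_factory=dict)
    n_trials: int = 0
    p_value: dict[str, float] = field(default_factory=dict)

    @property
    def accepted(self) -> list[str]:
        return [f for f in self.feature_names if self.status[f] == "accepted"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.feature_names,
            "status": [self.status[f] for f in self.feature_names],
            "hits": [self.hit_count[f] for f in self.feature_names],
            "trials": self.n_trials,
            "p": [self.p_value[f] for f in self.feature_names],
        })


def shadow_augment(X: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Append an independently row-permuted copy of each column as
    ``shadow_<name>``; width doubles."""
    if X.shape[1] < 1 or X.shape[0] < 2:
        raise ValueError("need at least 1 feature and 2 rows")
    rng = np.random.default_rng(seed)
    out = X.copy()
    for col in X.columns:
        out[f"shadow_{col}"] = X[col].to_numpy()[rng.permutation(len(X))]
    return out


def importance_scores(learner, X: np.ndarray, seed: int = 0,
                      importance_rows: int = 30, background_rows: int = 20,
                      budget: int = 256) -> np.ndarray:
    """Mean |Shapley| per column of a fitted learner.

    Exact enumeration when the table has <= 10 columns, the kernel
    estimator otherwise; rows to explain and background rows are seeded
    subsamples of ``X``.
    """
    if not hasattr(learner, "predict"):
        raise ValueError("learner must be fitted and expose predict")
    X = np.asarray(X, float)
    rng = np.random.default_rng(seed)
    n, m = X.shape
    rows = X[rng.choice(n, size=min(importance_rows, n), replace=False)]
    bg = X[rng.choice(n, size=min(background_rows, n), replace=False)]

    def fn(mat):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # lgb/sklearn feature-name chatter
            return learner.predict(mat)

    if m <= 10:
        attr = exact_shapley(fn, rows, bg)
    else:
        attr = kernel_shapley(fn, rows, bg, budget=max(budget, 2 * m + 2),
                              seed=int(rng.integers(2**31 - 1)))
    return np.abs(attr.values).mean(axis=0)


def _fit_learner(X: np.ndarray, y: np.ndarray, cfg: SelectionConfig, seed: int):
    model = lgb.LGBMRegressor(
        max_depth=cfg.max_depth, num_leaves=2**cfg.max_depth - 1,
        n_estimators=cfg.n_estimators, random_state=seed,
        feature_fraction=cfg.feature_fraction, feature_fraction_seed=seed + 1,
        deterministic=True, n_jobs=1, verbose=-1, force_col_wise=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model


def boruta_shap_select(X: pd.DataFrame, y, cfg: SelectionConfig | None = None
                       ) -> FeatureDecision:
    """Run the shadow-comparison loop and classify every feature.

    ``X`` must be complete (no missing values); ``y`` complete and aligned.
    """
    cfg = cfg or SelectionConfig()
    cfg.validate()
    if cfg.n_iterations < 5:
        warnings.warn("fewer than 5 iterations: binomial test is underpowered")
    if isinstance(X, np.ndarray):
        X = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
    if X.isna().any().any():
        raise ValueError("X must not contain missing values")
    y = np.asarray(y, float)
    names = list(X.columns)
    m = len(names)
    rng = np.random.default_rng(cfg.seed)
    hits = np.zeros(m, int)
    n_rows = len(X)
    for it in range(cfg.n_iterations):
        aug = shadow_augment(X, seed=int(rng.integers(2**31 - 1)))
        A = aug.to_numpy(float)
        # learner perturbation: each iteration fits on a fresh row subsample,
        # so finite-sample spurious structure does not recur identically and
        # real-vs-shadow exchangeability holds for null features
        sub = rng.choice(n_rows, size=max(2, int(round(cfg.subsample_frac * n_rows))),
                         replace=False)
        model = _fit_learner(A[sub], y[sub], cfg,
                             seed=int(rng.integers(2**31 - 1)))
        scores = importance_scores(
            model, A, seed=int(rng.integers(2**31 - 1)),
            importance_rows=cfg.importance_rows,
            background_rows=cfg.background_rows, budget=cfg.shap_budget)
        shadow_scores = scores[m:]
        threshold = np.percentile(shadow_scores, cfg.shadow_percentile)
        hits += (scores[:m] > threshold).astype(int)

    decision = FeatureDecision(feature_names=names, n_trials=cfg.n_iterations)
    for i, f in enumerate(names):
        res = binomtest(int(hits[i]), cfg.n_iterations, 0.5, alternative="two-sided")
        p = float(res.pvalue)
        decision.hit_count[f] = int(hits[i])
        decision.p_value[f] = p
        if p < cfg.alpha and hits[i] > cfg.n_iterations / 2:
            decision.status[f] = "accepted"
        elif p < cfg.alpha and hits[i] < cfg.n_iterations / 2:
            decision.status[f] = "rejected"
        else:
            decision.status[f] = "tentative"
    return decision


def union_features(dec_cl: FeatureDecision, dec_vd: FeatureDecision) -> list[str]:
    """Union of accepted features, CL order first, then VD-only additions."""
    out = list(dec_cl.accepted)
    seen = set(out)
    for f in dec_vd.accepted:
        if f not in seen:
            out.append(f)
            seen.add(f)
    return out


class BorutaShapSelector(BaseEstimator):
    """Estimator front end: ``fit(X, y)`` runs the selection loop;
    ``get_support()`` / ``transform`` expose the accepted subset."""

    def __init__(self, n_iterations: int = 5000, shadow_percentile: float = 80.0,
                 max_depth: int = 5, alpha: float = 0.05, seed: int = 0,
                 n_estimators: int = 40, subsample_frac: float = 0.5,
                 feature_fraction: float = 0.7, importance_rows: int = 24,
                 background_rows: int = 16, shap_budget: int = 256):
        self.n_iterations = n_iterations
        self.shadow_percentile = shadow_percentile
        self.max_depth = max_depth
        self.alpha = alpha
        self.seed = seed
        self.n_estimators = n_estimators
        self.subsample_frac = subsample_frac
        self.feature_fraction = feature_fraction
        self.importance_rows = importance_rows
        self.background_rows = background_rows
        self.shap_budget = shap_budget

    def fit(self, X, y):
        cfg = SelectionConfig(
            n_iterations=self.n_iterations, shadow_percentile=self.shadow_percentile,
            max_depth=self.max_depth, alpha=self.alpha, seed=self.seed,
            n_estimators=self.n_estimators, subsample_frac=self.subsample_frac,
            feature_fraction=self.feature_fraction,
            importance_rows=self.importance_rows,
            background_rows=self.background_rows, shap_budget=self.shap_budget)
        self.decision_ = boruta_shap_select(X, y, cfg)
        self.support_ = np.array(
            [self.decision_.status[f] == "accepted"
             for f in self.decision_.feature_names])
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X[self.decision_.accepted]
        return np.asarray(X)[:, self.support_]
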