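"""Quantitative evaluation of PK predictions.

Error is reported on two scales: mean squared error of log1p-transformed
values (the scale the models are trained on) and geometric mean fold error
(GMFE) on the original scale,

    GMFE = 10 ** mean(|log10(pred / obs)|),

a symmetric fold-error measure with minimum 1 that penalizes over- and
under-prediction equally.  Model comparison uses the Diebold-Mariano test
on the squared-error differential (h = 1), VD-range stratification of GMFE,
and win-rate summaries over repeated random splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm


def _check_pair(pred, obs):
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.size == 0 or obs.size == 0:
        raise ValueError("empty input")
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have the same length")
    return pred, obs


def mse_log(pred, obs) -> float:
    """Mean squared error of log1p-transformed original-scale values."""
    pred, obs = _check_pair(pred, obs)
    return float(np.mean((np.log1p(pred) - np.log1p(obs)) ** 2))


def gmfe(pred, obs, clip: float = 1e-6) -> float:
    """Geometric mean fold error, base 10.  Nonpositive predictions are
    clipped to ``clip`` with a warning (observations must be positive)."""
    pred, obs = _check_pair(pred, obs)
    if np.any(obs <= 0):
        raise ValueError("observations must be strictly positive")
    if np.any(pred <= 0):
        warnings.warn("nonpositive predictions clipped for GMFE")
        pred = np.clip(pred, clip, None)
    return float(10.0 ** np.mean(np.abs(np.log10(pred / obs))))


def r_squared(pred, obs) -> float:
    """Coefficient of determination on the log1p scale (same residual scale
    as :func:`mse_log`).  Constant observations make R^2 undefined."""
    pred, obs = _check_pair(pred, obs)
    if pred.size < 2:
        raise ValueError("need at least 2 points")
    lp, lo = np.log1p(pred), np.log1p(obs)
    ss_tot = float(np.sum((lo - lo.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("constant observations: R^2 undefined")
    return 1.0 - float(np.sum((lo - lp) ** 2)) / ss_tot


@dataclass
class MetricsReport:
    """Per-target metric bundle on one evaluation partition."""

    mse_log: float
    gmfe: float
    r2: float
    n: int

    def to_dict(self) -> dict:
        return {"mse_log": self.mse_log, "gmfe": self.gmfe, "r2": self.r2, "n": self.n}


def metrics_report(pred, obs) -> MetricsReport:
    pred, obs = _check_pair(pred, obs)
    keep = ~np.isnan(obs)
    pred, obs = pred[keep], obs[keep]
    return MetricsReport(
        mse_log=mse_log(pred, obs),
        gmfe=gmfe(pred, obs),
        r2=r_squared(pred, obs),
        n=int(obs.size),
    )


@dataclass
class DMResult:
    """Diebold-Mariano equal-accuracy test on squared errors, horizon 1."""

    statistic: float
    p_value: float
    h: int
    n: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic, "p_value": self.p_value,
            "h": self.h, "n": self.n, "degenerate": self.degenerate,
        }


def dm_test(err_a, err_b, h: int = 1) -> DMResult:
    """DM test with MSE criterion: d_i = err_a_i^2 - err_b_i^2,
    statistic = mean(d) / sqrt(var(d)/n), two-tailed normal p-value.

    With h = 1 no autocovariance terms enter the long-run variance.  A
    zero-variance differential is flagged degenerate (p = 1 when d == 0).
    """
    err_a, err_b = _check_pair(err_a, err_b)
    n = err_a.size
    if n < 3:
        raise ValueError("need at least 3 points")
    d = err_a**2 - err_b**2
    gamma0 = float(np.mean((d - d.mean()) ** 2))
    if gamma0 == 0.0:
        if np.all(d == 0):
            return DMResult(0.0, 1.0, h, n, degenerate=True)
        return DMResult(float("nan"), float("nan"), h, n, degenerate=True)
    stat = float(d.mean() / np.sqrt(gamma0 / n))
    p = float(2.0 * norm.sf(abs(stat)))
    return DMResult(stat, p, h, n)


@dataclass
class StratifiedReport:
    """GMFE of two models within VD ranges (low <0.5, mid 0.5-2.0, high >2.0 L/kg)."""

    bins: dict = field(default_factory=dict)  # name -> {n, gmfe_a, gmfe_b, delta}
    n_total: int = 0
    n_missing: int = 0

    def to_dict(self) -> dict:
        return {"bins": self.bins, "n_total": self.n_total, "n_missing": self.n_missing}


def stratified_gmfe(pred_a, pred_b, obs_vd,
                    boundaries: tuple[float, float] = (0.5, 2.0)) -> StratifiedReport:
    """Per-VD-range GMFE comparison.

    Bins: low obs < boundaries[0]; mid boundaries[0] <= obs <= boundaries[1]
    (closed on both ends); high obs > boundaries[1].  Rows with missing
    observations are excluded and counted.
    """
    pred_a = np.asarray(pred_a, float)
    pred_b = np.asarray(pred_b, float)
    obs = np.asarray(obs_vd, float)
    lo, hi = boundaries
    missing = np.isnan(obs)
    report = StratifiedReport(n_total=int((~missing).sum()), n_missing=int(missing.sum()))
    masks = {
        "low": (~missing) & (obs < lo),
        "mid": (~missing) & (obs >= lo) & (obs <= hi),
        "high": (~missing) & (obs > hi),
    }
    for name, m in masks.items():
        if not m.any():
            report.bins[name] = {"n": 0, "gmfe_a": None, "gmfe_b": None, "delta": None}
            continue
        ga = gmfe(pred_a[m], obs[m])
        gb = gmfe(pred_b[m], obs[m])
        report.bins[name] = {"n": int(m.sum()), "gmfe_a": ga, "gmfe_b": gb,
                             "delta": ga - gb}
    return report


@dataclass
class RepeatedRunSummary:
    """Aggregate of per-run MSEs for two models over k repeated splits.

    A "win" is a run where model A's MSE is strictly lower than model B's.
    """

    k: int
    mean_a: float
    sd_a: float | None
    mean_b: float
    sd_b: float | None
    win_count: int
    win_rate: float
    mean_delta_wins: float | None
    mean_delta_losses: float | None

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def summarize_repeats(mse_a, mse_b) -> RepeatedRunSummary:
    """Summarize aligned per-run MSE vectors for models A and B."""
    mse_a = np.asarray(mse_a, float)
    mse_b = np.asarray(mse_b, float)
    if mse_a.size != mse_b.size or mse_a.size < 1:
        raise ValueError("need k >= 1 aligned runs")
    k = mse_a.size
    delta = mse_a - mse_b
    wins = delta < 0
    losses = ~wins
    sd = (lambda v: float(np.std(v, ddof=1))) if k > 1 else (lambda v: None)
    return RepeatedRunSummary(
        k=k,
        mean_a=float(mse_a.mean()), sd_a=sd(mse_a),
        mean_b=float(mse_b.mean()), sd_b=sd(mse_b),
        win_count=int(wins.sum()),
        win_rate=float(wins.sum() / k),
        mean_delta_wins=float(delta[wins].mean()) if wins.any() else None,
        mean_delta_losses=float(delta[losses].mean()) if losses.any() else None,
    )
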