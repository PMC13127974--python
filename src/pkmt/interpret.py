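"""Model-agnostic Shapley attribution with an exact small-dimension oracle.

The value function is interventional: features absent from a coalition are
replaced by background rows and the model output averaged over the
background.  Two estimators are provided:

* :func:`exact_shapley` — full enumeration over all 2^M coalitions
  (M <= 12), the reference implementation;
* :func:`kernel_shapley` — the weighted-least-squares estimator with
  Shapley kernel weights over an enumerated-plus-sampled coalition design,
  constrained so that attributions sum exactly to prediction minus base
  (local accuracy).  With a budget covering every nonempty proper coalition
  the estimate is exact.

Attribution summaries (top-k ranking, per-modality importance shares) are
also computed here.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class Attribution:
    """Shapley values for a batch of rows: phi[rows, features] + base value."""

    values: np.ndarray             # (n_rows, M)
    base_value: float              # mean model output over the background
    predictions: np.ndarray        # f(row) for each explained row
    feature_names: list[str] = field(default_factory=list)


def _coalition_values(model_fn, rows: np.ndarray, background: np.ndarray,
                      masks: np.ndarray) -> np.ndarray:
    """v[row, coalition] = mean_b f(x_S, b_notS) for each coalition mask."""
    n_rows, m = rows.shape
    n_bg = background.shape[0]
    n_co = masks.shape[0]
    # build (n_rows * n_co * n_bg, m) synthetic matrix in one batch
    big = np.broadcast_to(background, (n_rows, n_co, n_bg, m)).copy()
    rows_e = rows[:, None, None, :]
    masks_e = masks[None, :, None, :].astype(bool)
    big = np.where(masks_e, rows_e, big)
    preds = np.asarray(model_fn(big.reshape(-1, m)), float)
    return preds.reshape(n_rows, n_co, n_bg).mean(axis=2)


def exact_shapley(model_fn, rows, background, feature_names=None) -> Attribution:
    """Exact Shapley values by enumeration over all coalitions (M <= 12)."""
    rows = np.atleast_2d(np.asarray(rows, float))
    background = np.atleast_2d(np.asarray(background, float))
    m = rows.shape[1]
    if m > 12:
        raise ValueError("exact enumeration limited to M <= 12 features; "
                         "use kernel_shapley")
    masks = np.array(list(itertools.product([0, 1], repeat=m)), dtype=np.int8)
    v = _coalition_values(model_fn, rows, background, masks)
    sizes = masks.sum(axis=1)
    # index coalitions by bitmask for O(1) lookup of S vs S+{i}
    bit = masks @ (1 << np.arange(m))
    order = np.argsort(bit)
    v_by_bit = np.empty_like(v)
    v_by_bit[:, bit[order]] = v[:, order]

    fact = [math.factorial(i) for i in range(m + 1)]
    phi = np.zeros((rows.shape[0], m))
    for ci in range(masks.shape[0]):
        s = int(sizes[ci])
        if s == m:
            continue
        w = fact[s] * fact[m - s - 1] / fact[m]
        b = int(bit[ci])
        for i in range(m):
            if not masks[ci, i]:
                phi[:, i] += w * (v_by_bit[:, b | (1 << i)] - v_by_bit[:, b])
    # base value is v(empty set), identical for every row
    base = float(v_by_bit[:, 0].mean())
    preds = v_by_bit[:, (1 << m) - 1]
    return Attribution(values=phi, base_value=base, predictions=preds,
                       feature_names=list(feature_names or []))


def _kernel_design(m: int, budget: int, rng: np.random.Generator):
    """Enumerate complete coalition sizes while they fit the budget, then
    sample the remainder; returns (masks, kernel weights)."""
    sizes = np.arange(1, m)
    size_w = (m - 1) / (sizes * (m - sizes))          # kernel weight per size
    size_w = size_w / size_w.sum()
    counts = np.array([math.comb(m, int(s)) for s in sizes])

    masks: list[np.ndarray] = []
    weights: list[float] = []
    remaining = budget
    remaining_w = 1.0
    # pair sizes (s, m-s) from the outside in, as the weights decay inward
    order = sorted(range(len(sizes)), key=lambda i: min(sizes[i], m - sizes[i]))
    enumerated = np.zeros(len(sizes), bool)
    for i in order:
        s = int(sizes[i])
        if counts[i] <= remaining:
            for comb in itertools.combinations(range(m), s):
                mk = np.zeros(m, np.int8)
                mk[list(comb)] = 1
                masks.append(mk)
                weights.append(size_w[i] / counts[i])
            remaining -= counts[i]
            remaining_w -= size_w[i]
            enumerated[i] = True
        else:
            break
    left = ~enumerated
    if remaining > 0 and left.any() and remaining_w > 1e-12:
        p = size_w[left] / size_w[left].sum()
        ss = rng.choice(sizes[left], size=remaining, p=p)
        for s in ss:
            idx = rng.choice(m, size=int(s), replace=False)
            mk = np.zeros(m, np.int8)
            mk[idx] = 1
            masks.append(mk)
            weights.append(remaining_w / remaining)
    return np.array(masks, np.int8), np.array(weights, float)


def kernel_shapley(model_fn, rows, background, budget: int = 2048,
                   seed: int = 0, feature_names=None) -> Attribution:
    """Kernel-weighted least-squares Shapley estimator.

    ``budget`` counts nonempty proper coalitions in the design (the empty
    and full coalitions are handled by the local-accuracy constraint).
    Requires budget >= 2*M + 2.  Deterministic given ``seed``.
    """
    rows = np.atleast_2d(np.asarray(rows, float))
    background = np.atleast_2d(np.asarray(background, float))
    m = rows.shape[1]
    if budget < 2 * m + 2:
        raise ValueError("budget must be at least 2*M + 2")
    rng = np.random.default_rng(seed)
    masks, w = _kernel_design(m, budget, rng)

    full = np.ones((1, m), np.int8)
    empty = np.zeros((1, m), np.int8)
    v_all = _coalition_values(model_fn, rows, background,
                              np.vstack([empty, full, masks]))
    base = float(v_all[:, 0].mean())
    preds = v_all[:, 1]
    v = v_all[:, 2:]

    # constrained WLS: eliminate the last feature via sum(phi) = f(x) - base
    z = masks.astype(float)
    z_last = z[:, -1]
    a = z[:, :-1] - z_last[:, None]
    sw = np.sqrt(w)
    phi = np.zeros((rows.shape[0], m))
    for r in range(rows.shape[0]):
        gap = preds[r] - base
        y = v[r] - base - z_last * gap
        try:
            sol, *_ = np.linalg.lstsq(a * sw[:, None], y * sw, rcond=None)
            if not np.all(np.isfinite(sol)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            warnings.warn("singular kernel design: ridge fallback")
            ata = (a * w[:, None]).T @ a + 1e-8 * np.eye(m - 1)
            sol = np.linalg.solve(ata, (a * w[:, None]).T @ y)
        phi[r, :-1] = sol
        phi[r, -1] = gap - sol.sum()
    return Attribution(values=phi, base_value=base, predictions=preds,
                       feature_names=list(feature_names or []))


def summarize_attributions(attr: Attribution, feature_modalities: dict[str, str],
                           top_k: int = 10) -> dict:
    """Mean-|phi| ranking and modality shares over the top-k features.

    ``feature_modalities`` must map every feature to one of
    {'preclinical_pk', 'physicochemical', 'embedding_cnn', 'embedding_mlp'}.
    Shares are each modality's fraction of the summed top-k mean |phi|.
    """
    names = attr.feature_names or [f"f{i}" for i in range(attr.values.shape[1])]
    for nm in names:
        if nm not in feature_modalities:
            raise ValueError(f"feature '{nm}' has no modality mapping")
    mean_abs = np.abs(attr.values).mean(axis=0)
    order = np.argsort(-mean_abs, kind="stable")[:top_k]
    top = [{"feature": names[i], "mean_abs_shap": float(mean_abs[i]),
            "modality": feature_modalities[names[i]]} for i in order]
    total = float(mean_abs[order].sum())
    shares: dict[str, float] = {}
    for row in top:
        shares[row["modality"]] = shares.get(row["modality"], 0.0) + row["mean_abs_shap"]
    if total > 0:
        shares = {k: v / total for k, v in shares.items()}
    return {"ranking": top, "modality_shares": shares, "top_k": len(top)}
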