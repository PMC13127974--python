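"""Supervised 2-d molecular embeddings from images (CNN) and descriptors (MLP).

Each embedder is a small regression network trained against one endpoint
(CL or VD) on the model scale; the penultimate layer is a 2-unit linear
bottleneck whose activations are the embedding.  Training follows a
three-step protocol in which the test partition is never touched:

1. hyperparameter search (seeded random search over learning rate, dropout,
   batch size and architecture width/depth), each candidate trained on the
   training partition with early stopping on the validation partition;
2. final refit on train+validation with the selected configuration, early
   stopping again monitored on the validation partition;
3. embedding extraction in inference mode (dropout off, no updates) for
   any rows, including test rows.

Embedding columns follow the ``cnn_vec{1,2}_{CL|VD}`` /
``mlp_vec{1,2}_{CL|VD}`` naming convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .nn import Conv3x3, Dense, Dropout, GlobalAvgPool, Network, ReLU


@dataclass
class HPOBudget:
    """Search budget and ranges for embedder hyperparameter optimization."""

    n_trials: int = 100
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0
    lr_range: tuple[float, float] = (1e-5, 1e-2)
    dropout_range: tuple[float, float] = (0.0, 0.5)
    batch_sizes: tuple[int, ...] = (8, 16, 32, 64)
    hidden_layers_range: tuple[int, int] = (1, 3)      # MLP only
    hidden_units_range: tuple[int, int] = (32, 256)    # MLP only


class _EmbedderMixin:
    """Shared fit/extract logic over a Network built by ``_build``."""

    def _fit_net(self, X, y, X_val, y_val):
        rng = np.random.default_rng(self.seed)
        self.net_ = self._build(rng)
        self.net_.fit(X, y, X_val, y_val, epochs=self.max_epochs,
                      batch_size=self.batch_size, lr=self.learning_rate,
                      patience=self.patience)
        self.best_val_loss_ = self.net_.best_val_loss_
        return self

    def transform(self, X) -> np.ndarray:
        """2-d bottleneck activations in inference mode."""
        if not hasattr(self, "net_"):
            raise ValueError("embedder not fitted")
        out = self.net_.forward(self._prepare(X), train=False,
                                upto=self._bottleneck_index)
        assert out.shape[1] == 2
        return out

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise ValueError("embedder not fitted")
        return self.net_.forward(self._prepare(X), train=False).ravel()


class MLPEmbedder(_EmbedderMixin, TransformerMixin, BaseEstimator):
    """Descriptor-vector regressor with a linear 2-d bottleneck.

    Architecture: [Dense-ReLU-Dropout] x n_hidden -> Dense(2, linear)
    -> Dense(1).  ``transform`` returns the bottleneck activations.
    """

    def __init__(self, hidden_units=(64,), dropout: float = 0.1,
                 learning_rate: float = 1e-3, batch_size: int = 32,
                 max_epochs: int = 200, patience: int = 10, seed: int = 0):
        self.hidden_units = hidden_units
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed

    def _prepare(self, X):
        return np.asarray(X, float)

    def _build(self, rng):
        layers = []
        n_in = self.n_features_in_
        for units in self.hidden_units:
            layers += [Dense(n_in, units, rng), ReLU()]
            if self.dropout > 0:
                layers.append(Dropout(self.dropout, rng))
            n_in = units
        layers.append(Dense(n_in, 2, rng))       # linear bottleneck
        self._bottleneck_index = len(layers)
        layers.append(Dense(2, 1, rng))
        return Network(layers, rng)

    def fit(self, X, y, eval_set=None):
        X = self._prepare(X)
        self.n_features_in_ = X.shape[1]
        X_val, y_val = eval_set if eval_set is not None else (None, None)
        if X_val is not None:
            X_val = self._prepare(X_val)
        return self._fit_net(X, y, X_val, y_val)


class CNNEmbedder(_EmbedderMixin, TransformerMixin, BaseEstimator):
    """Molecular-image regressor with a linear 2-d bottleneck.

    A strided residual-free convolutional stack ending in global average
    pooling, then Dense(2, linear) -> Dropout -> Dense(1).  The default
    ``channels`` is a tiny CPU profile; deeper stacks (e.g. ending at 512
    features) are configuration-selectable.
    """

    def __init__(self, channels=(8, 16, 32), dropout: float = 0.1,
                 learning_rate: float = 1e-3, batch_size: int = 32,
                 max_epochs: int = 60, patience: int = 8, seed: int = 0):
        self.channels = channels
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed

    def _prepare(self, X):
        X = np.asarray(X, float)
        if X.ndim != 4:
            raise ValueError("CNN input must be (n, H, W, 3) images")
        return 1.0 - X.transpose(0, 3, 1, 2)  # NCHW; invert: molecule > 0

    def _build(self, rng):
        layers = []
        c_in = 3
        for c_out in self.channels:
            layers += [Conv3x3(c_in, c_out, stride=2, rng=rng), ReLU()]
            c_in = c_out
        layers.append(GlobalAvgPool())
        layers.append(Dense(c_in, 2, rng))       # linear bottleneck
        self._bottleneck_index = len(layers)
        if self.dropout > 0:
            layers.append(Dropout(self.dropout, rng))
        layers.append(Dense(2, 1, rng))
        return Network(layers, rng)

    def fit(self, X, y, eval_set=None):
        X = self._prepare(X)
        X_val, y_val = eval_set if eval_set is not None else (None, None)
        if X_val is not None:
            X_val = self._prepare(X_val)
        self.n_features_in_ = X.shape[1:]
        return self._fit_net(X, y, X_val, y_val)


@dataclass
class EmbeddingModel:
    """A trained embedder plus the record of its hyperparameter search."""

    kind: str                    # 'cnn' | 'mlp'
    target: str                  # 'CL' | 'VD'
    estimator: object
    hpo_record: dict = field(default_factory=dict)

    @property
    def column_names(self) -> list[str]:
        return [f"{self.kind}_vec{i}_{self.target}" for i in (1, 2)]


def _sample_params(kind: str, budget: HPOBudget, rng: np.random.Generator) -> dict:
    lo, hi = budget.lr_range
    params = {
        "learning_rate": float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
        "dropout": float(rng.uniform(*budget.dropout_range)),
        "batch_size": int(rng.choice(budget.batch_sizes)),
        "max_epochs": budget.max_epochs,
        "patience": budget.patience,
    }
    if kind == "mlp":
        n_layers = int(rng.integers(budget.hidden_layers_range[0],
                                    budget.hidden_layers_range[1] + 1))
        params["hidden_units"] = tuple(
            int(rng.integers(budget.hidden_units_range[0],
                             budget.hidden_units_range[1] + 1))
            for _ in range(n_layers))
    return params


def train_embedder(kind: str, target: str, X_train, y_train, X_val, y_val,
                   budget: HPOBudget | None = None, seed: int = 0,
                   cnn_channels=(8, 16, 32)) -> EmbeddingModel:
    """Three-step supervised embedding training (search, refit, ready to extract).

    ``X_*`` are descriptor matrices for ``kind='mlp'`` or image stacks for
    ``kind='cnn'``; ``y_*`` are model-scale targets with no missing values.
    The validation partition drives both hyperparameter selection and the
    early stopping of the final train+validation refit.
    """
    if kind not in ("cnn", "mlp"):
        raise ValueError("kind must be 'cnn' or 'mlp'")
    if X_val is None or len(X_val) == 0:
        raise ValueError("validation partition must be nonempty")
    budget = budget or HPOBudget()
    rng = np.random.default_rng(seed)

    def make(params, est_seed):
        common = dict(params)
        if kind == "cnn":
            return CNNEmbedder(channels=cnn_channels, seed=est_seed, **common)
        return MLPEmbedder(seed=est_seed, **common)

    trials = []
    best_params, best_loss = None, np.inf
    for t in range(budget.n_trials):
        params = _sample_params(kind, budget, rng)
        est = make(params, est_seed=budget.seed + t)
        est.fit(X_train, y_train, eval_set=(X_val, y_val))
        loss = est.best_val_loss_
        trials.append({"params": params, "val_loss": float(loss)})
        if loss < best_loss:
            best_loss, best_params = loss, params

    X_full = np.concatenate([X_train, X_val])
    y_full = np.concatenate([np.asarray(y_train, float), np.asarray(y_val, float)])
    final = make(best_params, est_seed=budget.seed + budget.n_trials)
    final.fit(X_full, y_full, eval_set=(X_val, y_val))
    return EmbeddingModel(
        kind=kind, target=target, estimator=final,
        hpo_record={"n_trials": budget.n_trials, "trials": trials,
                    "chosen": best_params, "best_val_loss": float(best_loss)})


def extract_embeddings(model: EmbeddingModel, X) -> np.ndarray:
    """2-d embeddings for ``X`` in inference mode; weights untouched."""
    before = model.estimator.net_.weight_hash()
    out = model.estimator.transform(X)
    assert model.estimator.net_.weight_hash() == before
    return out
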