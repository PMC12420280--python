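"""Scikit-learn estimator wrapping the CDR3 recognition network.

:class:`DeepCaTCRClassifier` follows the sklearn estimator contract: all
hyperparameters are constructor arguments, ``fit`` learns from encoded
sequences (or raw CDR3 strings when a projection is supplied), fitted state
lives in trailing-underscore attributes, and ``get_params``/``set_params``
come from :class:`sklearn.base.BaseEstimator`, so the estimator composes
with pipelines and model selection.

Training follows the published protocol: stratified 80/20 train/validation
split, Adam at learning rate 0.001, cross-entropy loss, dropout 0.5 on the
hidden layer, at most 1000 epochs with early stopping after 20 epochs
without validation-loss improvement; the parameters from the best-validation
epoch are kept.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted

from ._autodiff import Adam, Tensor
from .network import (ModelConfig, batch_loss, forward, init_parameters,
                      motif_importance)
from .encoding import AminoAcidProjection, encode_cdr3

__all__ = ["DeepCaTCRClassifier", "TrainConfig", "cross_validate"]


@dataclass
class TrainConfig:
    """Optimisation settings (defaults follow the published protocol)."""

    learning_rate: float = 1e-3
    max_epochs: int = 1000
    patience: int = 20
    batch_size: int = 512
    val_fraction: float = 0.2
    n_folds: int = 5
    seed: int = 0
    min_improvement: float = 1e-6

    def __post_init__(self):
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


class DeepCaTCRClassifier(ClassifierMixin, BaseEstimator):
    """Multi-scale conv / k-max pooling / MHSA / BiLSTM CDR3 classifier.

    Parameters mirror :class:`deepcatcr.network.ModelConfig` and
    :class:`TrainConfig`; ``use_bilstm=False`` and/or ``use_mhsa=False``
    give the ablated variants.

    Attributes (after ``fit``)
    --------------------------
    params_ : dict of named weight tensors (best-validation epoch)
    config_ : the resolved ModelConfig
    history_ : list of per-epoch dicts (epoch, train_loss, val_loss)
    best_epoch_, best_val_loss_ : early-stopping bookkeeping
    classes_ : array([0, 1])
    """

    def __init__(
        self,
        kernel_heights=(2, 3, 4, 5),
        filters_per_height: int = 4,
        k_pool: int = 3,
        attn_heads: int = 2,
        attn_hidden: int = 4,
        lstm_hidden: int = 8,
        fc_units: int = 6,
        dropout: float = 0.5,
        use_bilstm: bool = True,
        use_mhsa: bool = True,
        value_projection: bool = True,
        learning_rate: float = 1e-3,
        max_epochs: int = 1000,
        patience: int = 20,
        batch_size: int = 512,
        val_fraction: float = 0.2,
        random_state: int = 0,
        projection: AminoAcidProjection | None = None,
    ):
        self.kernel_heights = kernel_heights
        self.filters_per_height = filters_per_height
        self.k_pool = k_pool
        self.attn_heads = attn_heads
        self.attn_hidden = attn_hidden
        self.lstm_hidden = lstm_hidden
        self.fc_units = fc_units
        self.dropout = dropout
        self.use_bilstm = use_bilstm
        self.use_mhsa = use_mhsa
        self.value_projection = value_projection
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.random_state = random_state
        self.projection = projection

    # ------------------------------------------------------------------
    def _model_config(self, encoding_dim: int) -> ModelConfig:
        return ModelConfig(
            kernel_heights=tuple(self.kernel_heights),
            filters_per_height=self.filters_per_height,
            kernel_width=encoding_dim,
            k_pool=self.k_pool,
            attn_heads=self.attn_heads,
            attn_hidden=self.attn_hidden,
            lstm_hidden=self.lstm_hidden,
            fc_units=self.fc_units,
            dropout=self.dropout,
            use_bilstm=self.use_bilstm,
            use_mhsa=self.use_mhsa,
            value_projection=self.value_projection,
        )

    def _as_matrix(self, X) -> np.ndarray:
        """Accept (n, 20, d) arrays, or CDR3 strings when a projection is set."""
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return np.asarray(X, dtype=np.float64)
        if len(X) and isinstance(X[0], str):
            if self.projection is None:
                raise ValueError(
                    "string input requires the `projection` parameter "
                    "(or pre-encode with CDR3Encoder)")
            return np.stack(
                [encode_cdr3(s, self.projection).matrix for s in X])
        return np.asarray(X, dtype=np.float64)

    # ------------------------------------------------------------------
    def fit(self, X, y):
        X = self._as_matrix(X)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data must contain both classes")
        if not set(classes) <= {0, 1}:
            raise ValueError("labels must be in {0, 1}")
        self.classes_ = np.array([0, 1])
        config = self._model_config(X.shape[2])
        rng = np.random.default_rng(self.random_state)
        params = init_parameters(config, rng)

        X_tr, X_val, y_tr, y_val = train_test_split(
            X, y, test_size=self.val_fraction, stratify=y,
            random_state=self.random_state)

        optimizer = Adam(params, lr=self.learning_rate)
        best_loss = np.inf
        best_params = None
        best_epoch = -1
        stale = 0
        history: list[dict] = []
        n = len(X_tr)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            train_losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                loss = batch_loss(Tensor(X_tr[idx]), y_tr[idx], params, config,
                                  train=True, rng=rng)
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"non-finite training loss at epoch {epoch}")
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                train_losses.append(float(loss.data) * len(idx))
            val_loss = float(batch_loss(Tensor(X_val), y_val, params, config,
                                        train=False).data)
            if not np.isfinite(val_loss):
                raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
            history.append({
                "epoch": epoch,
                "train_loss": sum(train_losses) / n,
                "val_loss": val_loss,
            })
            if val_loss < best_loss - TrainConfig.min_improvement:
                best_loss = val_loss
                best_epoch = epoch
                best_params = {k: p.data.copy() for k, p in params.items()}
                stale = 0
            else:
                stale += 1
                if stale > self.patience:
                    break
        if best_params is None:  # patience 0 and first epoch did not improve inf
            best_params = {k: p.data.copy() for k, p in params.items()}
            best_epoch = history[-1]["epoch"] if history else 0
        self.params_ = {k: Tensor(v, requires_grad=True)
                        for k, v in best_params.items()}
        self.config_ = config
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = best_loss
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    # ------------------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = self._as_matrix(X)
        out = np.empty((len(X), 2))
        for start in range(0, len(X), 4096):  # bound peak memory
            chunk = X[start:start + 4096]
            out[start:start + len(chunk)] = forward(
                chunk, self.params_, self.config_, train=False).data
        return out

    def decision_function(self, X) -> np.ndarray:
        """Cancer-class probability f(TCR) for each sequence."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.decision_function(X) >= threshold).astype(int)

    def motif_importance(self, sequence: str, projection=None, **kw):
        check_is_fitted(self, "params_")
        proj = projection if projection is not None else self.projection
        if proj is None:
            raise ValueError("motif_importance needs a projection")
        return motif_importance(sequence, self.params_, self.config_, proj, **kw)

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Serialize parameters + config as a versioned JSON checkpoint."""
        check_is_fitted(self, "params_")
        payload = {
            "format_version": 1,
            "config": self.config_.to_dict(),
            "estimator_params": {
                k: v for k, v in self.get_params().items() if k != "projection"},
            "weights": {k: v.data.tolist() for k, v in self.params_.items()},
            "best_epoch": self.best_epoch_,
            "best_val_loss": self.best_val_loss_,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path,
             projection: AminoAcidProjection | None = None) -> "DeepCaTCRClassifier":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != 1:
            raise ValueError(f"unsupported checkpoint version in {path}")
        est = cls(projection=projection, **payload["estimator_params"])
        est.config_ = ModelConfig.from_dict(payload["config"])
        est.params_ = {k: Tensor(np.asarray(v), requires_grad=True)
                       for k, v in payload["weights"].items()}
        est.classes_ = np.array([0, 1])
        est.history_ = []
        est.best_epoch_ = payload.get("best_epoch", -1)
        est.best_val_loss_ = payload.get("best_val_loss", float("nan"))
        return est


def cross_validate(X, y, estimator: DeepCaTCRClassifier | None = None,
                   n_folds: int = 5, random_state: int = 0,
                   threshold: float = 0.5):
    """Stratified k-fold cross-validation with per-fold metric reports.

    Each fold trains an independent clone of ``estimator`` from fresh
    initialization and evaluates on the held-out fold.  Returns
    ``(per_fold_reports, summary)`` where summary maps each metric to
    ``(mean, sd)``.
    """
    from .metrics import compute_metrics  # local import to avoid a cycle

    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    base = estimator if estimator is not None else DeepCaTCRClassifier()
    X = base._as_matrix(X)
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=random_state)
    reports = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {fold} contains a single class")
        est = copy.deepcopy(base)
        est.set_params(random_state=random_state + fold)
        est.fit(X[tr], y[tr])
        scores = est.decision_function(X[te])
        report = compute_metrics(y[te], scores, threshold=threshold)
        report["fold"] = fold
        reports.append(report)
    metric_names = [k for k in reports[0] if k not in
                    ("fold", "TP", "TN", "FP", "FN")]
    summary = {
        m: (float(np.mean([r[m] for r in reports])),
            float(np.std([r[m] for r in reports])))
        for m in metric_names
    }
    return reports, summary
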