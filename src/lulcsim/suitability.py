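"""Multinomial suitability modelling and autoregressive projection.

A probabilistic classifier maps each cell's feature vector (three lagged
class codes, neighbourhood composition, environmental predictors) to a
probability simplex over the modelled classes; the per-class probabilities,
mapped back onto the grid, are the suitability layers consumed by the
allocator.

The default backend is a feed-forward network: five densely connected ReLU
hidden layers and a softmax output, trained with an adaptive-moment
optimiser, a 0.2 validation split and early stopping once validation loss
plateaus.  Any estimator exposing ``fit``/``predict_proba`` and satisfying
the simplex contract can be plugged in; a multinomial-logistic backend is
provided for fast tests.

Projection is autoregressive: to forecast step t+1, the LULC-derived
features are recomputed from the (t-2, t-1, t0) history — observed maps or
previously allocated forecasts — while time-varying predictors can be
substituted and all other predictors stay fixed.  The feature schema is
frozen at training time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

from .features import FeaturePipeline, assemble_features
from .raster_io import Grid, LULCMap, PredictorLayer, PredictorStack
from .sampling import TrainingTable

__all__ = [
    "ModelSpec",
    "TrainingHistory",
    "SuitabilityStack",
    "SuitabilityModel",
    "train",
    "predict_suitability",
    "project_step",
]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and training configuration of the suitability classifier.

    ``hidden_sizes`` must name exactly five hidden layers for the network
    backend (tapered 256-128-64-32-16 by default).  ``dropout_rate`` is the
    nominal between-layer dropout of the reference architecture; the
    scikit-learn network backend has no dropout layers, so regularisation is
    carried by ``alpha`` (L2) and early stopping instead.
    """

    hidden_sizes: tuple[int, ...] = (256, 128, 64, 32, 16)
    dropout_rate: float = 0.2
    validation_split: float = 0.2
    max_epochs: int = 200
    batch_size: int = 256
    patience: int = 10
    alpha: float = 1e-4
    backend: str = "mlp"  # "mlp" | "logistic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("mlp", "logistic"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.backend == "mlp" and len(self.hidden_sizes) != 5:
            raise ValueError("the network backend uses exactly five hidden layers")
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if not 0 < self.validation_split < 1:
            raise ValueError("validation_split must be in (0, 1)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class TrainingHistory:
    """Per-epoch loss and validation accuracy of a completed training run."""

    loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.loss) != len(self.val_accuracy):
            raise ValueError("history series must share the epoch count")

    @property
    def n_epochs(self) -> int:
        return len(self.loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, self.n_epochs + 1),
            "loss": self.loss,
            "val_accuracy": self.val_accuracy,
        })


@dataclass
class SuitabilityStack:
    """Per-class membership-probability layers on one grid.

    ``probs`` has shape (n_classes, n_rows, n_cols) and holds NaN outside
    the cells the model scored; on scored cells the class axis sums to 1.
    """

    grid: Grid
    class_ids: tuple[int, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.class_ids), *self.grid.shape):
            raise ValueError("probs shape must be (n_classes, n_rows, n_cols)")

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.probs[0])

    def check_simplex(self, atol: float = 1e-6) -> None:
        m = self.valid_mask
        vals = self.probs[:, m]
        if vals.size == 0:
            return
        if (vals < -atol).any() or (vals > 1 + atol).any():
            raise ValueError("suitability values outside [0, 1]")
        sums = vals.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=atol):
            raise ValueError("per-cell suitability does not sum to 1")

    def layer(self, class_id: int) -> np.ndarray:
        return self.probs[self.class_ids.index(class_id)]


@dataclass
class SuitabilityModel:
    """Trained classifier plus its frozen feature schema and class space."""

    estimator: object
    pipeline: FeaturePipeline
    class_ids: tuple[int, ...]  # full modelled-class space, ascending
    window_cells: int
    spec: ModelSpec

    def predict_table(self, raw_table: pd.DataFrame) -> np.ndarray:
        """Probability matrix over ``class_ids`` for raw (pre-encoding) rows."""
        missing = (set(self.pipeline.continuous_cols)
                   | set(self.pipeline.categorical_cols)) - set(raw_table.columns)
        if missing:
            raise ValueError(f"feature schema mismatch: missing columns {sorted(missing)}")
        X = self.pipeline.transform(raw_table).to_numpy()
        p = self.estimator.predict_proba(X)
        out = np.zeros((len(raw_table), len(self.class_ids)))
        seen = list(getattr(self.estimator, "classes_"))
        for j, cid in enumerate(seen):
            out[:, self.class_ids.index(int(cid))] = p[:, j]
        return out


def _fit_mlp(X: np.ndarray, y: np.ndarray, spec: ModelSpec):
    est = MLPClassifier(
        hidden_layer_sizes=spec.hidden_sizes,
        activation="relu",
        solver="adam",
        alpha=spec.alpha,
        batch_size=min(spec.batch_size,
                       max(1, int(len(X) * (1 - spec.validation_split)))),
        max_iter=spec.max_epochs,
        early_stopping=True,
        validation_fraction=spec.validation_split,
        n_iter_no_change=spec.patience,
        random_state=spec.seed,
    )
    est.fit(X, y)
    history = TrainingHistory(
        loss=[float(v) for v in est.loss_curve_],
        val_accuracy=[float(v) for v in est.validation_scores_],
    )
    return est, history


def _fit_logistic(X: np.ndarray, y: np.ndarray, spec: ModelSpec):
    Xt, Xv, yt, yv = train_test_split(
        X, y, test_size=spec.validation_split, random_state=spec.seed, stratify=y
    )
    est = LogisticRegression(max_iter=2000)
    est.fit(Xt, yt)
    loss = float(log_loss(yt, est.predict_proba(Xt), labels=est.classes_))
    val_acc = float(np.mean(est.predict(Xv) == yv))
    return est, TrainingHistory(loss=[loss], val_accuracy=[val_acc])


def train(
    table: TrainingTable,
    spec: ModelSpec = ModelSpec(),
    *,
    pipeline: FeaturePipeline | None = None,
    class_ids: Sequence[int] | None = None,
    window_cells: int = 5,
) -> tuple[SuitabilityModel, TrainingHistory]:
    """Fit the suitability classifier on a (balanced, augmented) sample.

    The feature pipeline — correlation filter, standardisation, one-hot
    schema — is fitted here on the training rows and frozen for all later
    projection steps.
    """
    if pipeline is None:
        pipeline = FeaturePipeline().fit(
            table.features, table.continuous_cols, table.categorical_cols,
            table.change_flag.to_numpy(),
        )
    X = pipeline.transform(table.features).to_numpy()
    y = table.response.to_numpy()
    if class_ids is None:
        class_ids = tuple(sorted(np.unique(y).astype(int)))
    else:
        class_ids = tuple(sorted(int(c) for c in class_ids))
    if spec.backend == "mlp":
        est, history = _fit_mlp(X, y, spec)
    else:
        est, history = _fit_logistic(X, y, spec)
    model = SuitabilityModel(est, pipeline, class_ids, window_cells, spec)
    return model, history


def predict_suitability(
    model: SuitabilityModel,
    history: Sequence[LULCMap],
    predictors: PredictorStack,
) -> SuitabilityStack:
    """Score every dynamic cell of the current map; nodata propagates as NaN."""
    table, meta = assemble_features(history, predictors, model.window_cells)
    probs_flat = model.predict_table(table)
    t0 = history[-1]
    probs = np.full((len(model.class_ids), *t0.grid.shape), np.nan)
    probs[:, meta["rows"], meta["cols"]] = probs_flat.T
    stack = SuitabilityStack(t0.grid, model.class_ids, probs)
    stack.check_simplex()
    return stack


def project_step(
    model: SuitabilityModel,
    lulc_history: Sequence[LULCMap],
    static_predictors: PredictorStack,
    timestep_predictors: Sequence[PredictorLayer] | None = None,
) -> SuitabilityStack:
    """Suitability for t+1 from the (t-2, t-1, t0) history.

    LULC-derived features are recomputed from the supplied history;
    ``timestep_predictors`` (e.g. climate layers for the target period)
    replace same-named layers of the static stack; everything else is
    unchanged.
    """
    if len(lulc_history) != 3:
        raise ValueError("lulc_history must contain exactly 3 maps")
    stack = static_predictors
    if timestep_predictors:
        stack = PredictorStack(static_predictors.grid,
                               dict(static_predictors.layers))
        for layer in timestep_predictors:
            if layer.name not in stack.layers:
                raise ValueError(f"unknown time-step predictor {layer.name!r}")
            stack.add(layer)
    return predict_suitability(model, lulc_history, stack)
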