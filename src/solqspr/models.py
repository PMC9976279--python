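"""Descriptor-based regressors: Random Forest and a fixed-shape dense net.

The Random Forest is a scikit-learn ``RandomForestRegressor``; the neural
network is a feed-forward net with three densely connected hidden layers of
strictly decreasing width, ReLU activations, the Adam optimizer and a
mean-squared-error loss (scikit-learn ``MLPRegressor``).  Features for the
network are standardized with statistics learned from the training matrix
only; the scaler travels with the fitted model so prediction accepts raw
descriptor matrices.  Gini importances (mean impurity decrease) are exposed
for the forest family only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor

from .features import FeatureMatrix, Scaler, apply_scaler, fit_scaler

__all__ = ["ModelSpec", "FittedModel", "fit", "predict", "gini_importances",
           "save_model", "load_model", "DEFAULT_GRIDS"]

_BUNDLE_VERSION = 1

#: Default hyperparameter grids, overridable through configuration.
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "rf": [
        {"n_trees": nt, "max_features": mf, "min_samples_leaf": msl}
        for nt in (100, 500)
        for mf in ("sqrt", 0.3333333333333333, 1.0)
        for msl in (1, 3)
    ],
    "nn": [
        {"widths": w, "learning_rate": lr}
        for w in ((256, 128, 64), (128, 64, 32))
        for lr in (1e-3, 1e-4)
    ],
}


@dataclass(frozen=True)
class ModelSpec:
    """Model family plus hyperparameters and a seed.

    rf params: ``n_trees``, ``max_depth``, ``min_samples_leaf``,
    ``max_features``.  nn params: ``widths`` (three strictly decreasing
    hidden-layer widths), ``learning_rate``, ``batch_size``, ``epochs``.
    """

    family: str
    params: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("rf", "nn"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.family == "nn":
            w = tuple(self.params.get("widths", (256, 128, 64)))
            if len(w) != 3 or not (w[0] > w[1] > w[2] > 0):
                raise ValueError(f"nn widths must be 3 strictly decreasing positive ints, got {w}")
        for k, v in self.params.items():
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v is not None and v <= 0:
                raise ValueError(f"hyperparameter {k}={v} must be positive")

    def with_params(self, params: Mapping[str, object]) -> "ModelSpec":
        return ModelSpec(self.family, {**self.params, **params}, self.seed)


@dataclass
class FittedModel:
    """A trained regressor bound to the descriptor columns it was fit on."""

    spec: ModelSpec
    estimator: object
    columns: tuple[str, ...]
    scaler: Optional[Scaler] = None
    meta: dict = field(default_factory=dict)


def _build_estimator(spec: ModelSpec):
    p = dict(spec.params)
    if spec.family == "rf":
        return RandomForestRegressor(
            n_estimators=int(p.get("n_trees", 500)),
            max_depth=p.get("max_depth"),
            min_samples_leaf=int(p.get("min_samples_leaf", 1)),
            max_features=p.get("max_features", 1.0),
            bootstrap=bool(p.get("bootstrap", True)),
            random_state=spec.seed,
            n_jobs=1,
        )
    widths = tuple(int(w) for w in p.get("widths", (256, 128, 64)))
    return MLPRegressor(
        hidden_layer_sizes=widths,
        activation="relu",
        solver="adam",
        learning_rate_init=float(p.get("learning_rate", 1e-3)),
        batch_size=int(p.get("batch_size", 32)),
        max_iter=int(p.get("epochs", 200)),
        early_stopping=True,
        n_iter_no_change=20,
        validation_fraction=0.1,
        random_state=spec.seed,
    )


def fit(spec: ModelSpec, X: FeatureMatrix, y: Sequence[float]) -> FittedModel:
    """Train a model; deterministic for a fixed seed.

    For the nn family a standard scaler is fit on ``X`` (training data
    only) and stored with the model.
    """
    y = np.asarray(y, dtype=float)
    if X.n_molecules != y.shape[0]:
        raise ValueError(f"{X.n_molecules} rows but {y.shape[0]} targets")
    if X.n_molecules < 2:
        raise ValueError("need at least 2 training rows")
    if not np.isfinite(y).all():
        raise ValueError("non-finite target values")

    scaler = None
    Xt = X
    if spec.family == "nn":
        scaler = fit_scaler(X)
        Xt = apply_scaler(scaler, X)
    est = _build_estimator(spec)
    est.fit(Xt.values, y)
    return FittedModel(spec=spec, estimator=est, columns=tuple(Xt.names) if spec.family == "nn" else tuple(X.names), scaler=scaler)


def predict(model: FittedModel, X: FeatureMatrix) -> np.ndarray:
    """Predict log(S) for a matrix with the model's training columns."""
    if model.scaler is not None:
        X = apply_scaler(model.scaler, X)
        names = tuple(model.scaler.names)
    else:
        names = tuple(X.names)
    missing = [c for c in model.columns if c not in names]
    extra = [c for c in names if c not in model.columns]
    if missing or extra:
        raise ValueError(f"column mismatch: missing {missing}, unexpected {extra}")
    if names != model.columns:
        idx = [names.index(c) for c in model.columns]
        vals = X.values[:, idx]
    else:
        vals = X.values
    out = np.asarray(model.estimator.predict(vals), dtype=float)
    if not np.isfinite(out).all():
        raise RuntimeError("model produced non-finite predictions")
    return out


def gini_importances(model: FittedModel) -> list[tuple[str, float]]:
    """Ranked (descriptor, Gini importance) pairs; forest family only.

    Importances are the mean impurity decrease over trees, normalized to
    sum to 1, sorted descending.
    """
    if model.spec.family != "rf":
        raise ValueError("Gini importances are defined only for the rf family")
    imp = np.asarray(model.estimator.feature_importances_, dtype=float)
    pairs = sorted(zip(model.columns, imp), key=lambda t: -t[1])
    return [(n, float(v)) for n, v in pairs]


def save_model(model: FittedModel, path) -> None:
    """Write a versioned on-disk bundle (meta.json + estimator state)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "bundle_version": _BUNDLE_VERSION,
        "family": model.spec.family,
        "params": {k: (list(v) if isinstance(v, tuple) else v) for k, v in model.spec.params.items()},
        "seed": model.spec.seed,
        "columns": list(model.columns),
        "meta": model.meta,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    joblib.dump({"estimator": model.estimator, "scaler": model.scaler}, path / "state.joblib")


def load_model(path) -> FittedModel:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    if meta.get("bundle_version") != _BUNDLE_VERSION:
        raise ValueError(f"unsupported bundle version {meta.get('bundle_version')}")
    params = {k: (tuple(v) if isinstance(v, list) else v) for k, v in meta["params"].items()}
    state = joblib.load(path / "state.joblib")
    return FittedModel(
        spec=ModelSpec(meta["family"], params, meta["seed"]),
        estimator=state["estimator"],
        columns=tuple(meta["columns"]),
        scaler=state["scaler"],
        meta=meta.get("meta", {}),
    )
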