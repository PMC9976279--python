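"""Nested cross-validation experimental design and final-model refit.

The protocol: an outer loop of ``n_resamples`` (default 50) random
train/test splits (default 70%/30%); inside each training portion a 5-fold
cross-validation scores every hyperparameter grid point by mean RMSE; the
best point (ties broken by grid order) is refit on the whole training
portion and scored on the held-out test portion.  Reported statistics are
the mean and SD of the per-resample test statistics.  Feature scaling for
the network family is fit inside each training portion only, so no
information leaks from validation or test rows.

The final model is refit on 100% of the data with the modal best
hyperparameters across resamples.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.model_selection import KFold

from . import models as _models
from .curation import MoleculeRecord
from .features import FeatureMatrix
from .models import FittedModel, ModelSpec
from .stats import EvalStats, PredictionSet, evaluate

__all__ = ["ResampleResult", "ValidationReport", "nested_cv", "final_fit"]


@dataclass(frozen=True)
class ResampleResult:
    index: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    chosen_params: Mapping[str, object]
    stats: EvalStats

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test overlap")


@dataclass(frozen=True)
class ValidationReport:
    """Per-resample results plus mean +/- SD aggregation.

    ``summary`` maps each statistic name to (mean, sd) over resamples
    (sample SD, ddof=1; zero for a single resample).
    """

    resamples: tuple[ResampleResult, ...]
    summary: Mapping[str, tuple[float, float]]
    protocol: Mapping[str, object]
    modal_params: Mapping[str, object]

    def to_json(self) -> str:
        return json.dumps(
            {
                "protocol": dict(self.protocol),
                "summary": {k: list(v) for k, v in self.summary.items()},
                "modal_params": _jsonable(self.modal_params),
                "resamples": [
                    {
                        "index": r.index,
                        "train_ids": list(r.train_ids),
                        "test_ids": list(r.test_ids),
                        "chosen_params": _jsonable(r.chosen_params),
                        "stats": r.stats.to_dict(),
                    }
                    for r in self.resamples
                ],
            },
            indent=2,
        )

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def summary_csv_row(self, model: str, dataset: str) -> str:
        r2m, r2s = self.summary["r2"]
        rm, rs = self.summary["rmse"]
        return f"{model},{dataset},{r2m:.2f},{r2s:.2f},{rm:.2f},{rs:.2f}"


def _jsonable(params: Mapping[str, object]) -> dict:
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in params.items()}


def _aggregate(stats_list: Sequence[EvalStats]) -> dict[str, tuple[float, float]]:
    out: dict[str, tuple[float, float]] = {}
    for key in ("r2", "rmse", "bias", "sdep", "pct_within_half"):
        vals = np.array([getattr(s, key) for s in stats_list if getattr(s, key) is not None], dtype=float)
        if vals.size == 0:
            continue
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out[key] = (float(vals.mean()), sd)
    return out


def _inner_cv_rmse(
    family: str,
    params: Mapping[str, object],
    X: FeatureMatrix,
    y: np.ndarray,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
    seed: int,
) -> float:
    rmses = []
    for tr, va in folds:
        sub = FeatureMatrix(
            ids=tuple(X.ids[i] for i in tr), names=X.names, values=X.values[tr]
        )
        val = FeatureMatrix(
            ids=tuple(X.ids[i] for i in va), names=X.names, values=X.values[va]
        )
        m = _models.fit(ModelSpec(family, params, seed), sub, y[tr])
        pred = _models.predict(m, val)
        rmses.append(float(np.sqrt(np.mean((pred - y[va]) ** 2))))
    return float(np.mean(rmses))


def nested_cv(
    records: Sequence[MoleculeRecord],
    features: FeatureMatrix,
    spec_family: str,
    grid: Sequence[Mapping[str, object]] | None = None,
    n_resamples: int = 50,
    test_frac: float = 0.30,
    inner_k: int = 5,
    seed: int = 0,
) -> ValidationReport:
    """Run the nested cross-validation protocol.

    ``records`` supply ids and experimental log(S) (``logS``); ``features``
    must cover the same ids in the same order.  ``grid`` defaults to the
    family's standard grid.  The report is bit-reproducible for a fixed
    master seed: per-resample seeds are spawned deterministically.
    """
    if grid is None:
        grid = _models.DEFAULT_GRIDS[spec_family]
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    ids = tuple(r.id for r in records)
    if ids != features.ids:
        raise ValueError("records and feature matrix disagree on molecule ids/order")
    y = np.array([r.logS for r in records], dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite experimental log(S) values")
    if np.unique(y).size < 2:
        raise ValueError("degenerate target: all experimental values identical")
    n = len(records)
    n_test = int(round(n * test_frac))
    n_test = min(max(n_test, 1), n - 1)
    if inner_k > n - n_test:
        raise ValueError(f"inner_k={inner_k} exceeds training size {n - n_test}")

    master = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(n_resamples)]

    resamples: list[ResampleResult] = []
    for r_idx, r_seed in enumerate(child_seeds):
        rng = np.random.default_rng(r_seed)
        order = rng.permutation(n)
        test_idx = np.sort(order[:n_test])
        train_idx = np.sort(order[n_test:])

        Xtr = FeatureMatrix(
            ids=tuple(ids[i] for i in train_idx), names=features.names, values=features.values[train_idx]
        )
        Xte = FeatureMatrix(
            ids=tuple(ids[i] for i in test_idx), names=features.names, values=features.values[test_idx]
        )
        ytr, yte = y[train_idx], y[test_idx]

        # inner folds fixed per resample, shared by all grid points
        kf = KFold(n_splits=inner_k, shuffle=True, random_state=r_seed % (2**31))
        folds = list(kf.split(Xtr.values))

        best_params, best_rmse = None, np.inf
        if len(grid) == 1:
            best_params = dict(grid[0])
        else:
            for point in grid:
                rmse = _inner_cv_rmse(spec_family, point, Xtr, ytr, folds, r_seed)
                if rmse < best_rmse:  # strict: ties keep earlier grid point
                    best_rmse, best_params = rmse, dict(point)

        model = _models.fit(ModelSpec(spec_family, best_params, r_seed), Xtr, ytr)
        pred = _models.predict(model, Xte)
        st = evaluate(PredictionSet(ids=Xte.ids, y_calc=pred, y_exp=yte))
        resamples.append(
            ResampleResult(
                index=r_idx,
                train_ids=Xtr.ids,
                test_ids=Xte.ids,
                chosen_params=best_params,
                stats=st,
            )
        )

    # modal hyperparameter choice across resamples (ties -> grid order)
    keys = [json.dumps(_jsonable(r.chosen_params), sort_keys=True) for r in resamples]
    counts: dict[str, int] = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    grid_keys = [json.dumps(_jsonable(dict(p)), sort_keys=True) for p in grid]
    modal_key = max(counts, key=lambda k: (counts[k], -grid_keys.index(k) if k in grid_keys else 0))
    modal = json.loads(modal_key)
    modal = {k: (tuple(v) if isinstance(v, list) else v) for k, v in modal.items()}

    return ValidationReport(
        resamples=tuple(resamples),
        summary=_aggregate([r.stats for r in resamples]),
        protocol={
            "n_resamples": n_resamples,
            "test_frac": test_frac,
            "inner_k": inner_k,
            "seed": seed,
            "family": spec_family,
        },
        modal_params=modal,
    )


def final_fit(
    records: Sequence[MoleculeRecord],
    features: FeatureMatrix,
    spec_family: str,
    best_params: Mapping[str, object],
    seed: int = 0,
    report: Optional[ValidationReport] = None,
) -> FittedModel:
    """Refit on 100% of the data with the chosen hyperparameters.

    Provenance: when the originating validation report is supplied, its
    content hash is recorded in the model metadata.
    """
    y = np.array([r.logS for r in records], dtype=float)
    model = _models.fit(ModelSpec(spec_family, dict(best_params), seed), features, y)
    if report is not None:
        model.meta["validation_report_sha256"] = report.content_hash()
    return model
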