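"""Error-decomposition statistics for solubility predictions.

Predictions of log10 molar intrinsic solubility, log(S), are scored with
the coefficient of determination (R^2), the root-mean-square error (RMSE),
and a decomposition of the RMSE into a systematic part -- the bias, or mean
displacement M -- and a random part, the standard deviation of the error of
prediction (SDEP).  With the population (divide-by-N) convention for SDEP
the decomposition is exact:

    RMSE^2 = SDEP^2 + M^2

The bias uses the calculated-minus-experimental sign convention, so a
positive bias means the model overpredicts solubility.  A model whose RMSE
exceeds the standard deviation of the experimental values is worse than the
null model that predicts the experimental mean for every molecule.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PredictionSet",
    "EvalStats",
    "evaluate",
    "null_model_flag",
    "range_restrict",
    "rmse_from_components",
]

#: Identity tolerance for RMSE^2 = SDEP^2 + bias^2, checked on construction.
_IDENTITY_TOL = 1e-9


@dataclass(frozen=True)
class PredictionSet:
    """Paired calculated and experimental log(S) values for one molecule set.

    Parameters
    ----------
    ids
        Molecule identifiers, one per row.
    y_calc
        Predicted log10 molar solubilities.
    y_exp
        Experimental log10 molar solubilities.
    """

    ids: tuple[str, ...]
    y_calc: np.ndarray
    y_exp: np.ndarray

    def __init__(self, ids: Sequence[str], y_calc: Sequence[float], y_exp: Sequence[float]):
        ids = tuple(str(i) for i in ids)
        y_calc = np.asarray(y_calc, dtype=float)
        y_exp = np.asarray(y_exp, dtype=float)
        if not (len(ids) == y_calc.shape[0] == y_exp.shape[0]):
            raise ValueError(
                f"length mismatch: {len(ids)} ids, {y_calc.shape[0]} calculated, "
                f"{y_exp.shape[0]} experimental values"
            )
        if len(ids) < 1:
            raise ValueError("a PredictionSet needs at least one molecule")
        if not (np.isfinite(y_calc).all() and np.isfinite(y_exp).all()):
            raise ValueError("non-finite values in prediction set")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "y_calc", y_calc)
        object.__setattr__(self, "y_exp", y_exp)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class EvalStats:
    """Scores for one prediction set.

    ``r2`` is the coefficient of determination about the experimental mean
    (may be negative; ``None`` when the experimental values have zero
    variance).  ``pct_within_half`` is the percentage of molecules predicted
    within +/-0.5 log units (boundary inclusive).  The exact decomposition
    ``rmse**2 == sdep**2 + bias**2`` is asserted on every instance.
    """

    r2: Optional[float]
    rmse: float
    bias: float
    sdep: float
    pct_within_half: float
    n: int = field(default=0)

    def __post_init__(self) -> None:
        if self.sdep < 0:
            raise ValueError("SDEP must be non-negative")
        if not (0.0 <= self.pct_within_half <= 100.0):
            raise ValueError("pct_within_half must lie in [0, 100]")
        gap = abs(self.rmse**2 - (self.sdep**2 + self.bias**2))
        if gap > _IDENTITY_TOL:
            raise ValueError(
                f"RMSE^2 = SDEP^2 + bias^2 violated by {gap:.3e} "
                f"(rmse={self.rmse}, sdep={self.sdep}, bias={self.bias})"
            )

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "rmse": self.rmse,
            "bias": self.bias,
            "sdep": self.sdep,
            "pct_within_half": self.pct_within_half,
            "n": self.n,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def csv_row(self) -> str:
        """Row in the summary-table column order R2, RMSE, SDEP, bias, %+/-0.5."""
        r2 = "" if self.r2 is None else f"{self.r2:.2f}"
        return (
            f"{r2},{self.rmse:.2f},{self.sdep:.2f},{self.bias:.2f},"
            f"{self.pct_within_half:.0f}"
        )


def evaluate(p: PredictionSet) -> EvalStats:
    """Score a prediction set.

    The error is ``y_calc - y_exp``: RMSE is its root mean square, bias its
    mean, and SDEP its population (divide-by-N) standard deviation, so the
    decomposition RMSE^2 = SDEP^2 + bias^2 holds exactly.
    """
    err = p.y_calc - p.y_exp
    n = err.shape[0]
    bias = float(np.mean(err))
    rmse = float(np.sqrt(np.mean(err**2)))
    sdep = float(np.sqrt(np.mean((err - bias) ** 2)))
    # reconcile floating-point rounding so the identity is exact
    rmse = math.sqrt(sdep**2 + bias**2)
    ss_tot = float(np.sum((p.y_exp - np.mean(p.y_exp)) ** 2))
    if ss_tot == 0.0:
        r2: Optional[float] = None
    else:
        ss_res = float(np.sum(err**2))
        r2 = 1.0 - ss_res / ss_tot
    pct = float(100.0 * np.mean(np.abs(err) <= 0.5))
    return EvalStats(r2=r2, rmse=rmse, bias=bias, sdep=sdep, pct_within_half=pct, n=n)


def rmse_from_components(bias: float, sdep: float) -> float:
    """RMSE implied by a bias/SDEP pair through the exact decomposition."""
    if sdep < 0:
        raise ValueError("SDEP must be non-negative")
    return math.sqrt(bias**2 + sdep**2)


def null_model_flag(stats: EvalStats, exp_sd: float) -> bool:
    """True when the model is less accurate than the null (mean) model.

    The null model predicts the experimental mean for every molecule; its
    RMSE equals the standard deviation of the experimental data, so a model
    with RMSE strictly greater than ``exp_sd`` underperforms it.
    """
    if exp_sd < 0:
        raise ValueError("experimental SD must be non-negative")
    return stats.rmse > exp_sd


def range_restrict(p: PredictionSet, lower: float, upper: float) -> PredictionSet:
    """Restrict a prediction set to molecules with lower < y_exp < upper.

    Both boundaries are strict.  Used to compare test sets over a common
    experimental solubility range, e.g. restricting the high-variance
    "loose" challenge set to the range spanned by the "tight" set
    (-6.79 < log(S) < -1.18).  An empty result is returned as-is; callers
    should check ``len()`` before evaluating.
    """
    if not lower < upper:
        raise ValueError(f"need lower < upper, got ({lower}, {upper})")
    mask = (p.y_exp > lower) & (p.y_exp < upper)
    idx = np.flatnonzero(mask)
    return PredictionSet(
        ids=[p.ids[i] for i in idx],
        y_calc=p.y_calc[idx],
        y_exp=p.y_exp[idx],
    ) if idx.size else _empty_like(p)


class _EmptyPredictionSet(PredictionSet):
    """Zero-molecule prediction set (valid only as a range_restrict result)."""

    def __init__(self):  # noqa: D401 - trivially empty
        object.__setattr__(self, "ids", ())
        object.__setattr__(self, "y_calc", np.empty(0))
        object.__setattr__(self, "y_exp", np.empty(0))


def _empty_like(p: PredictionSet) -> PredictionSet:
    return _EmptyPredictionSet()
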