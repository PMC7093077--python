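"""Distance functions between a simulated trajectory and a dataset.

The estimation fitness dispatches through :func:`evaluate_quality`; a failed
trajectory maps to the finite sentinel :data:`FAILURE_SENTINEL` so that
optimizer selection never has to order IEEE infinities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # avoid a circular import; only used for annotations
    from .dataio import ColumnMapping, DataSet
    from .solvers import Trajectory

__all__ = [
    "FAILURE_SENTINEL",
    "EPSILON_DENOMINATOR",
    "QualityError",
    "QualitySpec",
    "relative_squared_error",
    "rmse",
    "mean_absolute_error",
    "euclidean",
    "evaluate_quality",
    "QUALITY_FUNCTIONS",
]

FAILURE_SENTINEL = 1e300
#: |data value| below this is treated as zero for RSE normalization
EPSILON_DENOMINATOR = 1e-10


class QualityError(ValueError):
    pass


@dataclass(frozen=True)
class QualitySpec:
    kind: str = "relative_squared_error"

    def __post_init__(self) -> None:
        if self.kind not in QUALITY_FUNCTIONS:
            raise QualityError(f"unknown quality function {self.kind!r}")


def _paired_values(sim: Trajectory, data: DataSet, mapping: ColumnMapping):
    """Yield (column, sim values, data values) for each mapped column with
    the simulation linearly interpolated onto the data time points.
    Missing data cells are dropped."""
    for col, target in mapping.pairs.items():
        if col not in data.columns:
            raise QualityError(f"mapped column {col!r} not present in dataset")
        if target not in sim.column_ids:
            raise QualityError(
                f"mapped quantity {target!r} not present in trajectory")
        d = np.asarray(data.columns[col], dtype=float)
        keep = ~np.isnan(d)
        if not np.any(keep):
            continue
        times = data.times[keep]
        if times[0] < sim.times[0] - 1e-9 or times[-1] > sim.times[-1] + 1e-9:
            raise QualityError(
                f"data time points for column {col!r} lie outside the "
                f"simulated span")
        s = np.interp(times, sim.times, sim.column(target))
        yield col, s, d[keep]


def relative_squared_error(sim: Trajectory, data: DataSet,
                           mapping: ColumnMapping) -> float:
    """Sum over mapped cells of ``((sim - data) / d)²``.

    The denominator ``d`` is the data value itself where ``|data| > ε``,
    otherwise the mean of the column's nonzero magnitudes; an all-zero
    column falls back to absolute squared error.
    """
    total = 0.0
    for _col, s, d in _paired_values(sim, data, mapping):
        nonzero = np.abs(d) > EPSILON_DENOMINATOR
        if np.any(nonzero):
            fallback = float(np.mean(np.abs(d[nonzero])))
            denom = np.where(nonzero, np.abs(d), fallback)
        else:
            denom = np.ones_like(d)
        total += float(np.sum(((s - d) / denom) ** 2))
    return total


def rmse(sim: Trajectory, data: DataSet, mapping: ColumnMapping) -> float:
    """Root mean squared error over all mapped cells."""
    sq_sum = 0.0
    n = 0
    for _col, s, d in _paired_values(sim, data, mapping):
        sq_sum += float(np.sum((s - d) ** 2))
        n += len(d)
    return math.sqrt(sq_sum / n) if n else 0.0


def mean_absolute_error(sim: Trajectory, data: DataSet,
                        mapping: ColumnMapping) -> float:
    abs_sum = 0.0
    n = 0
    for _col, s, d in _paired_values(sim, data, mapping):
        abs_sum += float(np.sum(np.abs(s - d)))
        n += len(d)
    return abs_sum / n if n else 0.0


def euclidean(sim: Trajectory, data: DataSet, mapping: ColumnMapping) -> float:
    sq_sum = 0.0
    for _col, s, d in _paired_values(sim, data, mapping):
        sq_sum += float(np.sum((s - d) ** 2))
    return math.sqrt(sq_sum)


QUALITY_FUNCTIONS = {
    "relative_squared_error": relative_squared_error,
    "rmse": rmse,
    "mean_absolute_error": mean_absolute_error,
    "euclidean": euclidean,
}


def evaluate_quality(spec: QualitySpec, sim: Trajectory, data: DataSet,
                     mapping: ColumnMapping) -> float:
    """Dispatch to the registered function; failed trajectories score the
    finite failure sentinel."""
    if spec.kind not in QUALITY_FUNCTIONS:
        raise QualityError(f"unknown quality function {spec.kind!r}")
    if not sim.ok:
        return FAILURE_SENTINEL
    return QUALITY_FUNCTIONS[spec.kind](sim, data, mapping)
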