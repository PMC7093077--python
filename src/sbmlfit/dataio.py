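"""Experimental-data tables, column mapping, and parameter-range files."""

from __future__ import annotations

import csv
import io
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import ModelDocument
from .quality import QualitySpec  # noqa: F401  (re-exported for problem assembly)
from .solvers import SolverSettings, Trajectory

__all__ = [
    "DataFormatError",
    "DataSet",
    "ColumnMapping",
    "ParameterSpec",
    "EstimationProblem",
    "read_data_csv",
    "suggest_mapping",
    "read_parameter_ranges",
    "write_trajectory_csv",
    "subsample",
]


class DataFormatError(ValueError):
    pass


@dataclass
class DataSet:
    """A time column plus named value series; NaN marks missing cells."""

    times: np.ndarray
    columns: dict[str, np.ndarray]
    source: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise DataFormatError("time values must be strictly increasing")
        for name, col in self.columns.items():
            arr = np.asarray(col, dtype=float)
            if len(arr) != len(self.times):
                raise DataFormatError(
                    f"column {name!r} has {len(arr)} rows, expected "
                    f"{len(self.times)}")
            self.columns[name] = arr

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ColumnMapping:
    """data column name -> model quantity id"""

    pairs: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ParameterSpec:
    """Search box and initialization box of one fitted quantity.

    The initialization interval is where candidates are randomly seeded;
    the min/max interval is enforced throughout the estimation.
    """

    id: str
    init_min: float
    init_max: float
    min: float
    max: float
    unit: str = ""

    def __post_init__(self) -> None:
        vals = (self.min, self.init_min, self.init_max, self.max)
        if not all(math.isfinite(v) for v in vals):
            raise DataFormatError(f"parameter {self.id!r}: bounds must be finite")
        if not self.min <= self.init_min <= self.init_max <= self.max:
            raise DataFormatError(
                f"parameter {self.id!r}: require min <= initMin <= initMax "
                f"<= max, got {vals}")


@dataclass
class EstimationProblem:
    model: ModelDocument
    data: DataSet
    mapping: ColumnMapping
    parameters: list[ParameterSpec]
    quality: QualitySpec
    solver: SolverSettings

    def __post_init__(self) -> None:
        if not self.parameters:
            raise DataFormatError("estimation problem needs at least one "
                                  "parameter to fit")
        known = self.model.global_ids
        for spec in self.parameters:
            if spec.id not in known:
                raise DataFormatError(
                    f"fitted quantity {spec.id!r} is not defined in the model")


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_data_csv(path: str | os.PathLike) -> DataSet:
    """Read a header + rows table (comma or tab separated).

    The time column is the one named ``time`` (case-insensitive) or, absent
    that, the first column.  Empty cells become missing values.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        text = fh.read()
    first_line = text.splitlines()[0] if text.strip() else ""
    if not first_line:
        raise DataFormatError(f"{path}: empty file")
    delim = _sniff_delimiter(first_line)
    reader = csv.reader(io.StringIO(text), delimiter=delim)
    rows = [row for row in reader if row and any(cell.strip() for cell in row)]
    header = [h.strip() for h in rows[0]]
    if len(rows) < 2:
        raise DataFormatError(f"{path}: no data rows")

    time_idx = 0
    for i, h in enumerate(header):
        if h.lower() == "time":
            time_idx = i
            break

    times: list[float] = []
    cols: dict[str, list[float]] = {h: [] for i, h in enumerate(header)
                                    if i != time_idx}
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise DataFormatError(
                f"{path}: line {lineno} has {len(row)} cells, expected "
                f"{len(header)}")
        try:
            times.append(float(row[time_idx]))
        except ValueError as exc:
            raise DataFormatError(
                f"{path}: line {lineno}: bad time value {row[time_idx]!r}"
            ) from exc
        for i, h in enumerate(header):
            if i == time_idx:
                continue
            cell = row[i].strip()
            if cell == "" or cell.lower() in ("na", "nan"):
                cols[h].append(math.nan)
            else:
                try:
                    cols[h].append(float(cell))
                except ValueError as exc:
                    raise DataFormatError(
                        f"{path}: line {lineno}: bad value {cell!r} in "
                        f"column {h!r}") from exc

    if not cols:
        raise DataFormatError(f"{path}: no value columns besides time")
    t = np.asarray(times)
    if np.any(np.diff(t) <= 0):
        raise DataFormatError(f"{path}: time column must be strictly increasing")
    return DataSet(times=t,
                   columns={k: np.asarray(v) for k, v in cols.items()},
                   source=str(path))


def suggest_mapping(data: DataSet, model: ModelDocument) -> ColumnMapping:
    """Deterministic name-based column mapping suggestion.

    Tiers: exact id match > exact display-name match > case-insensitive id
    match > case-insensitive name match > unmapped.
    """
    entities: list[tuple[str, str]] = []  # (id, display name)
    for group in (model.species, model.compartments, model.parameters):
        for ent in group:
            entities.append((ent.id, getattr(ent, "name", "") or ""))

    pairs: dict[str, str] = {}
    for col in data.columns:
        target = None
        for eid, _ in entities:
            if col == eid:
                target = eid
                break
        if target is None:
            for eid, name in entities:
                if name and col == name:
                    target = eid
                    break
        if target is None:
            low = col.casefold()
            for eid, _ in entities:
                if low == eid.casefold():
                    target = eid
                    break
        if target is None:
            low = col.casefold()
            for eid, name in entities:
                if name and low == name.casefold():
                    target = eid
                    break
        if target is not None:
            pairs[col] = target
    return ColumnMapping(pairs)


def read_parameter_ranges(path: str | os.PathLike) -> list[ParameterSpec]:
    """Parse the plain-text range file: one record per line, either

    ``id initMin initMax min max`` or the 3-field ``id min max`` form in
    which the initialization interval equals the search interval.  Blank
    lines and ``#`` comments are skipped; fields may be whitespace- or
    tab-separated.
    """
    specs: list[ParameterSpec] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.replace(",", " ").split()
            if len(fields) not in (3, 5):
                raise DataFormatError(
                    f"{path}: line {lineno}: expected 3 or 5 fields, got "
                    f"{len(fields)}")
            pid = fields[0]
            try:
                nums = [float(f) for f in fields[1:]]
            except ValueError as exc:
                raise DataFormatError(
                    f"{path}: line {lineno}: non-numeric bound") from exc
            if len(nums) == 2:
                lo, hi = nums
                init_lo, init_hi = lo, hi
            else:
                init_lo, init_hi, lo, hi = nums
            try:
                specs.append(ParameterSpec(pid, init_lo, init_hi, lo, hi))
            except DataFormatError as exc:
                raise DataFormatError(f"{path}: line {lineno}: {exc}") from exc
    if not specs:
        raise DataFormatError(f"{path}: no parameter records found")
    return specs


def write_trajectory_csv(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write ``time`` plus one column per reported quantity at full
    (repr) precision."""
    if not traj.ok:
        raise ValueError("refusing to write a failed trajectory "
                         f"({traj.failure_reason})")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time"] + list(traj.column_ids))
        for i, t in enumerate(traj.times):
            writer.writerow([repr(float(t))]
                            + [repr(float(v)) for v in traj.values[i]])


def subsample(data: DataSet, times: Sequence[float],
              tol: float = 1e-9) -> DataSet:
    """Restrict the dataset to the requested time points (must be present
    within ``tol``)."""
    idx: list[int] = []
    missing: list[float] = []
    for t in times:
        hits = np.flatnonzero(np.abs(data.times - t) <= tol)
        if len(hits) == 0:
            missing.append(float(t))
        else:
            idx.append(int(hits[0]))
    if missing:
        raise DataFormatError(
            f"requested time points absent from dataset: {missing}")
    sel = np.asarray(idx, dtype=int)
    return DataSet(
        times=data.times[sel],
        columns={k: v[sel] for k, v in data.columns.items()},
        source=data.source,
    )
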