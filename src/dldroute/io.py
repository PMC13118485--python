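"""Measurement tables and the data boundary of the analysis.

The input to every analysis is a table of segmented objects, one row per
particle, with at least a reservoir label (``inlet``, ``small``, ``medium``
or ``large``) and the object's major-axis length in micrometres.  For a
single sphere the major axis equals the diameter; for a cluster it is the
longest chord of the aggregate.  Sizes are carried in micrometres
throughout; there is no unit-conversion layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical reservoir labels.  ``inlet`` holds the unsorted sample; the
#: three outlets collect the zigzag (small), intermediate (medium) and
#: displacement (large) streams of the sorter.
RESERVOIRS: tuple[str, ...] = ("inlet", "small", "medium", "large")

#: Outlet labels in the canonical column order used by routing tables.
OUTLETS: tuple[str, ...] = ("small", "medium", "large")

_REQUIRED_COLUMNS = ("reservoir", "major_axis_um")
_OPTIONAL_COLUMNS = ("is_cluster", "population", "object_id")


class MeasurementSchemaError(ValueError):
    """The table is structurally invalid (missing column, bad header)."""


class MeasurementValueError(ValueError):
    """A row holds an invalid value; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


@dataclass(frozen=True)
class ParticleRecord:
    """One segmented object.

    Parameters
    ----------
    reservoir
        One of :data:`RESERVOIRS` (lower-case canonical form).
    size
        Major-axis length in μm; finite and strictly positive.
    is_cluster
        Whether the object is an aggregate of more than one particle,
        if known.
    population
        Optional label of the nominal population (e.g. ``"7um"``).
    object_id
        Optional opaque identifier carried through from segmentation.
    """

    reservoir: str
    size: float
    is_cluster: bool | None = None
    population: str | None = None
    object_id: str | None = None

    def __post_init__(self):
        if self.reservoir not in RESERVOIRS:
            raise MeasurementValueError(
                f"unknown reservoir {self.reservoir!r}; allowed labels: {', '.join(RESERVOIRS)}"
            )
        if not (math.isfinite(self.size) and self.size > 0):
            raise MeasurementValueError(
                f"size must be finite and > 0, got {self.size!r}"
            )


def _coerce_optional_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise MeasurementValueError(f"cannot interpret is_cluster value {value!r}")


def _coerce_optional_str(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return str(value)


def read_measurements(source: str | IO[str]) -> list[ParticleRecord]:
    """Read a particle measurement CSV into validated records.

    The table must be comma-separated UTF-8 with a header row containing at
    least ``reservoir`` and ``major_axis_um``.  Reservoir labels are matched
    case-insensitively and stored lower-case.  Row order is preserved.

    Raises
    ------
    MeasurementSchemaError
        If a required column is missing.
    MeasurementValueError
        If a row has a non-numeric or non-positive size, or an unknown
        reservoir label; the exception carries the 0-based row index.
    """
    frame = pd.read_csv(source, dtype=str)
    for column in _REQUIRED_COLUMNS:
        if column not in frame.columns:
            raise MeasurementSchemaError(f"missing required column {column!r}")
    records: list[ParticleRecord] = []
    for row_index, row in enumerate(frame.itertuples(index=False)):
        raw = dict(zip(frame.columns, row))
        label = str(raw["reservoir"]).strip().lower()
        if label not in RESERVOIRS:
            raise MeasurementValueError(
                f"row {row_index}: unknown reservoir {raw['reservoir']!r}; "
                f"allowed labels: {', '.join(RESERVOIRS)}",
                row=row_index,
            )
        try:
            size = float(raw["major_axis_um"])
        except (TypeError, ValueError):
            raise MeasurementValueError(
                f"row {row_index}: non-numeric size {raw['major_axis_um']!r}",
                row=row_index,
            ) from None
        if not (math.isfinite(size) and size > 0):
            raise MeasurementValueError(
                f"row {row_index}: size must be finite and > 0, got {size}",
                row=row_index,
            )
        records.append(
            ParticleRecord(
                reservoir=label,
                size=size,
                is_cluster=_coerce_optional_bool(raw.get("is_cluster")),
                population=_coerce_optional_str(raw.get("population")),
                object_id=_coerce_optional_str(raw.get("object_id")),
            )
        )
    return records


def write_measurements(records: Iterable[ParticleRecord], target: str | IO[str]) -> None:
    """Write records to a measurement CSV (inverse of :func:`read_measurements`)."""
    rows = []
    for r in records:
        rows.append(
            {
                "reservoir": r.reservoir,
                "major_axis_um": repr(r.size),
                "is_cluster": "" if r.is_cluster is None else str(r.is_cluster).lower(),
                "population": "" if r.population is None else r.population,
                "object_id": "" if r.object_id is None else r.object_id,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["reservoir", "major_axis_um", "is_cluster", "population", "object_id"]
    )
    frame.to_csv(target, index=False)


def outlet_fractions(
    outlet_counts: Mapping[str, float],
    sampling_volumes: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Outlet fractions ``P(k)`` from per-outlet counts or concentrations.

    With no volumes the fractions are plain count fractions.  With per-outlet
    sampling volumes the counts are first converted to concentrations
    (count / volume) and the concentrations normalised, which is appropriate
    when each outlet was sub-sampled with a different imaged volume.

    The result sums to 1 and is invariant to rescaling all counts by a common
    factor.
    """
    counts = {}
    for k in OUTLETS:
        if k not in outlet_counts:
            raise MeasurementSchemaError(f"missing outlet count for {k!r}")
        value = float(outlet_counts[k])
        if value < 0 or not math.isfinite(value):
            raise MeasurementValueError(f"count for {k!r} must be finite and >= 0, got {value}")
        counts[k] = value
    if sampling_volumes is not None:
        for k in OUTLETS:
            volume = float(sampling_volumes[k])
            if volume <= 0:
                raise MeasurementValueError(f"sampling volume for {k!r} must be > 0, got {volume}")
            counts[k] = counts[k] / volume
    total = sum(counts.values())
    if total <= 0:
        raise MeasurementValueError("no sorted particles: all outlet counts are zero")
    return {k: counts[k] / total for k in OUTLETS}


@dataclass
class ReservoirSet:
    """Records grouped by reservoir plus the outlet fractions ``P(k)``.

    ``fractions`` may come from realized record counts or be supplied
    externally (e.g. from concentration measurements); both paths are valid
    because the total particle number cancels in the routing-probability
    formula.
    """

    records: dict[str, list[ParticleRecord]]
    fractions: dict[str, float]
    total_count: int = field(default=0)

    def __post_init__(self):
        for label in self.records:
            if label not in RESERVOIRS:
                raise MeasurementValueError(
                    f"unknown reservoir {label!r}; allowed labels: {', '.join(RESERVOIRS)}"
                )
        s = sum(self.fractions.get(k, 0.0) for k in OUTLETS)
        if abs(s - 1.0) > 1e-9:
            raise MeasurementValueError(f"outlet fractions must sum to 1, got {s!r}")
        if self.total_count == 0:
            self.total_count = sum(len(self.records.get(k, [])) for k in OUTLETS)

    @classmethod
    def from_records(
        cls,
        records: Sequence[ParticleRecord],
        fractions: Mapping[str, float] | None = None,
    ) -> "ReservoirSet":
        """Group a flat record list; derive ``P(k)`` from outlet counts unless given."""
        grouped: dict[str, list[ParticleRecord]] = {k: [] for k in RESERVOIRS}
        for r in records:
            grouped[r.reservoir].append(r)
        if fractions is None:
            fractions = outlet_fractions({k: len(grouped[k]) for k in OUTLETS})
        return cls(records=grouped, fractions={k: float(fractions[k]) for k in OUTLETS})

    def sizes(self, reservoir: str) -> np.ndarray:
        """Sizes (μm) in one reservoir as a float array."""
        return np.asarray([r.size for r in self.records.get(reservoir, [])], dtype=float)

    def all_sizes(self) -> np.ndarray:
        """Pooled sizes across all reservoirs present."""
        parts = [self.sizes(k) for k in RESERVOIRS if self.records.get(k)]
        return np.concatenate(parts) if parts else np.empty(0)
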