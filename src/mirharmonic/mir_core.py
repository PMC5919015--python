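"""Marginal increment ratio (MIR) data: records, datasets, and summaries.

The MIR expresses the forming growth increment of a hard structure (shell,
otolith, vertebra) as a percentage of the last completed increment,

    MIR = MI / PI * 100,

where MI is the marginal increment (distance from the last growth mark to the
growing edge) and PI the penultimate increment (distance between the last two
completed marks).  In a population sampled through the year, MIR cycles from
near 0 % just after a band completes toward ~100 % as the next band forms, so
its monthly trajectory carries the periodicity signal that the harmonic models
in :mod:`mirharmonic.harmonic_models` describe.

This module holds the tabular containers (:class:`MIRRecord`,
:class:`MIRDataset`), the CSV/XLSX readers matching the standard per-individual
layout (sample id, month, year, MIR %, age), the two-period replication
convention applied before fitting, and monthly summary statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "InvalidMeasurementError",
    "EmptyDatasetError",
    "MIRRecord",
    "MIRDataset",
    "compute_mir",
    "replicate_two_periods",
    "monthly_means",
    "read_mir_table",
    "write_monthly_means",
]


class InvalidMeasurementError(ValueError):
    """A raw increment measurement violates its physical constraints."""


class EmptyDatasetError(ValueError):
    """An operation requiring records was given an empty dataset."""


@dataclass(frozen=True)
class MIRRecord:
    """One individual's capture time and marginal increment ratio.

    Parameters
    ----------
    sample_id:
        Opaque identifier; kept verbatim, never deduplicated.
    month:
        Integer calendar month of capture, 1-12.  This is the time
        coordinate ``t`` of the harmonic models.
    year:
        Calendar year of capture.  Metadata only: fitting pools across
        years with no year effect.
    mir:
        MIR percentage.  Must be strictly positive because the likelihood
        operates on ``ln(mir)``.
    age:
        Estimated age in years; optional, unused by the periodicity fit.
    """

    sample_id: str
    month: int
    year: int | None
    mir: float
    age: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= int(self.month) <= 12:
            raise ValueError(f"month must be in 1..12, got {self.month!r}")
        if not np.isfinite(self.mir) or self.mir <= 0:
            raise ValueError(
                f"mir must be a finite positive percentage, got {self.mir!r} "
                f"(sample {self.sample_id!r}); zero/negative MIR cannot enter "
                "the log-scale likelihood"
            )


@dataclass(frozen=True)
class MIRDataset:
    """Ordered collection of :class:`MIRRecord` with cycle metadata.

    ``period_unit`` is the nominal number of time units per cycle: 12 for
    monthly sampling within an annual cycle.  ``times`` may exceed
    ``period_unit`` after two-period replication.
    """

    records: tuple[MIRRecord, ...]
    species_label: str = ""
    period_unit: float = 12.0
    #: replication offsets already applied (0 for raw data)
    _offsets: tuple[float, ...] = field(default=(0.0,), repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if self.period_unit <= 0:
            raise ValueError("period_unit must be positive")

    def __len__(self) -> int:
        return len(self.records) * len(self._offsets)

    def __iter__(self) -> Iterator[MIRRecord]:
        return iter(self.records)

    @property
    def n_original(self) -> int:
        """Number of distinct sampled individuals (before replication)."""
        return len(self.records)

    @property
    def is_replicated(self) -> bool:
        return len(self._offsets) > 1

    @property
    def times(self) -> np.ndarray:
        """Observation times in months, replication offsets applied."""
        base = np.array([r.month for r in self.records], dtype=float)
        return np.concatenate([base + off for off in self._offsets])

    @property
    def mir(self) -> np.ndarray:
        """Observed MIR percentages aligned with :attr:`times`."""
        base = np.array([r.mir for r in self.records], dtype=float)
        return np.tile(base, len(self._offsets))

    def to_frame(self) -> pd.DataFrame:
        """Original (unreplicated) records as a tidy DataFrame."""
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "month": [r.month for r in self.records],
                "year": [r.year for r in self.records],
                "mir": [r.mir for r in self.records],
                "age": [r.age for r in self.records],
            }
        )

    def metadata_json(self) -> str:
        """JSON blob describing the dataset (no per-record data)."""
        return json.dumps(
            {
                "species_label": self.species_label,
                "n_records": self.n_original,
                "n_effective": len(self),
                "period_unit": self.period_unit,
                "replicated": self.is_replicated,
                "months_present": sorted({r.month for r in self.records}),
            },
            indent=2,
        )


def compute_mir(mi: float, pi: float) -> float:
    """MIR percentage from raw increment lengths: ``100 * mi / pi``.

    ``mi`` is the marginal (forming) increment, ``pi`` the penultimate
    (last completed) increment, in the same length units.  Values above
    100 are legitimate (bands shrink with age on average but the data are
    never clipped).

    Raises
    ------
    InvalidMeasurementError
        If ``pi <= 0`` or ``mi < 0``.
    """
    if pi <= 0:
        raise InvalidMeasurementError(f"penultimate increment must be > 0, got {pi!r}")
    if mi < 0:
        raise InvalidMeasurementError(f"marginal increment must be >= 0, got {mi!r}")
    return 100.0 * mi / pi


def replicate_two_periods(data: MIRDataset) -> MIRDataset:
    """Duplicate the dataset over a second cycle before fitting.

    Each record observed at month ``t`` is paired with a copy at
    ``t + period_unit``, the standard device for fitting a periodic curve to
    within-cycle samples: it removes the artificial boundary between the end
    of one cycle and the start of the next.  The observation count entering
    the likelihood doubles.  The input dataset is not modified; replicating
    an already replicated dataset doubles it again.
    """
    if data.n_original == 0:
        raise EmptyDatasetError("cannot replicate an empty dataset")
    span = max(data._offsets) + data.period_unit
    return replace(data, _offsets=data._offsets + tuple(o + span for o in data._offsets))


def monthly_means(data: MIRDataset) -> list[tuple[int, float, int]]:
    """Per-month arithmetic mean of MIR over the original records.

    Returns ``(month, mean, count)`` tuples for months present in the data,
    sorted by month; months with no records are omitted.  Counts sum to the
    original record count.
    """
    buckets: dict[int, list[float]] = {}
    for r in data.records:
        buckets.setdefault(r.month, []).append(r.mir)
    return [(m, float(np.mean(v)), len(v)) for m, v in sorted(buckets.items())]


_REQUIRED = ("sample_id", "month", "mir")
_OPTIONAL = ("year", "age")


def _normalise_columns(
    df: pd.DataFrame, column_map: Mapping[str, str] | None
) -> pd.DataFrame:
    """Lower-case headers, then apply the caller's logical->actual mapping."""
    df = df.rename(columns={c: str(c).strip().lower() for c in df.columns})
    if column_map:
        inverse = {str(actual).strip().lower(): logical for logical, actual in column_map.items()}
        df = df.rename(columns=inverse)
    return df


def read_mir_table(
    path: str | Path,
    *,
    species_label: str = "",
    period_unit: float = 12.0,
    column_map: Mapping[str, str] | None = None,
    sheet: str | int = 0,
) -> MIRDataset:
    """Read per-individual MIR records from CSV or XLSX.

    Expects columns ``sample_id, month, year, mir, age`` (case-insensitive;
    ``year``/``age`` optional).  ``column_map`` remaps logical names to the
    file's actual headers, e.g. ``{"mir": "MIR %"}``.  Records with
    non-positive MIR are excluded with a logged warning: the log-scale
    likelihood cannot accommodate them.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm", ".xls"}:
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        df = pd.read_csv(path)
    df = _normalise_columns(df, column_map)

    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise KeyError(
            f"{path.name}: required column(s) {missing} not found; "
            f"available: {list(df.columns)}"
        )

    records: list[MIRRecord] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        mir = float(getattr(row, "mir"))
        sid = str(getattr(row, "sample_id"))
        if not np.isfinite(mir) or mir <= 0:
            n_dropped += 1
            continue
        year = getattr(row, "year", None)
        age = getattr(row, "age", None)
        records.append(
            MIRRecord(
                sample_id=sid,
                month=int(getattr(row, "month")),
                year=None if year is None or pd.isna(year) else int(year),
                mir=mir,
                age=None if age is None or pd.isna(age) else int(age),
            )
        )
    if n_dropped:
        logger.warning(
            "%s: excluded %d record(s) with MIR <= 0 (undefined on the log scale)",
            path.name,
            n_dropped,
        )
    return MIRDataset(tuple(records), species_label=species_label, period_unit=period_unit)


def write_monthly_means(data: MIRDataset, path: str | Path) -> pd.DataFrame:
    """Write the monthly-mean summary as tidy CSV; returns the frame."""
    rows = monthly_means(data)
    df = pd.DataFrame(rows, columns=["month", "mean_mir", "n"])
    df.to_csv(path, index=False)
    return df


def dataset_from_arrays(
    months: Iterable[int],
    mir: Iterable[float],
    *,
    sample_ids: Sequence[str] | None = None,
    ages: Sequence[int | None] | None = None,
    species_label: str = "",
    period_unit: float = 12.0,
) -> MIRDataset:
    """Convenience constructor from parallel arrays (used by the simulator)."""
    months = list(months)
    mir = list(mir)
    if sample_ids is None:
        sample_ids = [f"s{i:05d}" for i in range(len(months))]
    if ages is None:
        ages = [None] * len(months)
    records = tuple(
        MIRRecord(sample_id=s, month=int(m), year=None, mir=float(v), age=a)
        for s, m, v, a in zip(sample_ids, months, mir, ages, strict=True)
    )
    return MIRDataset(records, species_label=species_label, period_unit=period_unit)
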