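"""Peak-table and calibration-series data model with CSV readers/writers.

Formats are plain comma-separated UTF-8 text with a header row:

peak tables
    ``sample_id,class_label,peak_id,rt_min,area`` — one row per peak, one
    :class:`PeakTable` per distinct sample_id.  ``class_label`` is ``CM``
    (*C. morifolium* flower), ``CI`` (*C. indicum* flower) or ``unknown``.
    ``peak_id`` is the common-peak number 1-18.

calibration series
    ``compound,instrument_id,conc_ug_ml,area`` — one row per level, one
    :class:`CalibrationSeries` per (compound, instrument) pair.

Readers never silently drop rows: every malformed row is reported with its
line number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "CLASS_LABELS",
    "Peak",
    "PeakTable",
    "CalibrationSeries",
    "read_peak_table",
    "write_peak_table",
    "read_calibration",
    "write_calibration",
]

CLASS_LABELS = ("CM", "CI", "unknown")

PEAK_COLUMNS = ["sample_id", "class_label", "peak_id", "rt_min", "area"]
CALIB_COLUMNS = ["compound", "instrument_id", "conc_ug_ml", "area"]


class Peak(NamedTuple):
    peak_id: int
    rt: float      # min
    area: float    # detector units, arbitrary but consistent within a set


@dataclass
class PeakTable:
    """All peaks of one sample injection, with its class label."""

    sample_id: str
    class_label: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self):
        if self.class_label not in CLASS_LABELS:
            raise ValidationError(
                f"sample {self.sample_id!r}: class_label must be one of {CLASS_LABELS}, "
                f"got {self.class_label!r}"
            )
        ids = [p.peak_id for p in self.peaks]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"sample {self.sample_id!r}: duplicate peak ids")
        for p in self.peaks:
            if not 1 <= p.peak_id <= 18:
                raise ValidationError(f"sample {self.sample_id!r}: peak_id {p.peak_id} outside 1..18")
            if p.rt <= 0:
                raise ValidationError(f"sample {self.sample_id!r}, peak {p.peak_id}: rt must be positive")
            if p.area < 0:
                raise ValidationError(f"sample {self.sample_id!r}, peak {p.peak_id}: negative area")

    def peak(self, peak_id: int) -> Peak:
        for p in self.peaks:
            if p.peak_id == peak_id:
                return p
        raise KeyError(f"sample {self.sample_id!r} has no peak {peak_id}")

    def has_peak(self, peak_id: int) -> bool:
        return any(p.peak_id == peak_id for p in self.peaks)


@dataclass
class CalibrationSeries:
    """Concentration-area pairs for one compound on one instrument."""

    compound: str
    instrument_id: str
    levels: list[tuple[float, float]]   # (conc ug/ml, area)

    def __post_init__(self):
        if self.n_levels < 2:
            raise ValidationError(
                f"{self.compound}/{self.instrument_id}: need >= 2 calibration levels"
            )
        concs = self.concentrations
        if np.any(concs <= 0):
            raise ValidationError(f"{self.compound}/{self.instrument_id}: concentrations must be positive")
        diffs = np.diff(concs)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValidationError(
                f"{self.compound}/{self.instrument_id}: concentrations must be strictly "
                "increasing or decreasing (duplicates not allowed)"
            )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.levels], dtype=float)

    @property
    def areas(self) -> np.ndarray:
        return np.array([a for _, a in self.levels], dtype=float)


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file without header") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _numeric(df: pd.DataFrame, column: str, path, integer: bool = False) -> pd.Series:
    """Coerce a column to numbers, naming the first bad data row (1-based,
    header = line 1)."""
    values = pd.to_numeric(df[column], errors="coerce")
    bad = values.isna() & df[column].notna() | df[column].isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(f"{path}: row {row + 2}: malformed value in column {column!r}")
    if integer:
        frac = values % 1 != 0
        if frac.any():
            row = int(np.flatnonzero(frac.to_numpy())[0])
            raise FormatError(f"{path}: row {row + 2}: column {column!r} must be an integer")
    return values


def read_peak_table(path) -> list[PeakTable]:
    """Read peak tables from CSV; one :class:`PeakTable` per sample_id.

    Sample order follows first appearance in the file.  Malformed rows are
    rejected with their line number; negative areas raise ValidationError.
    """
    df = _read_csv(path, PEAK_COLUMNS)
    if df.empty:
        return []
    df = df.copy()
    df["peak_id"] = _numeric(df, "peak_id", path, integer=True).astype(int)
    df["rt_min"] = _numeric(df, "rt_min", path)
    df["area"] = _numeric(df, "area", path)
    neg = df["area"] < 0
    if neg.any():
        row = int(np.flatnonzero(neg.to_numpy())[0])
        raise ValidationError(f"{path}: row {row + 2}: negative area")

    tables = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        labels = grp["class_label"].unique()
        if len(labels) != 1:
            raise ValidationError(f"{path}: sample {sample_id!r} has conflicting class labels {list(labels)}")
        peaks = [Peak(int(r.peak_id), float(r.rt_min), float(r.area)) for r in grp.itertuples()]
        tables.append(PeakTable(str(sample_id), str(labels[0]), peaks))
    total = sum(len(t.peaks) for t in tables)
    if total != len(df):  # count reconciliation; groupby must not drop rows
        raise FormatError(f"{path}: row count mismatch after parsing ({total} != {len(df)})")
    return tables


def write_peak_table(tables: list[PeakTable], path) -> str:
    """Write peak tables to CSV readable by :func:`read_peak_table`."""
    if not tables:
        raise ValidationError("no peak tables to write")
    rows = [
        (t.sample_id, t.class_label, p.peak_id, p.rt, p.area)
        for t in tables
        for p in t.peaks
    ]
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(path, index=False, float_format="%.10g")
    return str(path)


def read_calibration(path) -> list[CalibrationSeries]:
    """Read calibration series; one per (compound, instrument_id) pair."""
    df = _read_csv(path, CALIB_COLUMNS)
    if df.empty:
        return []
    df = df.copy()
    df["conc_ug_ml"] = _numeric(df, "conc_ug_ml", path)
    df["area"] = _numeric(df, "area", path)
    dup = df.duplicated(subset=["compound", "instrument_id", "conc_ug_ml"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"{path}: row {row + 2}: duplicate (compound, instrument, concentration)"
        )
    series = []
    for (compound, instrument), grp in df.groupby(["compound", "instrument_id"], sort=False):
        levels = [(float(r.conc_ug_ml), float(r.area)) for r in grp.itertuples()]
        series.append(CalibrationSeries(str(compound), str(instrument), levels))
    return series


def write_calibration(series: list[CalibrationSeries], path) -> str:
    if not series:
        raise ValidationError("no calibration series to write")
    rows = [
        (s.compound, s.instrument_id, conc, area)
        for s in series
        for conc, area in s.levels
    ]
    pd.DataFrame(rows, columns=CALIB_COLUMNS).to_csv(path, index=False, float_format="%.10g")
    return str(path)
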