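"""Reading, validating and writing eye-tracker gaze logs.

A gaze log holds the raw samples an eye tracker emits while one subject
views one stimulus image: a timestamp (seconds since image onset), pixel
coordinates for each eye (top-left origin, x rightward, y downward) and a
pupil diameter in millimetres for each eye.  Any of the per-eye fields may
be missing (blinks, tracking loss); missing values are encoded as NaN, never
as sentinel zeros, because (0, 0) is a valid top-left coordinate.

The on-disk format is a plain UTF-8 CSV with columns
``subject_id,image_id,day,timestamp,left_x,left_y,right_x,right_y,
left_pupil,right_pupil`` and empty cells for missing values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GazeRecord",
    "GazeLog",
    "MergedSample",
    "read_gaze_log",
    "read_gaze_logs",
    "write_gaze_log",
    "write_gaze_logs",
    "merge_binocular",
    "merged_samples",
]

CSV_COLUMNS = [
    "subject_id",
    "image_id",
    "day",
    "timestamp",
    "left_x",
    "left_y",
    "right_x",
    "right_y",
    "left_pupil",
    "right_pupil",
]


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


@dataclass(frozen=True)
class GazeRecord:
    """One tracker sample: per-eye gaze coordinates and pupil diameters."""

    timestamp: float
    left_xy: tuple[float, float] | None = None
    right_xy: tuple[float, float] | None = None
    left_pupil: float | None = None
    right_pupil: float | None = None

    def __post_init__(self):
        if self.timestamp < 0 or not math.isfinite(self.timestamp):
            raise ValueError(f"timestamp must be finite and >= 0, got {self.timestamp}")
        for name in ("left_xy", "right_xy"):
            xy = getattr(self, name)
            if xy is not None and not all(math.isfinite(c) for c in xy):
                raise ValueError(f"{name} must be finite when present, got {xy}")
        for name in ("left_pupil", "right_pupil"):
            p = getattr(self, name)
            if p is not None and not (math.isfinite(p) and p > 0):
                raise ValueError(f"{name} must be > 0 when present, got {p}")


@dataclass
class GazeLog:
    """Ordered tracker samples for one (subject, image, day) presentation."""

    subject_id: str
    image_id: str
    day: int = 1
    records: list[GazeRecord] = field(default_factory=list)

    def __post_init__(self):
        ts = [r.timestamp for r in self.records]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("gaze records must be sorted by timestamp")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def all_missing(self) -> bool:
        """True when no record carries a usable gaze point (see merge rule)."""
        return all(r.left_xy is None and r.right_xy is None for r in self.records)


@dataclass(frozen=True)
class MergedSample:
    """A binocular sample merged to a single gaze point and pupil value."""

    xy: tuple[float, float] | None
    pupil: float | None

    @property
    def missing(self) -> bool:
        return self.xy is None and self.pupil is None


def merge_binocular(record: GazeRecord) -> MergedSample:
    """Merge the two eyes of one record into a single sample.

    Both eyes present: per-field arithmetic mean.  One eye present: that
    eye's values pass through.  Neither: the field is missing.  The rule is
    symmetric in the two eyes and applied independently to coordinates and
    pupil diameter.
    """
    if record.left_xy is not None and record.right_xy is not None:
        xy = (
            (record.left_xy[0] + record.right_xy[0]) / 2.0,
            (record.left_xy[1] + record.right_xy[1]) / 2.0,
        )
    else:
        xy = record.left_xy if record.left_xy is not None else record.right_xy

    if record.left_pupil is not None and record.right_pupil is not None:
        pupil = (record.left_pupil + record.right_pupil) / 2.0
    elif record.left_pupil is not None:
        pupil = record.left_pupil
    else:
        pupil = record.right_pupil

    return MergedSample(xy=xy, pupil=pupil)


def merged_samples(log: GazeLog) -> list[MergedSample]:
    """Merge every record of a log; order is preserved."""
    return [merge_binocular(r) for r in log.records]


def _cell(v) -> float | None:
    if pd.isna(v):
        return None
    return float(v)


def _row_to_record(row: pd.Series, row_number: int) -> GazeRecord:
    lx, ly = _cell(row["left_x"]), _cell(row["left_y"])
    rx, ry = _cell(row["right_x"]), _cell(row["right_y"])
    if (lx is None) != (ly is None):
        raise ValueError(f"row {row_number}: left eye has exactly one coordinate")
    if (rx is None) != (ry is None):
        raise ValueError(f"row {row_number}: right eye has exactly one coordinate")
    try:
        return GazeRecord(
            timestamp=float(row["timestamp"]),
            left_xy=None if lx is None else (lx, ly),
            right_xy=None if rx is None else (rx, ry),
            left_pupil=_cell(row["left_pupil"]),
            right_pupil=_cell(row["right_pupil"]),
        )
    except (ValueError, TypeError) as exc:
        raise ValueError(f"row {row_number}: {exc}") from exc


def _frame_to_logs(df: pd.DataFrame, path) -> list[GazeLog]:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    logs = []
    for (subj, img, day), group in df.groupby(
        ["subject_id", "image_id", "day"], sort=False
    ):
        records = [
            _row_to_record(row, int(idx) + 2)  # +2: 1-based, after header
            for idx, row in group.iterrows()
        ]
        ts = [r.timestamp for r in records]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError(
                f"{path}: timestamps not sorted for subject={subj} image={img}"
            )
        logs.append(
            GazeLog(subject_id=str(subj), image_id=str(img), day=int(day), records=records)
        )
    return logs


def read_gaze_logs(path: str | Path) -> list[GazeLog]:
    """Read a gaze CSV that may hold several (subject, image, day) groups."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "image_id": str})
    if df.empty:
        # header-only file: no groups at all
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        return []
    return _frame_to_logs(df, path)


def read_gaze_log(path: str | Path) -> GazeLog:
    """Read a gaze CSV containing one subject-image presentation.

    A header-only file yields an empty log with placeholder identifiers.
    """
    logs = read_gaze_logs(path)
    if not logs:
        return GazeLog(subject_id="", image_id="", day=1, records=[])
    if len(logs) > 1:
        raise ValueError(
            f"{path}: expected a single subject-image log, found {len(logs)}"
        )
    return logs[0]


def _logs_to_frame(logs: Iterable[GazeLog]) -> pd.DataFrame:
    rows = []
    for log in logs:
        for r in log.records:
            rows.append(
                {
                    "subject_id": log.subject_id,
                    "image_id": log.image_id,
                    "day": log.day,
                    "timestamp": r.timestamp,
                    "left_x": np.nan if r.left_xy is None else r.left_xy[0],
                    "left_y": np.nan if r.left_xy is None else r.left_xy[1],
                    "right_x": np.nan if r.right_xy is None else r.right_xy[0],
                    "right_y": np.nan if r.right_xy is None else r.right_xy[1],
                    "left_pupil": np.nan if r.left_pupil is None else r.left_pupil,
                    "right_pupil": np.nan if r.right_pupil is None else r.right_pupil,
                }
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_gaze_log(log: GazeLog, path: str | Path) -> None:
    write_gaze_logs([log], path)


def write_gaze_logs(logs: Sequence[GazeLog], path: str | Path) -> None:
    """Write logs to CSV; empty cells encode missing values."""
    _logs_to_frame(logs).to_csv(path, index=False)
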