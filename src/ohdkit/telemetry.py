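"""Telemetry and tracking I/O plus VOC summarization.

The olfactometer logs total-VOC (tVOC) readings from environmental sensors at
the chamber's primary (odor-delivery) and secondary (positive-pressure)
inlets, together with the five valve states and the active stimulus label, to
CSV at roughly 260 ms intervals.  Sensors report 0-32,768 ppb raw and
saturate near 29,000 ppb.  A commercial video tracker supplies per-frame
centroid pixel coordinates, calibrated in mm per pixel.

This module reads and writes both CSV layouts, aggregates VOC series per
second and per trial, and applies the empty-bottle screening rule used when
selecting odorant bottles.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .paradigm import TrialWindow

__all__ = [
    "TVOC_MAX",
    "TELEMETRY_COLUMNS",
    "TelemetryParseError",
    "TelemetryRecord",
    "TrackingCalibration",
    "TrackingTrace",
    "BottleScreenResult",
    "read_telemetry",
    "write_telemetry",
    "read_tracking",
    "write_tracking",
    "per_second_voc",
    "per_trial_voc",
    "screen_bottle",
]

TVOC_MAX = 32768  # sensor raw reading ceiling, ppb

TELEMETRY_COLUMNS = [
    "time_ms",
    "tvoc_primary_ppb",
    "tvoc_secondary_ppb",
    "valve_clean",
    "valve_1",
    "valve_2",
    "valve_3",
    "valve_4",
    "stimulus",
]


class TelemetryParseError(ValueError):
    """Raised on malformed telemetry/tracking files; carries the 1-based row."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True)
class TelemetryRecord:
    """One telemetry sample: time, both tVOC readings, valve flags, stimulus."""

    time_ms: int
    tvoc_primary_ppb: int
    tvoc_secondary_ppb: int
    valve_states: tuple[int, int, int, int, int]  # clean, odor 1-4
    stimulus: str = ""

    def __post_init__(self) -> None:
        for v in (self.tvoc_primary_ppb, self.tvoc_secondary_ppb):
            if not (0 <= v <= TVOC_MAX):
                raise TelemetryParseError(
                    f"tVOC reading {v} outside sensor range [0, {TVOC_MAX}]")
        if len(self.valve_states) != 5 or any(s not in (0, 1) for s in self.valve_states):
            raise TelemetryParseError(f"valve_states must be 5 binary flags, got {self.valve_states}")


def write_telemetry(records: Iterable[TelemetryRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TELEMETRY_COLUMNS)
        for r in records:
            w.writerow([r.time_ms, r.tvoc_primary_ppb, r.tvoc_secondary_ppb,
                        *r.valve_states, r.stimulus])


def read_telemetry(path: str | Path) -> list[TelemetryRecord]:
    """Parse a telemetry CSV, enforcing the sensor range and monotone time.

    Errors name the offending 1-based data row.  Round-trips exactly with
    :func:`write_telemetry`.
    """
    records: list[TelemetryRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != TELEMETRY_COLUMNS:
            raise TelemetryParseError(
                f"expected header {TELEMETRY_COLUMNS}, got {header}")
        prev_t: int | None = None
        for i, row in enumerate(reader, start=1):
            if len(row) != len(TELEMETRY_COLUMNS):
                raise TelemetryParseError(
                    f"expected {len(TELEMETRY_COLUMNS)} fields, got {len(row)}", row=i)
            try:
                t = int(row[0])
                rec = TelemetryRecord(
                    time_ms=t,
                    tvoc_primary_ppb=int(row[1]),
                    tvoc_secondary_ppb=int(row[2]),
                    valve_states=tuple(int(x) for x in row[3:8]),  # type: ignore[arg-type]
                    stimulus=row[8],
                )
            except TelemetryParseError as e:
                raise TelemetryParseError(str(e), row=i) from None
            except ValueError as e:
                raise TelemetryParseError(f"bad field: {e}", row=i) from None
            if prev_t is not None and t <= prev_t:
                raise TelemetryParseError(
                    f"time_ms not strictly increasing ({prev_t} -> {t})", row=i)
            prev_t = t
            records.append(rec)
    return records


@dataclass(frozen=True)
class TrackingCalibration:
    """Video calibration and primary-end reference geometry.

    ``primary_coord_px`` is the pixel coordinate of the primary end's inner
    face along ``primary_axis``; ``primary_direction`` is +1 if distance from
    the primary end grows with that pixel coordinate, -1 otherwise.
    """

    mm_per_pixel: float
    avg_fps: float
    primary_coord_px: float = 0.0
    primary_axis: str = "x"  # tube axis in the image
    primary_direction: int = 1

    def __post_init__(self) -> None:
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be > 0")
        if self.avg_fps <= 0:
            raise ValueError("avg_fps must be > 0")
        if self.primary_axis not in ("x", "y"):
            raise ValueError("primary_axis must be 'x' or 'y'")
        if self.primary_direction not in (-1, 1):
            raise ValueError("primary_direction must be +/-1")


@dataclass
class TrackingTrace:
    """Per-frame centroid coordinates with calibration.

    Frame indices must be strictly increasing; dropped frames keep their gap
    (no interpolation).  ``time_s`` defaults to ``frame_index / avg_fps``.
    """

    frame_index: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    calibration: TrackingCalibration
    time_s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        n = len(self.frame_index)
        if len(self.x_px) != n or len(self.y_px) != n:
            raise TelemetryParseError("frame/x/y arrays must have equal length")
        if n and np.any(np.diff(self.frame_index) <= 0):
            bad = int(np.argmax(np.diff(self.frame_index) <= 0)) + 2
            raise TelemetryParseError("frame_index not strictly increasing", row=bad)
        if self.time_s is None:
            self.time_s = self.frame_index / self.calibration.avg_fps
        else:
            self.time_s = np.asarray(self.time_s, dtype=float)
            if len(self.time_s) != n:
                raise TelemetryParseError("time_s length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)


def read_tracking(path: str | Path, calibration: TrackingCalibration) -> TrackingTrace:
    """Read a ``frame,time_s,x_px,y_px`` CSV; the time column is optional."""
    df = pd.read_csv(path)
    if "frame" not in df.columns or "x_px" not in df.columns or "y_px" not in df.columns:
        raise TelemetryParseError(
            f"tracking CSV needs columns frame,x_px,y_px (time_s optional); got {list(df.columns)}")
    if df["frame"].duplicated().any():
        dup = int(df["frame"][df["frame"].duplicated()].iloc[0])
        raise TelemetryParseError(f"duplicate frame index {dup}")
    return TrackingTrace(
        frame_index=df["frame"].to_numpy(),
        x_px=df["x_px"].to_numpy(dtype=float),
        y_px=df["y_px"].to_numpy(dtype=float),
        time_s=df["time_s"].to_numpy(dtype=float) if "time_s" in df.columns else None,
        calibration=calibration,
    )


def write_tracking(trace: TrackingTrace, path: str | Path, include_time: bool = True) -> None:
    cols = {"frame": trace.frame_index}
    if include_time:
        cols["time_s"] = trace.time_s
    cols["x_px"] = trace.x_px
    cols["y_px"] = trace.y_px
    pd.DataFrame(cols).to_csv(path, index=False)


def _sensor_column(sensor: str) -> str:
    if sensor not in ("primary", "secondary"):
        raise ValueError("sensor must be 'primary' or 'secondary'")
    return f"tvoc_{sensor}_ppb"


def per_second_voc(records: Sequence[TelemetryRecord], sensor: str = "primary") -> pd.Series:
    """Mean tVOC per whole-second bucket [k, k+1).

    Returns a Series indexed by bucket start second spanning the telemetry's
    full extent; seconds with no samples are NaN (missing, not interpolated).
    """
    col = _sensor_column(sensor)
    if not records:
        raise ValueError("per_second_voc needs non-empty telemetry")
    t = np.array([r.time_ms for r in records], dtype=np.int64)
    v = np.array([getattr(r, col) for r in records], dtype=float)
    sec = t // 1000
    lo, hi = int(sec.min()), int(sec.max())
    sums = np.zeros(hi - lo + 1)
    counts = np.zeros(hi - lo + 1)
    np.add.at(sums, sec - lo, v)
    np.add.at(counts, sec - lo, 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.Series(means, index=pd.RangeIndex(lo, hi + 1, name="second"),
                     name=f"mean_{sensor}_ppb")


def per_trial_voc(
    records: Sequence[TelemetryRecord],
    windows: Sequence[TrialWindow],
    sensor: str = "primary",
) -> pd.DataFrame:
    """Per-trial mean (over in-window per-second values) and peak raw reading.

    A second bucket [k, k+1) belongs to a window iff it lies fully inside
    [t_start, t_end); the peak is the max raw sample inside the window.
    Windows outside the telemetry span get NaN with a warning.
    """
    col = _sensor_column(sensor)
    secs = per_second_voc(records, sensor)
    t_ms = np.array([r.time_ms for r in records], dtype=np.int64)
    raw = np.array([getattr(r, col) for r in records], dtype=float)
    span = (t_ms.min() / 1000.0, t_ms.max() / 1000.0) if len(t_ms) else (np.nan, np.nan)
    rows = []
    for w in windows:
        if w.t_start_s >= span[1] or w.t_end_s <= span[0]:
            warnings.warn(
                f"trial window {w.index} [{w.t_start_s}, {w.t_end_s}) outside telemetry span",
                stacklevel=2)
            mean = peak = np.nan
        else:
            in_win = secs.index[(secs.index >= w.t_start_s)
                                & (secs.index + 1 <= w.t_end_s)]
            vals = secs.loc[in_win].dropna()
            mean = float(vals.mean()) if len(vals) else np.nan
            m = (t_ms / 1000.0 >= w.t_start_s) & (t_ms / 1000.0 < w.t_end_s)
            peak = float(raw[m].max()) if m.any() else np.nan
        rows.append({
            "trial": w.index,
            "stimulus": w.stimulus if w.stimulus is not None else f"V{w.valve_id}",
            "presentation": w.presentation,
            "mean_ppb": mean,
            "peak_ppb": peak,
        })
    return pd.DataFrame(rows, columns=["trial", "stimulus", "presentation",
                                       "mean_ppb", "peak_ppb"])


@dataclass(frozen=True)
class BottleScreenResult:
    passed: bool
    median_ppb: float
    n: int
    low: float
    high: float


def screen_bottle(
    bottle_readings_ppb: Sequence[float],
    low: float = 30.0,
    high: float = 70.0,
) -> BottleScreenResult:
    """Empty-bottle acceptance check before odorant use.

    Bottles whose own tVOC signature (relative to baseline air) is outside
    the accepted band would contaminate stimuli; a bottle passes iff the
    median reading lies in [low, high], bounds inclusive.
    """
    readings = np.asarray(list(bottle_readings_ppb), dtype=float)
    if readings.size == 0:
        raise ValueError("screen_bottle needs at least one reading")
    med = float(np.median(readings))
    return BottleScreenResult(low <= med <= high, med, int(readings.size), low, high)
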