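"""Automatic investigation scoring from centroid tracking.

The chamber is a tube with the odor delivered at one ("primary") end.  A
frame counts as investigation when the subject's centroid lies between 2 cm
and 6 cm from the primary end's inner face *during or after motion toward*
that end; a subject closer than 2 cm is taken to be turning away from the
stimulus and does not count.  At the study's calibration of 0.458 mm/pixel
the zone boundaries are 44 and 132 pixels.

Motion direction is estimated from the windowed displacement of the
distance-to-primary series; stationary frames inherit the most recent
non-stationary direction, so a pause inside the zone after an approach still
counts.  Maximal runs of investigating frames become bouts, converted to
seconds by dividing frame counts by the average frame rate, and bouts are
intersected with trial windows to give per-trial investigation durations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .paradigm import TrialWindow
from .telemetry import TrackingTrace

__all__ = [
    "TOWARD",
    "AWAY",
    "STATIONARY",
    "ZoneRule",
    "InvestigationBout",
    "TrialScore",
    "ScoringError",
    "cm_to_px",
    "distance_from_primary",
    "motion_labels",
    "detect_bouts",
    "frames_to_seconds",
    "score_trials",
    "import_manual_bouts",
    "scores_to_frame",
    "write_scores",
    "read_scores",
]

# Motion label codes (sign matches the distance derivative: toward shrinks it).
TOWARD = -1
STATIONARY = 0
AWAY = 1


class ScoringError(ValueError):
    """Raised for invalid scoring inputs."""


@dataclass(frozen=True)
class ZoneRule:
    """Geometric and kinematic parameters of the investigation rule.

    ``motion_window_frames`` is the span of the centered displacement window
    (about 0.25 s of video by default); displacements smaller than
    ``motion_epsilon_mm`` over that window count as stationary.
    """

    inner_cm: float = 2.0
    outer_cm: float = 6.0
    motion_window_frames: int = 7
    motion_epsilon_mm: float = 2.0
    min_bout_s: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.inner_cm < self.outer_cm):
            raise ScoringError("need 0 < inner_cm < outer_cm")
        if self.motion_window_frames < 1:
            raise ScoringError("motion_window_frames must be >= 1")
        if self.motion_epsilon_mm < 0:
            raise ScoringError("motion_epsilon_mm must be >= 0")

    @classmethod
    def for_fps(cls, fps: float, window_s: float = 0.25, **kwargs) -> "ZoneRule":
        """Rule with the motion window sized to ``window_s`` of video."""
        return cls(motion_window_frames=max(1, round(fps * window_s)), **kwargs)

    @property
    def inner_mm(self) -> float:
        return self.inner_cm * 10.0

    @property
    def outer_mm(self) -> float:
        return self.outer_cm * 10.0

    def inner_px(self, mm_per_pixel: float) -> int:
        return cm_to_px(self.inner_cm, mm_per_pixel)

    def outer_px(self, mm_per_pixel: float) -> int:
        return cm_to_px(self.outer_cm, mm_per_pixel)


def cm_to_px(distance_cm: float, mm_per_pixel: float) -> int:
    """Smallest pixel count covering ``distance_cm`` at the given calibration.

    Ceiling of mm / (mm per pixel): 2 cm -> 44 px and 6 cm -> 132 px at
    0.458 mm/pixel.
    """
    if mm_per_pixel <= 0:
        raise ScoringError("mm_per_pixel must be > 0")
    if distance_cm < 0:
        raise ScoringError("distance_cm must be >= 0")
    return math.ceil(distance_cm * 10.0 / mm_per_pixel - 1e-12)


def distance_from_primary(trace: TrackingTrace) -> np.ndarray:
    """Per-frame distance (mm) from the primary end along the tube axis.

    Signed projection of the centroid onto the tube axis relative to the
    primary end's inner face, clipped at 0 (the face itself).
    """
    cal = trace.calibration
    coord = trace.x_px if cal.primary_axis == "x" else trace.y_px
    d_px = (coord - cal.primary_coord_px) * cal.primary_direction
    return np.clip(d_px, 0.0, None) * cal.mm_per_pixel


def motion_labels(distance_mm: np.ndarray, rule: ZoneRule) -> np.ndarray:
    """Label each frame toward (-1) / stationary (0) / away (+1).

    Uses the displacement over a centered window of ``motion_window_frames``
    frames, truncated at the trace ends: toward if the distance shrank by
    more than ``motion_epsilon_mm``, away if it grew by more, else
    stationary.
    """
    d = np.asarray(distance_mm, dtype=float)
    n = len(d)
    if n < rule.motion_window_frames:
        raise ScoringError(
            f"need at least {rule.motion_window_frames} frames, got {n}")
    w = rule.motion_window_frames
    back, fwd = w // 2, w - w // 2
    idx = np.arange(n)
    lo = np.clip(idx - back, 0, n - 1)
    hi = np.clip(idx + fwd, 0, n - 1)
    disp = d[hi] - d[lo]
    labels = np.zeros(n, dtype=np.int8)
    labels[disp < -rule.motion_epsilon_mm] = TOWARD
    labels[disp > rule.motion_epsilon_mm] = AWAY
    return labels


def _effective_direction(labels: np.ndarray) -> np.ndarray:
    """Forward-fill non-stationary labels; leading stationary stays 0."""
    lab = np.asarray(labels, dtype=np.int8)
    moving = lab != STATIONARY
    # index of last moving frame at or before each position (-1 if none)
    last = np.where(moving, np.arange(len(lab)), -1)
    last = np.maximum.accumulate(last)
    eff = np.where(last >= 0, lab[np.maximum(last, 0)], STATIONARY)
    return eff.astype(np.int8)


@dataclass(frozen=True)
class InvestigationBout:
    start_s: float
    end_s: float
    source: str = "auto"  # auto | manual

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ScoringError(f"bout end {self.end_s} <= start {self.start_s}")
        if self.source not in ("auto", "manual"):
            raise ScoringError(f"bout source must be auto/manual, got {self.source!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def investigating_frames(trace: TrackingTrace, rule: ZoneRule) -> np.ndarray:
    """Boolean per-frame mask of the investigation rule.

    A frame investigates iff its distance from the primary end lies in
    [inner, outer] and its effective direction (stationary frames inherit
    the last non-stationary label) is toward.  Frames nearer than the inner
    boundary (turning away) or beyond the outer boundary never count.
    """
    d = distance_from_primary(trace)
    eff = _effective_direction(motion_labels(d, rule))
    in_zone = (d >= rule.inner_mm) & (d <= rule.outer_mm)
    return in_zone & (eff == TOWARD)


def detect_bouts(trace: TrackingTrace, rule: ZoneRule) -> list[InvestigationBout]:
    """Maximal runs of investigating frames, as timestamped bouts.

    A bout spans from its first frame's time to one frame-interval past its
    last frame, so an n-frame bout lasts n/avg_fps seconds.  Bouts shorter
    than ``min_bout_s`` are dropped.
    """
    mask = investigating_frames(trace, rule)
    if not mask.any():
        return []
    dt = 1.0 / trace.calibration.avg_fps
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1  # inclusive index
    bouts = []
    for i0, i1 in zip(starts, ends):
        b = InvestigationBout(float(trace.time_s[i0]),
                              float(trace.time_s[i1]) + dt, "auto")
        if b.duration_s >= rule.min_bout_s:
            bouts.append(b)
    return bouts


def frames_to_seconds(n_frames: int, avg_fps: float) -> float:
    """Convert a frame count to seconds via the average frame rate."""
    if avg_fps <= 0:
        raise ScoringError("avg_fps must be > 0")
    return n_frames / avg_fps


@dataclass(frozen=True)
class TrialScore:
    """Total investigation duration for one trial of one session."""

    subject: str
    session: str
    stimulus: str
    presentation: int
    duration_s: float
    method: str = "auto"  # auto | manual

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise ScoringError("duration_s must be >= 0")


def _check_non_overlapping(bouts: Sequence[InvestigationBout]) -> None:
    for a, b in zip(bouts, bouts[1:]):
        if b.start_s < a.end_s:
            raise ScoringError(
                f"overlapping bouts: [{a.start_s}, {a.end_s}) and [{b.start_s}, {b.end_s})")


def score_trials(
    bouts: Sequence[InvestigationBout],
    windows: Sequence[TrialWindow],
    subject: str,
    session: str = "1",
    method: str = "auto",
) -> list[TrialScore]:
    """Per-trial investigation time: sum of bout/window intersections.

    Bouts straddling a window boundary contribute their overlap to each
    side.  Bouts must be time-ordered and non-overlapping.
    """
    ordered = sorted(bouts, key=lambda b: b.start_s)
    _check_non_overlapping(ordered)
    scores = []
    for w in windows:
        total = 0.0
        for b in ordered:
            total += max(0.0, min(b.end_s, w.t_end_s) - max(b.start_s, w.t_start_s))
        stim = w.stimulus if w.stimulus is not None else f"V{w.valve_id}"
        pres = w.presentation if w.presentation is not None else _nth_for_valve(windows, w)
        scores.append(TrialScore(subject, session, stim, pres,
                                 min(total, w.duration_s), method))
    return scores


def _nth_for_valve(windows: Sequence[TrialWindow], w: TrialWindow) -> int:
    return sum(1 for v in windows if v.valve_id == w.valve_id and v.index <= w.index)


def import_manual_bouts(annotation_rows: Iterable[tuple[float, float]]) -> list[InvestigationBout]:
    """Normalize manually scored (start_s, end_s) rows into bouts.

    Rows are sorted and overlapping or touching intervals merged, so manual
    annotations flow through the same :func:`score_trials` path as automatic
    bouts.  A row with end <= start is rejected.
    """
    rows = sorted(annotation_rows)
    for i, (s, e) in enumerate(rows):
        if e <= s:
            raise ScoringError(f"annotation row {i}: end {e} <= start {s}")
    merged: list[list[float]] = []
    for s, e in rows:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [InvestigationBout(s, e, "manual") for s, e in merged]


SCORE_COLUMNS = ["subject", "session", "stimulus", "presentation", "method", "duration_s"]


def scores_to_frame(scores: Sequence[TrialScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"subject": s.subject, "session": s.session, "stimulus": s.stimulus,
          "presentation": s.presentation, "method": s.method,
          "duration_s": s.duration_s} for s in scores],
        columns=SCORE_COLUMNS,
    )


def write_scores(scores: Sequence[TrialScore] | pd.DataFrame, path: str | Path) -> None:
    df = scores if isinstance(scores, pd.DataFrame) else scores_to_frame(scores)
    df.to_csv(path, index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject": str, "session": str})
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ScoringError(f"scores CSV missing columns {missing}")
    return df
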