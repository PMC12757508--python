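"""Synthetic OHD sessions: valve logs, VOC telemetry, trajectories, truth.

Real sessions produce a valve event log, tVOC telemetry at both chamber
inlets, and a centroid tracking trace.  This module generates all three with
known ground truth so every pipeline stage is testable without the study's
raw video.

VOC kinetics are first-order: while a valve is ON the primary-inlet
concentration relaxes toward that stimulus' plateau with time constant
``tau_rise_s``; while OFF it decays toward baseline with ``tau_decay_s``.
Readings add Gaussian sensor noise, round to integer ppb, and saturate at
the sensor cap (~29,000 ppb within the 0-32,768 ppb range).

The behaving subject is a discrete-time mean-reverting (Ornstein-Uhlenbeck)
walk along the tube axis.  Each second the walk's target is redrawn: the
attraction point near the odor port with probability proportional to the
trial's effective salience ``salience_s * r**(p-1)`` (salience decays by the
habituation ratio ``r`` at each repeat presentation), otherwise a rest point
far from the port.  Ground-truth bouts come from applying the same
geometric/direction scoring rule to the un-quantized trajectory, so scorer
validation tests the implementation rather than the behavioral model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .paradigm import (
    CLEAN_VALVE,
    ParadigmConfig,
    SessionSchedule,
    TrialWindow,
    ValveEvent,
    build_ohd_schedule,
    default_paradigm,
    schedule_to_valve_events,
    windows_from_schedule,
    write_valve_events,
)
from .scoring import InvestigationBout, ZoneRule, detect_bouts, score_trials
from .telemetry import (
    TVOC_MAX,
    TelemetryRecord,
    TrackingCalibration,
    TrackingTrace,
    write_telemetry,
    write_tracking,
)

__all__ = [
    "VocParams",
    "AgentParams",
    "SessionFixture",
    "simulate_voc_telemetry",
    "simulate_agent_trace",
    "true_effect_table",
    "generate_session",
    "simulate_cohort",
]

# Fixed offsets deriving per-component streams from one master seed.
_SEED_VOC = 1
_SEED_AGENT = 2
_SEED_SUBJECT = 3


@dataclass(frozen=True)
class VocParams:
    """First-order VOC kinetics and sensor characteristics.

    ``plateau_ppb`` maps valve id -> steady-state concentration; odorant
    valves default to 11,500 ppb (stimuli are diluted to peak in the
    10,000-13,000 ppb range) and the clean valve to baseline room air.
    """

    baseline_ppb: float = 50.0
    plateau_ppb: Mapping[int, float] = field(
        default_factory=lambda: {1: 11_500.0, 2: 11_500.0, 3: 11_500.0, 4: 11_500.0})
    tau_rise_s: float = 10.0
    tau_decay_s: float = 20.0
    noise_sd_ppb: float = 5.0
    cap_ppb: float = 29_000.0
    sensor_max_ppb: float = float(TVOC_MAX)
    sample_interval_ms: int = 260

    def __post_init__(self) -> None:
        if self.tau_rise_s <= 0 or self.tau_decay_s <= 0:
            raise ValueError("time constants must be > 0")
        if not (0 <= self.baseline_ppb <= self.cap_ppb <= self.sensor_max_ppb):
            raise ValueError("need 0 <= baseline <= cap <= sensor_max")
        for v, p in self.plateau_ppb.items():
            if not (self.baseline_ppb < p <= self.sensor_max_ppb):
                raise ValueError(f"plateau for valve {v} must lie in (baseline, sensor_max]")

    def plateau_for(self, valve_id: int) -> float:
        if valve_id == CLEAN_VALVE:
            return self.baseline_ppb
        return float(self.plateau_ppb.get(valve_id, self.baseline_ppb))


@dataclass(frozen=True)
class AgentParams:
    """Mean-reverting walk parameters for the synthetic subject.

    Distances are mm from the primary (odor) end of the 6-inch tube.  The
    attraction point sits inside the 2-6 cm investigation zone; the rest
    point sits outside it.  ``attract_gain`` converts effective salience to
    the per-second probability of targeting the attraction point (clipped
    at 1).
    """

    tube_length_mm: float = 152.4
    salience: Mapping[str, float] = field(
        default_factory=lambda: {"CLN": 0.05, "NSA": 1.0, "NSB": 1.0, "SOC": 2.5})
    habituation_ratio: float = 0.6
    attract_gain: float = 0.3
    ou_theta: float = 1.5  # mean-reversion rate, 1/s
    ou_sigma: float = 10.0  # diffusion, mm/sqrt(s); rest-state spread ~6 mm
    attract_point_mm: float = 30.0
    rest_point_mm: float = 90.0
    fps: float = 30.0
    mm_per_pixel: float = 0.458
    tube_center_y_px: float = 80.0
    lateral_jitter_px: float = 1.5

    def __post_init__(self) -> None:
        if not (0 < self.attract_point_mm < self.tube_length_mm):
            raise ValueError("attract_point_mm must lie inside the tube")
        if not (0 < self.habituation_ratio <= 1):
            raise ValueError("habituation_ratio must be in (0, 1]")
        if self.ou_theta <= 0 or self.ou_sigma < 0 or self.fps <= 0:
            raise ValueError("ou_theta, fps must be > 0 and ou_sigma >= 0")
        if any(w < 0 for w in self.salience.values()):
            raise ValueError("salience weights must be >= 0")

    def effective_salience(self, label: str, presentation: int,
                           category: str = "nonsocial") -> float:
        """Salience after habituation decay.

        Habituation is odor-specific: repeated presentations of an odorant
        multiply its salience by ``habituation_ratio`` each time, while the
        clean-air control only ever elicits odor-independent baseline
        exploration, which does not decay.
        """
        w = self.salience.get(label, 0.0)
        if category == "clean":
            return w
        return w * self.habituation_ratio ** (presentation - 1)

    def attract_probability(self, label: str, presentation: int,
                            category: str = "nonsocial") -> float:
        return min(1.0, self.attract_gain
                   * self.effective_salience(label, presentation, category))


def _open_valve_segments(events: Sequence[ValveEvent], end_s: float) -> list[tuple[float, float, int]]:
    """(start, end, open valve) spans reconstructed from the event log."""
    segs: list[tuple[float, float, int]] = []
    current: int | None = None
    t0 = 0.0
    i, n = 0, len(events)
    while i < n:
        t = events[i].time_s
        opened = None
        while i < n and events[i].time_s == t:
            if events[i].state == "open":
                opened = events[i].valve_id
            i += 1
        if opened is not None and opened != current:
            if current is not None and t > t0:
                segs.append((t0, t, current))
            current, t0 = opened, t
    if current is not None and end_s > t0:
        segs.append((t0, end_s, current))
    return segs


def simulate_voc_telemetry(
    events: Sequence[ValveEvent],
    windows: Sequence[TrialWindow],
    params: VocParams = VocParams(),
    seed: int = 0,
) -> list[TelemetryRecord]:
    """Generate telemetry records for a validated valve log.

    The primary sensor follows the first-order rise/decay kinetics described
    in the module docstring; the secondary sensor (positive-pressure inlet)
    stays at baseline plus noise.  Readings are rounded, floored at 0, and
    capped at ``cap_ppb``.  Deterministic given ``seed``.
    """
    end_s = max((w.t_end_s for w in windows), default=0.0)
    if not events or end_s <= 0:
        return []
    segs = _open_valve_segments(events, end_s)
    rng = np.random.default_rng([seed, _SEED_VOC])
    dt_ms = params.sample_interval_ms
    times_ms = np.arange(0, int(end_s * 1000), dt_ms, dtype=np.int64)

    records: list[TelemetryRecord] = []
    c = params.baseline_ppb  # concentration at segment start
    seg_i = 0
    seg_start, seg_c0 = 0.0, params.baseline_ppb
    for t_ms in times_ms:
        t = t_ms / 1000.0
        while seg_i + 1 < len(segs) and t >= segs[seg_i][1]:
            # advance concentration analytically to the segment boundary
            s0, s1, v = segs[seg_i]
            tau = params.tau_rise_s if v != CLEAN_VALVE else params.tau_decay_s
            target = params.plateau_for(v)
            seg_c0 = target + (seg_c0 - target) * math.exp(-(s1 - max(s0, seg_start)) / tau)
            seg_i += 1
            seg_start = segs[seg_i][0]
        s0, s1, v = segs[seg_i]
        tau = params.tau_rise_s if v != CLEAN_VALVE else params.tau_decay_s
        target = params.plateau_for(v)
        c = target + (seg_c0 - target) * math.exp(-(t - max(s0, seg_start)) / tau)
        noise_p, noise_s = (rng.normal(0.0, params.noise_sd_ppb, size=2)
                            if params.noise_sd_ppb > 0 else (0.0, 0.0))
        primary = int(min(round(c + noise_p), params.cap_ppb))
        secondary = int(min(round(params.baseline_ppb + noise_s), params.cap_ppb))
        flags = [0, 0, 0, 0, 0]
        flags[v if v <= 4 else 0] = 1
        stim = ""
        for w in windows:
            if w.t_start_s <= t < w.t_end_s:
                stim = w.stimulus or f"V{w.valve_id}"
                break
        records.append(TelemetryRecord(
            time_ms=int(t_ms),
            tvoc_primary_ppb=max(0, primary),
            tvoc_secondary_ppb=max(0, secondary),
            valve_states=tuple(flags),  # type: ignore[arg-type]
            stimulus=stim,
        ))
    return records


def simulate_agent_trace(
    schedule: SessionSchedule,
    params: AgentParams = AgentParams(),
    zone: ZoneRule | None = None,
    seed: int = 0,
) -> tuple[TrackingTrace, list[InvestigationBout]]:
    """Simulate the subject's centroid trajectory plus ground-truth bouts.

    Euler-Maruyama steps of the mean-reverting walk at the video frame rate,
    reflected into [0, tube_length].  The exported trace is in integer
    pixels (with lateral jitter on the off-axis coordinate); ground-truth
    bouts are detected on the exact (un-quantized) trajectory with the same
    ``zone`` rule the scorer uses.  Deterministic given ``seed``.
    """
    zone = zone or ZoneRule.for_fps(params.fps)
    rng = np.random.default_rng([seed, _SEED_AGENT])
    dt = 1.0 / params.fps
    n = int(round(schedule.total_duration_s * params.fps))
    a = params.ou_theta * dt
    noise = rng.normal(0.0, params.ou_sigma * math.sqrt(dt), size=n)

    # Per-second attraction target, per the active trial's effective salience.
    n_sec = int(math.ceil(schedule.total_duration_s))
    p_attract = np.zeros(n_sec)
    for tr in schedule.trials:
        s0, s1 = int(tr.t_start_s), int(min(tr.t_end_s, n_sec))
        p_attract[s0:s1] = params.attract_probability(
            tr.stimulus.label, tr.presentation, tr.stimulus.category)
    draws = rng.random(n_sec)
    targets_by_sec = np.where(draws < p_attract, params.attract_point_mm,
                              params.rest_point_mm)

    x = np.empty(n)
    xi = params.rest_point_mm
    L = params.tube_length_mm
    for k in range(n):
        mu = targets_by_sec[min(int(k * dt), n_sec - 1)]
        xi = xi + a * (mu - xi) + noise[k]
        if xi < 0.0:
            xi = -xi
        if xi > L:
            xi = 2 * L - xi
        x[k] = xi

    frame_index = np.arange(n)
    cal = TrackingCalibration(mm_per_pixel=params.mm_per_pixel, avg_fps=params.fps,
                              primary_coord_px=0.0, primary_axis="x",
                              primary_direction=1)
    exact = TrackingTrace(frame_index=frame_index,
                          x_px=x / params.mm_per_pixel,
                          y_px=np.full(n, params.tube_center_y_px),
                          calibration=cal)
    truth = detect_bouts(exact, zone)

    y_jitter = rng.normal(0.0, params.lateral_jitter_px, size=n)
    trace = TrackingTrace(
        frame_index=frame_index,
        x_px=np.round(x / params.mm_per_pixel),
        y_px=np.round(params.tube_center_y_px + y_jitter),
        calibration=cal,
    )
    return trace, truth


def true_effect_table(
    agent_params: AgentParams,
    paradigm_config: ParadigmConfig,
) -> pd.DataFrame:
    """Expected effective salience per (stimulus, presentation).

    ``salience * r**(p-1)`` predicts effect signs: habituation differences
    are negative iff r < 1 (for nonzero salience), and the dishabituation
    difference into a stimulus is positive iff its first-presentation
    salience exceeds the previous stimulus' final-presentation salience.
    """
    rows = []
    for stim in paradigm_config.stimuli:
        for p in range(1, paradigm_config.presentations_per_stimulus + 1):
            rows.append({
                "stimulus": stim.label,
                "category": stim.category,
                "presentation": p,
                "salience_effective": agent_params.effective_salience(
                    stim.label, p, stim.category),
                "p_attract": agent_params.attract_probability(
                    stim.label, p, stim.category),
            })
    return pd.DataFrame(rows)


@dataclass
class SessionFixture:
    """In-memory handles plus on-disk paths for one generated session."""

    schedule: SessionSchedule
    events: list[ValveEvent]
    telemetry: list[TelemetryRecord]
    trace: TrackingTrace
    truth_bouts: list[InvestigationBout]
    truth_table: pd.DataFrame
    seed: int
    paths: dict[str, Path] = field(default_factory=dict)


def generate_session(
    paradigm_config: ParadigmConfig | None = None,
    voc_params: VocParams = VocParams(),
    agent_params: AgentParams = AgentParams(),
    zone: ZoneRule | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> SessionFixture:
    """Generate one complete session; optionally write the five fixture files.

    With ``outdir`` set, writes ``events.csv``, ``telemetry.csv``,
    ``trace.csv``, ``truth_bouts.csv``, and ``truth_params.json`` (parameter
    values and the seeds used).  All time bases start at 0 and the fixture
    passes the package's validators.  Byte-identical given the same seed.
    """
    config = paradigm_config or default_paradigm()
    schedule = build_ohd_schedule(config)
    events = schedule_to_valve_events(schedule)
    windows = windows_from_schedule(schedule)
    telemetry = simulate_voc_telemetry(events, windows, voc_params, seed)
    trace, truth = simulate_agent_trace(schedule, agent_params, zone, seed)
    fixture = SessionFixture(
        schedule=schedule, events=events, telemetry=telemetry, trace=trace,
        truth_bouts=truth, truth_table=true_effect_table(agent_params, config),
        seed=seed,
    )
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "events": out / "events.csv",
            "telemetry": out / "telemetry.csv",
            "trace": out / "trace.csv",
            "truth_bouts": out / "truth_bouts.csv",
            "truth_params": out / "truth_params.json",
        }
        write_valve_events(events, paths["events"])
        write_telemetry(telemetry, paths["telemetry"])
        write_tracking(trace, paths["trace"])
        pd.DataFrame([{"start_s": b.start_s, "end_s": b.end_s} for b in truth]
                     ).to_csv(paths["truth_bouts"], index=False)
        manifest = {
            "seed": seed,
            "component_seeds": {"voc": [seed, _SEED_VOC], "agent": [seed, _SEED_AGENT]},
            "paradigm": config.to_dict(),
            "voc_params": {**asdict(voc_params),
                           "plateau_ppb": dict(voc_params.plateau_ppb)},
            "agent_params": {**asdict(agent_params),
                             "salience": dict(agent_params.salience)},
            "true_effect_table": fixture.truth_table.to_dict(orient="records"),
        }
        paths["truth_params"].write_text(json.dumps(manifest, indent=2))
        fixture.paths = paths
    return fixture


def simulate_cohort(
    n_subjects: int = 24,
    paradigm_config: ParadigmConfig | None = None,
    agent_params: AgentParams = AgentParams(),
    zone: ZoneRule | None = None,
    seed: int = 0,
    session: str = "1",
) -> pd.DataFrame:
    """Simulate and score a cohort, returning the long trial-score table.

    Each subject gets an independent seed derived from the master seed, a
    simulated trajectory, and automatic scoring of that trajectory (ground
    truth is not used here: this is the full pipeline end to end).
    """
    config = paradigm_config or default_paradigm()
    schedule = build_ohd_schedule(config)
    windows = windows_from_schedule(schedule)
    zone = zone or ZoneRule.for_fps(agent_params.fps)
    frames = []
    from .scoring import scores_to_frame  # local import to avoid cycle at module load
    for i in range(n_subjects):
        trace, _ = simulate_agent_trace(schedule, agent_params, zone,
                                        seed=int(np.random.default_rng(
                                            [seed, _SEED_SUBJECT, i]).integers(2 ** 31)))
        bouts = detect_bouts(trace, zone)
        scores = score_trials(bouts, windows, subject=f"S{i + 1:02d}",
                              session=session, method="auto")
        frames.append(scores_to_frame(scores))
    return pd.concat(frames, ignore_index=True)
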