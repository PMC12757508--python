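"""Stimulus scheduling and valve-event bookkeeping for the olfactory
habituation/dishabituation (OHD) task.

An OHD session on an automated olfactometer presents each odor stimulus in a
block of consecutive trials.  Each trial turns the stimulus valve ON for
``on_s`` seconds and then OFF for ``off_s`` seconds while clean air flushes
the lines.  The apparatus routes air through exactly one valve at any instant
— either the normally-open clean-air valve (id 0) or one of up to four
odorant valves (ids 1-4) — so the session timeline can be reconstructed from
the valve event log alone.

This module builds the trial schedule, converts it to/from a timestamped
valve event log, validates valve exclusivity, and segments a log into
per-trial analysis windows.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "ParadigmError",
    "StimulusSpec",
    "ParadigmConfig",
    "Trial",
    "SessionSchedule",
    "ValveEvent",
    "ValveViolation",
    "TrialWindow",
    "CLEAN_VALVE",
    "default_paradigm",
    "noise_habituation_config",
    "build_ohd_schedule",
    "schedule_to_valve_events",
    "validate_valve_events",
    "trial_windows",
    "windows_from_schedule",
    "read_valve_events",
    "write_valve_events",
]

CLEAN_VALVE = 0
CATEGORIES = ("clean", "nonsocial", "social")


class ParadigmError(ValueError):
    """Raised for invalid paradigm configurations or valve logs."""


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus: a label, the valve that delivers it, and its category.

    Valve 0 is the clean-air valve; the clean control "stimulus" is delivered
    by leaving valve 0 open, so ``category == "clean"`` iff ``valve_id == 0``.
    """

    label: str
    valve_id: int
    category: str

    def __post_init__(self) -> None:
        if not self.label:
            raise ParadigmError("stimulus label must be non-empty")
        if not (0 <= self.valve_id <= 4):
            raise ParadigmError(f"valve_id must be 0-4, got {self.valve_id}")
        if self.category not in CATEGORIES:
            raise ParadigmError(f"unknown category {self.category!r}")
        if (self.category == "clean") != (self.valve_id == CLEAN_VALVE):
            raise ParadigmError(
                "clean stimuli and valve 0 must coincide "
                f"(got {self.label}: valve {self.valve_id}, {self.category})"
            )


@dataclass(frozen=True)
class ParadigmConfig:
    """Session paradigm: stimulus order, trial counts, and timing (seconds)."""

    stimuli: tuple[StimulusSpec, ...]
    presentations_per_stimulus: int = 3
    on_s: float = 60.0
    off_s: float = 60.0
    chamber_habituation_s: float = 300.0
    noise_habituation_trials: int = 6

    def __post_init__(self) -> None:
        object.__setattr__(self, "stimuli", tuple(self.stimuli))
        if not self.stimuli:
            raise ParadigmError("paradigm needs at least one stimulus")
        valves = [s.valve_id for s in self.stimuli]
        if len(set(valves)) != len(valves):
            raise ParadigmError("valve_id must be unique within a paradigm")
        labels = [s.label for s in self.stimuli]
        if len(set(labels)) != len(labels):
            raise ParadigmError("stimulus labels must be unique")
        if self.presentations_per_stimulus < 1:
            raise ParadigmError("presentations_per_stimulus must be >= 1")
        if self.on_s <= 0:
            raise ParadigmError("on_s must be > 0")
        if self.off_s < 0:
            raise ParadigmError("off_s must be >= 0")
        if self.noise_habituation_trials < 0:
            raise ParadigmError("noise_habituation_trials must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "ParadigmConfig":
        stimuli = tuple(
            StimulusSpec(s["label"], int(s["valve_id"]), s["category"])
            for s in d["stimuli"]
        )
        kwargs = {k: d[k] for k in (
            "presentations_per_stimulus", "on_s", "off_s",
            "chamber_habituation_s", "noise_habituation_trials") if k in d}
        return cls(stimuli=stimuli, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParadigmConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "stimuli": [
                {"label": s.label, "valve_id": s.valve_id, "category": s.category}
                for s in self.stimuli
            ],
            "presentations_per_stimulus": self.presentations_per_stimulus,
            "on_s": self.on_s,
            "off_s": self.off_s,
            "chamber_habituation_s": self.chamber_habituation_s,
            "noise_habituation_trials": self.noise_habituation_trials,
        }


def default_paradigm() -> ParadigmConfig:
    """The standard 4-stimulus testing paradigm.

    Clean-air control (CLN), two nonsocial odors (NSA, NSB), and a same-sex
    social (urine) odor (SOC), three presentations each at 60 s ON / 60 s OFF:
    12 trials, 24 min.  The social stimulus is reserved for the last odorant
    valve so social odors never share lines with nonsocial ones.
    """
    return ParadigmConfig(
        stimuli=(
            StimulusSpec("CLN", 0, "clean"),
            StimulusSpec("NSA", 1, "nonsocial"),
            StimulusSpec("NSB", 2, "nonsocial"),
            StimulusSpec("SOC", 4, "social"),
        )
    )


def noise_habituation_config(base: ParadigmConfig | None = None) -> ParadigmConfig:
    """Clean-valve-only phase habituating subjects to valve noise and airflow."""
    base = base or default_paradigm()
    return ParadigmConfig(
        stimuli=(StimulusSpec("CLN", 0, "clean"),),
        presentations_per_stimulus=base.noise_habituation_trials,
        on_s=base.on_s,
        off_s=base.off_s,
        chamber_habituation_s=base.chamber_habituation_s,
        noise_habituation_trials=base.noise_habituation_trials,
    )


@dataclass(frozen=True)
class Trial:
    stimulus: StimulusSpec
    presentation: int  # 1-based within its stimulus block
    t_start_s: float
    t_on_end_s: float
    t_end_s: float


@dataclass(frozen=True)
class SessionSchedule:
    trials: tuple[Trial, ...]
    total_duration_s: float


def build_ohd_schedule(config: ParadigmConfig) -> SessionSchedule:
    """Lay out one trial per (stimulus, presentation), contiguous from t=0.

    Stimuli appear in configured order with their presentations consecutive,
    so a 4-stimulus, 3-presentation, 60/60 s paradigm yields 12 trials and
    1440 s (24 min) total.
    """
    trials: list[Trial] = []
    t = 0.0
    period = config.on_s + config.off_s
    for stim in config.stimuli:
        for p in range(1, config.presentations_per_stimulus + 1):
            trials.append(Trial(stim, p, t, t + config.on_s, t + period))
            t += period
    return SessionSchedule(trials=tuple(trials), total_duration_s=t)


@dataclass(frozen=True, order=True)
class ValveEvent:
    time_s: float
    valve_id: int
    state: str  # "open" | "closed"

    def __post_init__(self) -> None:
        if self.state not in ("open", "closed"):
            raise ParadigmError(f"valve state must be open/closed, got {self.state!r}")
        if not (0 <= self.valve_id <= 4):
            raise ParadigmError(f"valve_id must be 0-4, got {self.valve_id}")


def schedule_to_valve_events(schedule: SessionSchedule) -> list[ValveEvent]:
    """Emit the valve log realizing a schedule under the exclusivity rule.

    During a trial's ON phase its odorant valve is open; at all other times
    the clean valve (0) is open.  Clean-stimulus trials therefore produce no
    transitions of their own.  At every switch the previously open valve is
    closed and the new one opened at the same timestamp; the log starts at
    t=0 with the session's initial state.
    """
    # Piecewise open-valve timeline, merging consecutive equal-valve spans.
    segments: list[tuple[float, int]] = []  # (start time, open valve)

    def push(t: float, valve: int) -> None:
        if segments and segments[-1][1] == valve:
            return
        segments.append((t, valve))

    t_cursor = 0.0
    for trial in schedule.trials:
        if trial.t_start_s > t_cursor:
            push(t_cursor, CLEAN_VALVE)
        push(trial.t_start_s, trial.stimulus.valve_id)
        push(trial.t_on_end_s, CLEAN_VALVE)
        t_cursor = trial.t_end_s
    if not segments:
        segments.append((0.0, CLEAN_VALVE))

    events: list[ValveEvent] = []
    first_t, first_v = segments[0]
    if first_v == CLEAN_VALVE:
        events.append(ValveEvent(first_t, CLEAN_VALVE, "open"))
    else:
        # Clean valve is normally open: record it closing as the odor opens.
        events.append(ValveEvent(first_t, CLEAN_VALVE, "closed"))
        events.append(ValveEvent(first_t, first_v, "open"))
    prev_v = first_v
    for t, v in segments[1:]:
        events.append(ValveEvent(t, prev_v, "closed"))
        events.append(ValveEvent(t, v, "open"))
        prev_v = v
    return events


@dataclass(frozen=True)
class ValveViolation:
    time_s: float
    kind: str  # "none_open" | "multiple_open" | "redundant"
    detail: str


def _check_ordered(events: Sequence[ValveEvent]) -> None:
    for a, b in zip(events, events[1:]):
        if b.time_s < a.time_s:
            raise ParadigmError(
                f"valve events out of order at t={b.time_s} (after t={a.time_s})"
            )


def validate_valve_events(events: Sequence[ValveEvent]) -> list[ValveViolation]:
    """Check the single-open-valve invariant over a time-ordered event log.

    Replays the log and reports every instant at which zero or two-or-more
    valves are open.  Events sharing a timestamp are applied together before
    the state is checked, so a simultaneous close/open handover is legal.
    """
    _check_ordered(events)
    violations: list[ValveViolation] = []
    open_valves: set[int] = set()
    i, n = 0, len(events)
    while i < n:
        t = events[i].time_s
        while i < n and events[i].time_s == t:
            ev = events[i]
            if ev.state == "open":
                open_valves.add(ev.valve_id)
            else:
                open_valves.discard(ev.valve_id)
            i += 1
        if len(open_valves) == 0:
            violations.append(ValveViolation(t, "none_open", "no valve open"))
        elif len(open_valves) > 1:
            violations.append(ValveViolation(
                t, "multiple_open",
                "valves open simultaneously: " + ",".join(map(str, sorted(open_valves)))))
    return violations


@dataclass(frozen=True)
class TrialWindow:
    """Per-trial analysis window: valve onset to the next trial onset."""

    index: int  # 0-based trial index within the session
    valve_id: int
    t_start_s: float
    t_on_end_s: float
    t_end_s: float
    stimulus: str | None = None
    presentation: int | None = None

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s


def windows_from_schedule(schedule: SessionSchedule) -> list[TrialWindow]:
    """Trial windows straight from the schedule, carrying stimulus labels.

    Preferred when the schedule is known: clean-stimulus trials leave no
    trace in the valve log, so the schedule is the unambiguous source.
    """
    return [
        TrialWindow(i, tr.stimulus.valve_id, tr.t_start_s, tr.t_on_end_s,
                    tr.t_end_s, tr.stimulus.label, tr.presentation)
        for i, tr in enumerate(schedule.trials)
    ]


def trial_windows(
    events: Sequence[ValveEvent],
    on_s: float,
    off_s: float,
    session_end_s: float | None = None,
) -> list[TrialWindow]:
    """Segment a validated valve log into per-trial windows.

    Odorant-valve onsets anchor the segmentation: each window runs from one
    onset to the next (ON + OFF, nominally ``on_s + off_s``), which absorbs
    small onset jitter.  Clean-stimulus trials emit no transitions, so gaps
    of roughly k multiples of the trial period before, between, or (when
    ``session_end_s`` is given) after odor anchors are filled with evenly
    divided clean-valve windows.

    Raises :class:`ParadigmError` on overlapping ON episodes.
    """
    _check_ordered(events)
    if any(v.kind == "multiple_open" for v in validate_valve_events(events)):
        raise ParadigmError("overlapping valve ON episodes in log")
    period = on_s + off_s
    onsets = [(e.time_s, e.valve_id) for e in events
              if e.valve_id != CLEAN_VALVE and e.state == "open"]
    closes = {  # first close time after each onset, per valve
        (t, v): next((e.time_s for e in events
                      if e.valve_id == v and e.state == "closed" and e.time_s > t),
                     None)
        for t, v in onsets
    }
    windows: list[TrialWindow] = []

    def add_clean(t0: float, t1: float, n: int) -> None:
        if n <= 0:
            return
        width = (t1 - t0) / n
        for j in range(n):
            s = t0 + j * width
            windows.append(TrialWindow(len(windows), CLEAN_VALVE, s,
                                       s + min(on_s, width), s + width))

    if not onsets:
        if session_end_s is not None and session_end_s > 0 and events:
            add_clean(0.0, session_end_s, max(1, round(session_end_s / period)))
        return windows

    first_t = onsets[0][0]
    add_clean(0.0, first_t, round(first_t / period))
    for k, (t, v) in enumerate(onsets):
        if k + 1 < len(onsets):
            gap = onsets[k + 1][0] - t
            n_seg = max(1, round(gap / period))
            end = t + gap / n_seg
        else:
            gap = (session_end_s - t) if session_end_s is not None else period
            n_seg = max(1, round(gap / period))
            end = t + gap / n_seg
        close = closes.get((t, v))
        t_on_end = close if close is not None and close <= end else t + on_s
        windows.append(TrialWindow(len(windows), v, t, t_on_end, end))
        if k + 1 < len(onsets):
            add_clean(end, onsets[k + 1][0], n_seg - 1)
        elif session_end_s is not None:
            add_clean(end, session_end_s, n_seg - 1)
    return windows


def write_valve_events(events: Iterable[ValveEvent], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "valve_id", "state"])
        for e in events:
            w.writerow([repr(e.time_s), e.valve_id, e.state])


def read_valve_events(path: str | Path) -> list[ValveEvent]:
    events: list[ValveEvent] = []
    with open(path, newline="") as fh:
        r = csv.reader(fh)
        header = next(r, None)
        if header != ["time_s", "valve_id", "state"]:
            raise ParadigmError(f"unexpected valve-log header: {header}")
        for row in r:
            events.append(ValveEvent(float(row[0]), int(row[1]), row[2]))
    _check_ordered(events)
    return events
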