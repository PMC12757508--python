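"""Habituation/dishabituation effect statistics.

Analysis keeps only the first and final (third) presentation of each
stimulus.  The habituation effect for a stimulus is the per-subject change
in investigation duration from its first to its final presentation (negative
= habituation); the dishabituation effect for an adjacent stimulus pair is
the change from the final presentation of one stimulus to the first
presentation of the next (positive = dishabituation).

Effects are summarized by the mean per-subject difference with a percentile
bootstrap 95% CI (subjects resampled with replacement) plus the bootstrap
median, a two-sided sign-flip permutation p-value, and Holm step-down
adjustment across the family of effects.  Mixed-effects model fitting is
deliberately delegated: :func:`export_long_table` writes the model-ready
long-format table for any external mixed-model tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EffectEstimate",
    "habituation_diffs",
    "dishabituation_diffs",
    "bootstrap_ci",
    "paired_permutation_test",
    "holm_adjust",
    "exclude_subjects",
    "export_long_table",
    "compute_effects",
]

FIRST, FINAL = 1, 3  # presentations entering the analysis


@dataclass(frozen=True)
class EffectEstimate:
    """Point estimate and bootstrap CI for one habituation/dishabituation effect."""

    kind: str  # "habituation" | "dishabituation"
    stimulus: str  # stimulus label, or "prev->next" pair
    point_s: float  # mean per-subject difference, seconds
    boot_median_s: float  # median of the bootstrap distribution
    ci_low_s: float
    ci_high_s: float
    n_subjects: int
    n_boot: int
    level: float
    seed: int

    def excludes_zero(self) -> bool:
        return self.ci_low_s > 0 or self.ci_high_s < 0


def _unit_frame(scores: pd.DataFrame, unit_keys: Sequence[str]) -> pd.DataFrame:
    """Collapse to one duration per (unit, stimulus, presentation).

    The default unit is a subject-session pair, mirroring an analysis that
    pools sessions (and with them sexes and odor sets) as independent
    replicates; pass ``unit_keys=("subject",)`` to average within subject
    instead.
    """
    df = scores.copy()
    df["_unit"] = df[list(unit_keys)].astype(str).agg("|".join, axis=1)
    return (df.groupby(["_unit", "stimulus", "presentation"], as_index=False)
              ["duration_s"].mean())


def habituation_diffs(
    scores: pd.DataFrame,
    unit_keys: Sequence[str] = ("subject", "session"),
) -> pd.DataFrame:
    """Per-unit final-minus-first differences for each stimulus.

    Returns columns ``unit, stimulus, diff_s`` with
    ``diff_s = duration(presentation 3) - duration(presentation 1)``;
    negative values indicate habituation.  Units missing either
    presentation are skipped with a warning.
    """
    df = _unit_frame(scores, unit_keys)
    wide = df.pivot_table(index=["_unit", "stimulus"], columns="presentation",
                          values="duration_s", aggfunc="mean")
    rows = []
    for (unit, stim), r in wide.iterrows():
        if FIRST not in r.index or FINAL not in r.index or r[[FIRST, FINAL]].isna().any():
            warnings.warn(f"unit {unit!r} missing presentation {FIRST} or {FINAL} "
                          f"for {stim!r}; skipped", stacklevel=2)
            continue
        rows.append({"unit": unit, "stimulus": stim,
                     "diff_s": float(r[FINAL] - r[FIRST])})
    return pd.DataFrame(rows, columns=["unit", "stimulus", "diff_s"])


def dishabituation_diffs(
    scores: pd.DataFrame,
    stimulus_order: Sequence[str],
    unit_keys: Sequence[str] = ("subject", "session"),
) -> pd.DataFrame:
    """Per-unit differences across adjacent stimulus transitions.

    For each consecutive pair in ``stimulus_order``,
    ``diff_s = duration(first presentation of next) - duration(final
    presentation of previous)``; positive values indicate dishabituation.
    Returns columns ``unit, pair, diff_s`` with ``pair = "prev->next"``.
    """
    df = _unit_frame(scores, unit_keys)
    wide = df.pivot_table(index="_unit", columns=["stimulus", "presentation"],
                          values="duration_s", aggfunc="mean")
    rows = []
    for prev, nxt in zip(stimulus_order, stimulus_order[1:]):
        pair = f"{prev}->{nxt}"
        for unit, r in wide.iterrows():
            try:
                a, b = r[(prev, FINAL)], r[(nxt, FIRST)]
            except KeyError:
                a = b = np.nan
            if np.isnan(a) or np.isnan(b):
                warnings.warn(f"unit {unit!r} missing data for pair {pair}; skipped",
                              stacklevel=2)
                continue
            rows.append({"unit": unit, "pair": pair, "diff_s": float(b - a)})
    return pd.DataFrame(rows, columns=["unit", "pair", "diff_s"])


def bootstrap_ci(
    diffs: Sequence[float] | np.ndarray,
    kind: str,
    stimulus: str,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> EffectEstimate:
    """Percentile bootstrap CI for the mean per-subject difference.

    Subjects (units) are resampled with replacement ``n_boot`` times; the CI
    is the (1-level)/2 and 1-(1-level)/2 percentiles of the bootstrap means.
    Deterministic given ``seed``.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("bootstrap_ci needs at least one difference")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, d.size, size=(n_boot, d.size))
    boot_means = d[idx].mean(axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(boot_means, [alpha, 1 - alpha])
    return EffectEstimate(
        kind=kind, stimulus=stimulus,
        point_s=float(d.mean()),
        boot_median_s=float(np.median(boot_means)),
        ci_low_s=float(lo), ci_high_s=float(hi),
        n_subjects=int(d.size), n_boot=int(n_boot),
        level=float(level), seed=int(seed),
    )


def paired_permutation_test(
    diffs: Sequence[float] | np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided sign-flip permutation p-value for mean(diffs) = 0.

    When 2^n <= n_perm all sign assignments are enumerated and the p-value
    is exact (#{|mean*| >= |mean|} / 2^n, which includes the identity so
    p >= 2^-n); otherwise n_perm random sign flips are drawn and
    p = (1 + #{|mean*| >= |mean|}) / (1 + n_perm).
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("paired_permutation_test needs at least one difference")
    n = d.size
    obs = abs(d.mean())
    tol = 1e-12 * max(1.0, float(np.abs(d).max()))
    if 2 ** n <= n_perm:
        codes = np.arange(2 ** n, dtype=np.int64)
        signs = ((codes[:, None] >> np.arange(n)) & 1) * 2 - 1
        means = np.abs(signs @ d) / n
        return float(np.count_nonzero(means >= obs - tol) / 2 ** n)
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    means = np.abs(signs @ d) / n
    return float((1 + np.count_nonzero(means >= obs - tol)) / (1 + n_perm))


def holm_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values, in the original order.

    Sort ascending, multiply p_(i) by (m - i), take the running maximum,
    cap at 1.  Controls FWER for any dependence structure.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, np.maximum.accumulate(
        p[order] * (m - np.arange(m))))
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def exclude_subjects(
    scores: pd.DataFrame,
    excluded: Sequence[str],
    session: str | None = None,
) -> pd.DataFrame:
    """Drop excluded subjects' rows (optionally only within one session).

    Cohort bookkeeping for attrition and technical loss: e.g. removing two
    subjects from a 24-subject cohort's second session leaves 22 analyzable
    subjects for that session.
    """
    excluded = set(map(str, excluded))
    mask = scores["subject"].astype(str).isin(excluded)
    if session is not None:
        mask &= scores["session"].astype(str) == str(session)
    return scores.loc[~mask].reset_index(drop=True)


def export_long_table(
    scores: pd.DataFrame,
    path: str | Path,
    presentations: Sequence[int] = (FIRST, FINAL),
    full_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write the model-ready long-format table for external mixed-model fits.

    The main file keeps only the analyzed presentations (first and final by
    default); ``full_path``, if given, receives the unrestricted table.
    Columns: subject, session, method, stimulus, presentation, duration_s.
    """
    cols = ["subject", "session", "method", "stimulus", "presentation", "duration_s"]
    df = scores.loc[:, cols].copy()
    restricted = df[df["presentation"].isin(list(presentations))].reset_index(drop=True)
    restricted.to_csv(path, index=False)
    if full_path is not None:
        df.to_csv(full_path, index=False)
    return restricted


def compute_effects(
    scores: pd.DataFrame,
    stimulus_order: Sequence[str] | None = None,
    unit_keys: Sequence[str] = ("subject", "session"),
    n_boot: int = 10_000,
    n_perm: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Full effect table: habituation per stimulus, dishabituation per pair.

    Returns columns ``kind, stimulus, point_s, boot_median_s, ci_low_s,
    ci_high_s, n, p_perm, p_holm``.  Holm adjustment spans the whole family
    of effects in the table.  Deterministic given ``seed`` (each effect gets
    a distinct sub-seed).
    """
    if stimulus_order is None:
        stimulus_order = list(pd.unique(scores["stimulus"]))
    hab = habituation_diffs(scores, unit_keys)
    dis = dishabituation_diffs(scores, stimulus_order, unit_keys)
    effects: list[EffectEstimate] = []
    pvals: list[float] = []
    k = 0
    for stim in stimulus_order:
        d = hab.loc[hab["stimulus"] == stim, "diff_s"].to_numpy()
        if d.size == 0:
            continue
        effects.append(bootstrap_ci(d, "habituation", stim, n_boot, level, seed + k))
        pvals.append(paired_permutation_test(d, n_perm, seed + k))
        k += 1
    for pair in [f"{a}->{b}" for a, b in zip(stimulus_order, stimulus_order[1:])]:
        d = dis.loc[dis["pair"] == pair, "diff_s"].to_numpy()
        if d.size == 0:
            continue
        effects.append(bootstrap_ci(d, "dishabituation", pair, n_boot, level, seed + k))
        pvals.append(paired_permutation_test(d, n_perm, seed + k))
        k += 1
    p_holm = holm_adjust(pvals) if pvals else np.array([])
    return pd.DataFrame([
        {"kind": e.kind, "stimulus": e.stimulus, "point_s": e.point_s,
         "boot_median_s": e.boot_median_s, "ci_low_s": e.ci_low_s,
         "ci_high_s": e.ci_high_s, "n": e.n_subjects,
         "p_perm": p, "p_holm": ph}
        for e, p, ph in zip(effects, pvals, p_holm)
    ], columns=["kind", "stimulus", "point_s", "boot_median_s", "ci_low_s",
                "ci_high_s", "n", "p_perm", "p_holm"])
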