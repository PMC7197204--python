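"""Behavioral coordination measures.

The chain mirrors the study's movement analysis: mean-center, detrend and
low-pass filter both position traces (second-order Butterworth at 20 Hz,
applied forward and backward), z-normalize, estimate each signal's
instantaneous phase with the Hilbert transform and form the continuous
relative phase RP = phase(human) - phase(VP), wrapped to (-pi, pi]. The
first and last second of the 10-s interaction are discarded, leaving 8 s
split into two 4-s halves. Each segment is summarized by the circular
mean of RP (the produced pattern) and the circular variance 1 - R (its
instability); stability = R. A phase coordination score measures the
normalized circular distance between the produced pattern and the task
target (0 rad in-phase, pi rad anti-phase), and an intention attribution
score compares the reported cooperativeness with the VP's true behavior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import signal as sps

from .records import (ANTI_PHASE, IN_PHASE, Reports, TrialConfig,
                      TrialRecord, half_behavior)

__all__ = [
    "FilterSpec",
    "PhaseSeries",
    "CoordinationSummary",
    "Segments",
    "preprocess",
    "three_point_velocity",
    "relative_phase",
    "wrap_phase",
    "segment_interaction",
    "interaction_segments",
    "circular_summary",
    "coordination_score",
    "attribution_metrics",
    "AttributionSummary",
    "normalize_per_participant",
    "trial_measures",
    "session_table",
    "export_trial_table",
]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter: Butterworth of the given order per pass, applied
    forward and backward (dual-pass, zero phase lag)."""

    order: int = 2
    cutoff_hz: float = 20.0

    def validate(self, fs: float) -> None:
        if self.cutoff_hz >= fs / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must be below Nyquist ({fs / 2})"
            )


@dataclass(frozen=True)
class PhaseSeries:
    """Sample-wise relative phase in radians, wrapped to (-pi, pi]."""

    t: np.ndarray
    rp: np.ndarray


@dataclass(frozen=True)
class CoordinationSummary:
    """Circular summary of a relative-phase segment."""

    mean_rp: float
    circ_var: float
    segment: str = "full"

    @property
    def stability(self) -> float:
        return 1.0 - self.circ_var


@dataclass(frozen=True)
class Segments:
    """Sample slices of the retained interaction and its two halves."""

    retained: slice
    first_half: slice
    second_half: slice


def preprocess(x: np.ndarray, fs: float,
               spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Mean-center, detrend, dual-pass low-pass filter and z-normalize."""
    x = np.asarray(x, dtype=float)
    spec.validate(fs)
    if fs <= 40:
        raise ValueError(f"sampling rate {fs}/s too low for preprocessing")
    if len(x) < 10 * spec.order:
        raise ValueError(
            f"series of length {len(x)} too short to filter (need >= "
            f"{10 * spec.order} samples)"
        )
    if np.ptp(x) == 0.0:
        raise ValueError("cannot normalize a constant series (zero variance)")
    x = sps.detrend(x, type="linear")  # removes mean and linear trend
    b, a = sps.butter(spec.order, spec.cutoff_hz / (fs / 2.0))
    x = sps.filtfilt(b, a, x)
    x = x - x.mean()  # filtering can reintroduce a tiny offset
    sd = x.std()
    if sd == 0.0:
        raise ValueError("series has zero variance after filtering")
    return x / sd


def three_point_velocity(x: np.ndarray, fs: float) -> np.ndarray:
    """Causal three-point backward-difference velocity.

    v[n] = (3 x[n] - 4 x[n-1] + x[n-2]) * fs / 2 for n >= 2 (exact for
    polynomials up to degree 2); the first two samples use a forward and a
    central difference respectively. Matches the apparatus, which can only
    use past samples in real time.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples for three-point velocity")
    v = np.empty_like(x)
    v[2:] = (3.0 * x[2:] - 4.0 * x[1:-1] + x[:-2]) * fs / 2.0
    v[0] = (x[1] - x[0]) * fs
    v[1] = (x[2] - x[0]) * fs / 2.0
    return v


def wrap_phase(a: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Wrap an angle (difference) to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(a)))


def relative_phase(x: np.ndarray, y: np.ndarray, fs: float) -> PhaseSeries:
    """Continuous relative phase of x with respect to y (x minus y).

    Phases come from the analytic signal (Hilbert transform) of each
    series; inputs should already be preprocessed. Convention: rp < 0
    means x lags y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero-variance input; phase is undefined")
    px = np.angle(sps.hilbert(x))
    py = np.angle(sps.hilbert(y))
    rp = wrap_phase(px - py)
    return PhaseSeries(t=np.arange(len(x)) / fs, rp=rp)


def interaction_segments(n_samples: int, fs: float,
                         interaction_s: float = 10.0,
                         trim_s: float = 1.0) -> Segments:
    """Slices for the retained segment and halves of an interaction.

    The first and last trim_s seconds are discarded; the remainder is
    split into two equal halves.
    """
    expected = int(round(interaction_s * fs))
    if n_samples != expected:
        raise ValueError(
            f"record has {n_samples} samples, expected {expected} for a "
            f"{interaction_s}-s interaction at {fs}/s"
        )
    i0 = int(round(trim_s * fs))
    i1 = n_samples - i0
    mid = (i0 + i1) // 2
    return Segments(retained=slice(i0, i1),
                    first_half=slice(i0, mid),
                    second_half=slice(mid, i1))


def segment_interaction(rec: TrialRecord) -> Segments:
    return interaction_segments(len(rec.human_x), rec.config.fs,
                                rec.config.interaction_s)


def circular_summary(ph: Union[PhaseSeries, np.ndarray],
                     segment: str = "full") -> CoordinationSummary:
    """Circular mean direction and variance (1 - mean resultant length)."""
    angles = ph.rp if isinstance(ph, PhaseSeries) else np.asarray(ph)
    if angles.size == 0:
        raise ValueError("cannot summarize an empty phase series")
    z = np.mean(np.exp(1j * angles))
    return CoordinationSummary(mean_rp=float(np.angle(z)),
                               circ_var=float(1.0 - np.abs(z)),
                               segment=segment)


def coordination_score(summary: Union[CoordinationSummary, float],
                       task: str) -> float:
    """Normalized circular distance from the task-target relative phase.

    0 = produced pattern exactly on target (0 rad for the in-phase task,
    pi for anti-phase), 1 = diametrically opposite.
    """
    mean_rp = (summary.mean_rp if isinstance(summary, CoordinationSummary)
               else float(summary))
    target = 0.0 if task == IN_PHASE else np.pi
    return float(np.abs(wrap_phase(mean_rp - target)) / np.pi)


@dataclass(frozen=True)
class AttributionSummary:
    """Session-level intention-attribution aggregates."""

    accuracy: float
    false_cooperation_rate: float
    false_competition_rate: float
    n_halves: int


def attribution_metrics(
    reports: Sequence[Tuple[float, float]],
    schedule: Sequence[TrialConfig],
) -> Tuple[pd.DataFrame, AttributionSummary]:
    """Per-half attribution scores and session aggregates.

    reports: one (coop_early, coop_late) pair per trial, each in [0, 1].
    The true behavior per half comes from each trial's VP schedule
    (1 = cooperative, 0 = competitive). The attribution score is
    1 - |perceived - actual|; a half is judged correct when the report
    falls on the true side of 0.5 (reports of exactly 0.5 count correct).
    """
    if len(reports) != len(schedule):
        raise ValueError("reports and schedule must have equal length")
    rows = []
    for trial_idx, (rep, cfg) in enumerate(zip(reports, schedule)):
        actual = half_behavior(cfg)
        for half, perceived in zip(("first", "second"), rep):
            if not 0.0 <= perceived <= 1.0:
                raise ValueError(
                    f"report {perceived} out of [0, 1] in trial {trial_idx}"
                )
            act = actual[0 if half == "first" else 1]
            tie = perceived == 0.5
            correct = tie or ((perceived > 0.5) == bool(act))
            rows.append(dict(
                trial=trial_idx, half=half, perceived=perceived,
                actual=act, attr_score=1.0 - abs(perceived - act),
                attr_correct=int(correct),
            ))
    df = pd.DataFrame(rows)
    comp = df[df.actual == 0]
    coop = df[df.actual == 1]
    false_coop = float((comp.perceived > 0.5).mean()) if len(comp) else 0.0
    false_comp = float((coop.perceived < 0.5).mean()) if len(coop) else 0.0
    summary = AttributionSummary(
        accuracy=float(df.attr_correct.mean()),
        false_cooperation_rate=false_coop,
        false_competition_rate=false_comp,
        n_halves=len(df),
    )
    return df, summary


def normalize_per_participant(df: pd.DataFrame, columns: Sequence[str],
                              participant_col: str = "participant",
                              suffix: str = "_z") -> pd.DataFrame:
    """Z-score the given columns within each participant (population SD).

    Returns a copy with new columns <name><suffix>. Raises if any
    participant has fewer than 2 values or zero variance in a column.
    """
    out = df.copy()
    for col in columns:
        zs = np.empty(len(df), dtype=float)
        for pid, grp in df.groupby(participant_col):
            vals = grp[col].to_numpy(dtype=float)
            if len(vals) < 2:
                raise ValueError(
                    f"participant {pid!r} has fewer than 2 values in {col!r}"
                )
            sd = vals.std()  # population SD
            if sd == 0.0:
                raise ValueError(
                    f"participant {pid!r} has zero variance in {col!r}; "
                    "cannot z-score"
                )
            zs[grp.index.to_numpy()] = (vals - vals.mean()) / sd
        out[col + suffix] = zs
    return out


def trial_measures(rec: TrialRecord,
                   filter_spec: FilterSpec = FilterSpec()) -> List[Dict]:
    """Full behavioral analysis of one trial: one dict per half.

    Runs the preprocessing chain on both traces, computes RP, trims
    transients, and summarizes each 4-s half.
    """
    fs = rec.config.fs
    hx = preprocess(rec.human_x, fs, filter_spec)
    vx = preprocess(rec.vp_x, fs, filter_spec)
    ph = relative_phase(hx, vx, fs)
    seg = segment_interaction(rec)
    actual = half_behavior(rec.config)
    transition = rec.config.trial_type in ("coop2comp", "comp2coop")
    rows = []
    for name, sl, act in (("first", seg.first_half, actual[0]),
                          ("second", seg.second_half, actual[1])):
        summ = circular_summary(ph.rp[sl], segment=f"{name}-half")
        row = dict(
            half=name,
            task=rec.config.task,
            trial_type=rec.config.trial_type,
            vp_behavior="coop" if act else "comp",
            transition="yes" if transition else "no",
            mean_rp=summ.mean_rp,
            circ_var=summ.circ_var,
            stability=summ.stability,
            coord_score=coordination_score(summ, rec.config.task),
        )
        if rec.reports is not None:
            perceived = (rec.reports.coop_early if name == "first"
                         else rec.reports.coop_late)
            tie = perceived == 0.5
            row.update(
                report_coop=perceived,
                humanness=rec.reports.humanness,
                attr_score=1.0 - abs(perceived - act),
                attr_correct=int(tie or ((perceived > 0.5) == bool(act))),
            )
        rows.append(row)
    return rows


#: Column order of the tidy per-trial-half table.
TRIAL_TABLE_COLUMNS = [
    "participant", "trial", "half", "task", "trial_type", "vp_behavior",
    "transition", "mean_rp", "circ_var", "stability", "coord_score",
    "report_coop", "humanness", "attr_score", "attr_correct",
]


def session_table(records: Sequence[TrialRecord],
                  participant: Union[int, str] = 0,
                  filter_spec: FilterSpec = FilterSpec()) -> pd.DataFrame:
    """Tidy table with one row per trial x half for a session."""
    rows = []
    for trial_idx, rec in enumerate(records):
        for row in trial_measures(rec, filter_spec):
            row.update(participant=participant, trial=trial_idx)
            rows.append(row)
    df = pd.DataFrame(rows)
    cols = [c for c in TRIAL_TABLE_COLUMNS if c in df.columns]
    return df[cols]


def export_trial_table(df: pd.DataFrame, path) -> None:
    """Write the tidy trial table as tab-separated text."""
    df.to_csv(path, sep="\t", index=False)
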