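"""Trial-level data containers shared across the simulation and analysis layers.

A trial is the unit of the experiment: a 3-s paced lead-in (not recorded
here), a 10-s interaction during which the human and the virtual partner
(VP) move together at 500 Hz, and a self-report phase. The VP's intention
parameter mu (+1 = prefers in-phase, -1 = prefers anti-phase) follows a
per-trial schedule that defines the four trial types: cooperation
throughout, competition throughout, and the two mid-trial switches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence, Tuple

import numpy as np

IN_PHASE = "in-phase"
ANTI_PHASE = "anti-phase"
TASKS = (IN_PHASE, ANTI_PHASE)

TRIAL_TYPES = ("coop", "comp", "coop2comp", "comp2coop")

__all__ = [
    "IN_PHASE",
    "ANTI_PHASE",
    "TASKS",
    "TRIAL_TYPES",
    "Reports",
    "TrialConfig",
    "TrialRecord",
    "task_mu",
    "half_behavior",
]


class Reports(NamedTuple):
    """Subjective reports collected after a trial.

    coop_early/coop_late: perceived cooperativeness of the VP in the first
    and second half of the interaction, on a continuous 0 (competitive) to
    1 (cooperative) scale. humanness: binary judgment, 0 = machine,
    1 = human.
    """

    coop_early: float
    coop_late: float
    humanness: int


def task_mu(task: str) -> int:
    """Intention value matching a task: +1 for in-phase, -1 for anti-phase."""
    if task == IN_PHASE:
        return 1
    if task == ANTI_PHASE:
        return -1
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


@dataclass(frozen=True)
class TrialConfig:
    """Static description of one trial.

    vp_schedule is a list of (start_s, end_s, mu) segments that must tile
    [0, interaction_s] without gaps or overlap; mu is +1 or -1 per segment.
    """

    task: str = IN_PHASE
    trial_type: str = "coop"
    pacing_s: float = 3.0
    interaction_s: float = 10.0
    fs: float = 500.0
    f_move: float = 1.6
    vp_schedule: Tuple[Tuple[float, float, int], ...] = ((0.0, 10.0, 1),)

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial_type {self.trial_type!r}")
        if self.fs <= 0 or self.interaction_s <= 0:
            raise ValueError("fs and interaction_s must be positive")
        segs = tuple(tuple(s) for s in self.vp_schedule)
        object.__setattr__(self, "vp_schedule", segs)
        t = 0.0
        for start, end, mu in segs:
            if not np.isclose(start, t):
                raise ValueError(
                    f"vp_schedule segments must tile [0, {self.interaction_s}] "
                    f"contiguously; segment starts at {start}, expected {t}"
                )
            if end <= start:
                raise ValueError("vp_schedule segment must have end > start")
            if mu not in (-1, 1):
                raise ValueError(f"segment mu must be +1 or -1, got {mu}")
            t = end
        if not np.isclose(t, self.interaction_s):
            raise ValueError(
                f"vp_schedule ends at {t}, expected {self.interaction_s}"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.interaction_s * self.fs))

    @property
    def task_mu(self) -> int:
        return task_mu(self.task)

    def mu_at(self, t: float) -> int:
        """VP intention at time t (s) into the interaction."""
        for start, end, mu in self.vp_schedule:
            if start <= t < end:
                return int(mu)
        return int(self.vp_schedule[-1][2])

    def mu_series(self, n_steps: Optional[int] = None) -> np.ndarray:
        """Per-sample VP intention on the fs grid."""
        n = self.n_samples if n_steps is None else n_steps
        t = np.arange(n) / self.fs
        out = np.empty(n, dtype=float)
        for start, end, mu in self.vp_schedule:
            out[(t >= start) & (t < end)] = mu
        out[t >= self.vp_schedule[-1][1]] = self.vp_schedule[-1][2]
        return out


def half_behavior(cfg: TrialConfig) -> Tuple[int, int]:
    """True VP behavior per trial half: 1 = cooperative, 0 = competitive.

    A half counts as cooperative when the VP's intention matches the
    participant's task target for (the bulk of) that half.
    """
    mid = cfg.interaction_s / 2.0
    out = []
    for t_probe in (mid / 2.0, mid + mid / 2.0):
        out.append(int(cfg.mu_at(t_probe) == cfg.task_mu))
    return out[0], out[1]


@dataclass
class TrialRecord:
    """One simulated (or loaded) trial: synchronized movement plus metadata."""

    config: TrialConfig
    t: np.ndarray
    human_x: np.ndarray
    vp_x: np.ndarray
    reports: Optional[Reports] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        n = self.config.n_samples
        for name in ("t", "human_x", "vp_x"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ValueError(
                    f"{name} has length {arr.shape}, expected ({n},) for a "
                    f"{self.config.interaction_s}-s trial at {self.config.fs}/s"
                )
        if self.reports is not None:
            r = Reports(*self.reports)
            if not (0.0 <= r.coop_early <= 1.0 and 0.0 <= r.coop_late <= 1.0):
                raise ValueError("cooperativeness reports must lie in [0, 1]")
            if r.humanness not in (0, 1):
                raise ValueError("humanness must be 0 or 1")
            self.reports = r
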