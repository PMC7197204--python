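"""Synthetic participants: schedule, closed-loop movement, and reports.

The human mover is modeled as a second HKB oscillator with an intention
of its own (the task instruction: +1 in-phase, -1 anti-phase) and
additive Gaussian acceleration noise. Human and VP are integrated as a
two-way closed loop at 500 Hz: the human receives the VP's true state,
while the VP receives the human's position together with a causal
three-point-differentiated velocity, emulating the real-time apparatus.
The VP's intention follows the trial's schedule (cooperative = matching
the participant's task target, competitive = opposing it, with optional
mid-trial switches), and its initial phase is randomized per trial.

The human's coupling uses a strong linear gain with no quadratic
pattern-preference term (coup_a = -1.5, coup_b = 0): an instructed
participant corrects deviations from the target pattern regardless of
the current relative phase, whereas the VP's quadratic term would make
opposition lock *more* tightly at a compromise phase. With acceleration
noise of sd 40 units/s^1.5 this regime reproduces the qualitative
phenomena of interest: stable coordination under cooperation, degraded
stability under competition, and a stability drop after a mid-trial
intention switch.

A minimal observer model turns each simulated trial into subjective
reports: perceived cooperativeness per half is a logistic function of
that half's goal congruence (1 - coordination distance to the task
target) plus noise, and the humanness judgment is a Bernoulli draw whose
probability increases with the trial's stability variability (machines
are too steady; humans waver).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import behavior
from .oscillator import (OscState, VPParams, limit_cycle_amplitude)
from .records import (ANTI_PHASE, IN_PHASE, Reports, TASKS, TRIAL_TYPES,
                      TrialConfig, TrialRecord, task_mu)

__all__ = [
    "HumanParams",
    "ObserverParams",
    "make_schedule",
    "simulate_closed_loop",
    "simulate_session",
    "simulate_reports",
    "calibrate_observer_noise",
]


@dataclass(frozen=True)
class HumanParams:
    """The simulated participant.

    oscillator: the human's own HKB parameters (see module docstring for
    why the coupling defaults differ from the VP's). detune_hz shifts the
    human's intrinsic frequency away from the VP's. task_mu is the
    instructed pattern (+1 in-phase, -1 anti-phase) and is normally set
    per trial from the task. noise_sd is the Langevin acceleration-noise
    scale in units/s^1.5.
    """

    oscillator: VPParams = field(default_factory=lambda: VPParams(
        coup_a=-1.5, coup_b=0.0))
    detune_hz: float = 0.0
    task_mu: int = 1
    noise_sd: float = 40.0

    def __post_init__(self) -> None:
        if self.task_mu not in (-1, 1):
            raise ValueError("task_mu must be +1 or -1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def effective_oscillator(self) -> VPParams:
        f = self.oscillator.f_intrinsic + self.detune_hz
        return replace(self.oscillator, f_intrinsic=f,
                       omega=2.0 * math.pi * f, mu=self.task_mu)


@dataclass(frozen=True)
class ObserverParams:
    """The report-generating observer.

    report_noise_sd: Gaussian noise added to the cooperativeness report
    before clipping to [0, 1]. stability_weight in [0, 1] scales how
    strongly stability variability drives the humanness judgment away
    from a coin flip.
    """

    report_noise_sd: float = 0.3
    stability_weight: float = 0.8

    def __post_init__(self) -> None:
        if self.report_noise_sd < 0:
            raise ValueError("report_noise_sd must be non-negative")
        if not 0.0 <= self.stability_weight <= 1.0:
            raise ValueError("stability_weight must lie in [0, 1]")


def _schedule_for_type(trial_type: str, task: str,
                       interaction_s: float) -> Tuple[Tuple[float, float, int],
                                                      ...]:
    mu_c = task_mu(task)
    half = interaction_s / 2.0
    if trial_type == "coop":
        return ((0.0, interaction_s, mu_c),)
    if trial_type == "comp":
        return ((0.0, interaction_s, -mu_c),)
    if trial_type == "coop2comp":
        return ((0.0, half, mu_c), (half, interaction_s, -mu_c))
    if trial_type == "comp2coop":
        return ((0.0, half, -mu_c), (half, interaction_s, mu_c))
    raise ValueError(f"unknown trial type {trial_type!r}")


def make_schedule(n_trials: int = 80, block_size: int = 10,
                  seed: Optional[int] = 0, fs: float = 500.0,
                  interaction_s: float = 10.0) -> List[TrialConfig]:
    """Pseudo-randomized session schedule.

    Trials come in blocks of block_size with a single task per block;
    tasks are counterbalanced across blocks (equal in-/anti-phase block
    counts, order shuffled). The four trial types are balanced overall
    (n_trials/4 each when divisible) and shuffled across the session.
    Deterministic for a fixed seed.
    """
    if n_trials <= 0 or block_size <= 0:
        raise ValueError("n_trials and block_size must be positive")
    if n_trials % block_size != 0:
        raise ValueError(
            f"n_trials ({n_trials}) must be divisible by block_size "
            f"({block_size})"
        )
    n_blocks = n_trials // block_size
    if n_blocks % 2 != 0:
        raise ValueError(
            f"need an even number of blocks to counterbalance tasks, got "
            f"{n_blocks}"
        )
    rng = np.random.default_rng(seed)
    block_tasks = [IN_PHASE] * (n_blocks // 2) + [ANTI_PHASE] * (n_blocks // 2)
    rng.shuffle(block_tasks)
    # balanced trial types (counts differ by at most 1), shuffled
    reps = -(-n_trials // len(TRIAL_TYPES))
    types = (list(TRIAL_TYPES) * reps)[:n_trials]
    rng.shuffle(types)
    configs = []
    for i in range(n_trials):
        task = block_tasks[i // block_size]
        ttype = types[i]
        configs.append(TrialConfig(
            task=task, trial_type=ttype, fs=fs, interaction_s=interaction_s,
            vp_schedule=_schedule_for_type(ttype, task, interaction_s),
        ))
    return configs


def _batched_rk4(x, v, y, yd, mu, p: VPParams, dt: float):
    """Vectorized RK4 step of the HKB equation over a batch of units."""
    a, b, al, be, ga, w2 = (p.coup_a, p.coup_b, p.alpha_vdp, p.beta_ray,
                            p.gamma_damp, p.omega ** 2)

    def deriv(x_, v_):
        acc = (-(al * x_ * x_ + be * v_ * v_ - ga) * v_ - w2 * x_
               + (a + b * (x_ - mu * y) ** 2) * (v_ - mu * yd))
        return v_, acc

    k1x, k1v = deriv(x, v)
    k2x, k2v = deriv(x + dt / 2 * k1x, v + dt / 2 * k1v)
    k3x, k3v = deriv(x + dt / 2 * k2x, v + dt / 2 * k2v)
    k4x, k4v = deriv(x + dt * k3x, v + dt * k3v)
    return (x + dt / 6 * (k1x + 2 * k2x + 2 * k3x + k4x),
            v + dt / 6 * (k1v + 2 * k2v + 2 * k3v + k4v))


def _simulate_pairs(task_mus: np.ndarray, mu_vp: np.ndarray,
                    hp: HumanParams, vp: VPParams,
                    rng: np.random.Generator,
                    blowup_bound: float = 1e6
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Integrate B independent human-VP pairs in lock step.

    task_mus: (B,) human intentions; mu_vp: (n_steps, B) VP intention per
    step. Returns human and VP positions, each (n_steps, B).
    """
    n_steps, nb = mu_vp.shape
    dt = vp.dt
    fs = 1.0 / dt
    hosc = hp.effective_oscillator()
    if not math.isclose(hosc.dt, dt, rel_tol=1e-12):
        raise ValueError("human and VP oscillators must share dt")

    amp_v = limit_cycle_amplitude(vp)
    amp_h = limit_cycle_amplitude(hosc)
    phase = rng.uniform(0.0, 2.0 * np.pi, nb)  # randomized VP phase
    xv = amp_v * np.sin(phase)
    vv = amp_v * vp.omega * np.cos(phase)
    # human starts metronome-locked at phase 0 (peak velocity)
    xh = np.zeros(nb)
    vh = np.full(nb, amp_h * hosc.omega)
    noise = rng.standard_normal((n_steps, nb)) * hp.noise_sd * math.sqrt(dt)

    XH = np.empty((n_steps, nb))
    XV = np.empty((n_steps, nb))
    xh1 = xh.copy()
    xh2 = xh.copy()
    check_every = max(1, int(round(0.25 * fs)))
    for i in range(n_steps):
        XH[i] = xh
        XV[i] = xv
        # causal three-point velocity of the sampled human position
        vh_est = (3.0 * xh - 4.0 * xh1 + xh2) * fs / 2.0
        nxh, nvh = _batched_rk4(xh, vh, xv, vv, task_mus, hosc, dt)
        nxv, nvv = _batched_rk4(xv, vv, xh, vh_est, mu_vp[i], vp, dt)
        nvh = nvh + noise[i]
        xh2, xh1 = xh1, xh
        xh, vh, xv, vv = nxh, nvh, nxv, nvv
        if i % check_every == 0 and (
                not np.all(np.isfinite(xh)) or np.any(np.abs(xh) > blowup_bound)
                or not np.all(np.isfinite(xv))
                or np.any(np.abs(xv) > blowup_bound)):
            raise RuntimeError(
                f"closed-loop integration diverged at step {i}"
            )
    return XH, XV


def simulate_session(configs: Sequence[TrialConfig], hp: HumanParams,
                     vp: VPParams, seed: Optional[int] = 0
                     ) -> List[TrialRecord]:
    """Simulate all trials of a session in one vectorized batch."""
    if not configs:
        return []
    n = configs[0].n_samples
    fs = configs[0].fs
    for cfg in configs:
        if cfg.n_samples != n or cfg.fs != fs:
            raise ValueError("all trials in a batch must share fs and length")
    if not math.isclose(1.0 / fs, vp.dt, rel_tol=1e-9):
        raise ValueError(f"trial fs {fs}/s does not match VP dt {vp.dt}s")
    rng = np.random.default_rng(seed)
    task_mus = np.array([float(c.task_mu) for c in configs])
    mu_vp = np.stack([c.mu_series() for c in configs], axis=1)
    hp_trial = replace(hp, task_mu=1)  # per-trial intention via task_mus
    XH, XV = _simulate_pairs(task_mus, mu_vp, hp_trial, vp, rng)
    t = np.arange(n) / fs
    return [
        TrialRecord(config=cfg, t=t, human_x=XH[:, k], vp_x=XV[:, k],
                    seed=None if seed is None else int(seed))
        for k, cfg in enumerate(configs)
    ]


def simulate_closed_loop(cfg: TrialConfig, hp: HumanParams, vp: VPParams,
                         seed: Optional[int] = 0) -> TrialRecord:
    """Simulate one closed-loop trial (human and VP mutually coupled)."""
    hp = replace(hp, task_mu=cfg.task_mu)
    return simulate_session([cfg], hp, vp, seed=seed)[0]


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


#: Slope of the congruence -> cooperativeness report map.
_REPORT_SLOPE = 8.0
#: Humanness model: logistic slope and midpoint on stability variability.
#: The midpoint sits at the typical half-to-half stability change of a
#: default synthetic session, putting the humanness rate near 50%.
_HUMANNESS_SLOPE = 25.0
_HUMANNESS_MID = 0.10


def simulate_reports(rec: TrialRecord, op: ObserverParams,
                     seed: Optional[int] = 0) -> Reports:
    """Subjective reports for a simulated trial.

    Perceived cooperativeness of half h is
    clip(logistic(8 (c_h - 1/2)) + noise, 0, 1) where c_h is the half's
    goal congruence (1 - coordination score). The humanness probability
    is 1/2 + w (logistic(25 (|stab_1 - stab_2| - 0.1)) - 1/2) with
    w = stability_weight. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    rows = behavior.trial_measures(rec)
    reports = []
    for row in rows:
        congruence = 1.0 - row["coord_score"]
        raw = _logistic(_REPORT_SLOPE * (congruence - 0.5))
        noisy = raw + rng.normal(0.0, op.report_noise_sd) \
            if op.report_noise_sd > 0 else raw
        reports.append(float(np.clip(noisy, 0.0, 1.0)))
    variability = abs(rows[0]["stability"] - rows[1]["stability"])
    p_raw = _logistic(_HUMANNESS_SLOPE * (variability - _HUMANNESS_MID))
    p_human = 0.5 + op.stability_weight * (p_raw - 0.5)
    humanness = int(rng.random() < p_human)
    return Reports(coop_early=reports[0], coop_late=reports[1],
                   humanness=humanness)


def calibrate_observer_noise(
    target_accuracy: float,
    configs: Sequence[TrialConfig],
    hp: HumanParams,
    vp: VPParams,
    grid: Sequence[float] = tuple(np.linspace(0.0, 1.0, 21)),
    n_sessions: int = 5,
    seed: Optional[int] = 0,
) -> Tuple[float, Dict[float, float]]:
    """Pick report_noise_sd so session attribution accuracy hits a target.

    Runs a Monte-Carlo calibration curve: for each candidate noise level,
    simulate n_sessions sessions, score attribution accuracy, and return
    the grid point whose mean accuracy is closest to the target (plus the
    full curve). Reports are monotone in congruence, so accuracy falls
    monotonically (in expectation) as noise grows.
    """
    rng = np.random.default_rng(seed)
    session_seeds = [int(s) for s in
                     rng.integers(0, 2 ** 31 - 1, size=n_sessions)]
    records_per_session = [
        simulate_session(configs, hp, vp, seed=s) for s in session_seeds
    ]
    curve: Dict[float, float] = {}
    for sd in grid:
        op = ObserverParams(report_noise_sd=float(sd))
        accs = []
        for k, records in enumerate(records_per_session):
            reports = [
                simulate_reports(r, op,
                                 seed=session_seeds[k] + 7919 * i)
                for i, r in enumerate(records)
            ]
            pairs = [(rep.coop_early, rep.coop_late) for rep in reports]
            _, summary = behavior.attribution_metrics(
                pairs, [r.config for r in records])
            accs.append(summary.accuracy)
        curve[float(sd)] = float(np.mean(accs))
    best = min(curve, key=lambda s: abs(curve[s] - target_accuracy))
    return best, curve
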