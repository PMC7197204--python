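"""Ground-truth recovery studies on fully synthetic experiments.

These functions run the whole pipeline end to end against the synthetic
generators' known ground truth: do the connectivity statistics recover
the channels that really carry movement information (and nothing else),
and does the behavioral pipeline reproduce the qualitative coordination
effects the closed-loop generator is built to exhibit?
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .behavior import (interaction_segments, session_table,
                       three_point_velocity)
from .neural import NeuralSimConfig, simulate_neural
from .oscillator import VPParams
from .participant import HumanParams, make_schedule, simulate_session
from .permstats import PermSpec, sign_flip_test
from .records import TrialConfig
from .spectral import (WindowSpec, band_summarize, cortico_motor_coherence,
                       default_bands, phase_scramble)

__all__ = [
    "RecoveryResult",
    "planted_recovery_experiment",
    "recovery_study",
    "behavioral_effect_replication",
]


@dataclass(frozen=True)
class RecoveryResult:
    """Outcome of one planted-network recovery experiment."""

    flagged_self: Tuple[int, ...]
    flagged_other: Tuple[int, ...]
    sensitivity: float
    any_false_positive: bool


def _theta(f_move: float = 1.6):
    return [b for b in default_bands(f_move) if b.name == "Theta"]


def planted_recovery_experiment(
    n_participants: int = 8,
    n_trials: int = 20,
    neural: Optional[NeuralSimConfig] = None,
    hp: Optional[HumanParams] = None,
    vp: Optional[VPParams] = None,
    seed: int = 0,
    alpha: float = 0.05,
) -> RecoveryResult:
    """One synthetic experiment: plant coherent channels, run the full
    pipeline, and test which channels the statistics flag.

    Per participant, trials are simulated in the closed loop, neural
    channels are generated with planted self/other theta coherence, and
    the theta-band cortico-motor coherence is contrasted against a
    phase-scrambled-velocity control. Group-level sign-flip permutation
    tests with max-stat FWER correction (exhaustive over 2^n
    participants) flag channels per contrast.

    sensitivity counts planted channels flagged in their matching
    contrast(s); any_false_positive records whether a background channel
    was flagged in either contrast.
    """
    if neural is None:
        neural = NeuralSimConfig(
            n_channels=8,
            groups={"self": (0, 1), "other": (2, 3), "overlap": (4,),
                    "background": (5, 6, 7)},
        )
    hp = hp or HumanParams()
    vp = vp or VPParams()
    rng = np.random.default_rng(seed)
    fs = 1.0 / vp.dt
    theta = _theta()
    window = WindowSpec()
    n_ch = neural.n_channels

    theta_coh = {k: np.empty((n_participants, 2, n_ch))
                 for k in ("self", "other")}
    # closed-loop trials for all participants integrate as one batch
    block = max(2, n_trials // 2)
    while n_trials % block:
        block -= 1
    all_configs: List[TrialConfig] = []
    for p in range(n_participants):
        all_configs.extend(make_schedule(n_trials, block,
                                         seed=int(rng.integers(2 ** 31))))
    all_records = simulate_session(all_configs, hp, vp,
                                   seed=int(rng.integers(2 ** 31)))
    for p in range(n_participants):
        records = all_records[p * n_trials:(p + 1) * n_trials]
        neural_trials = []
        vels = {"self": [], "other": []}
        for i, rec in enumerate(records):
            seg = interaction_segments(len(rec.human_x), fs,
                                       rec.config.interaction_s)
            nrec = simulate_neural(rec, neural,
                                   seed=int(rng.integers(2 ** 31)))
            neural_trials.append(nrec.data[:, seg.retained])
            vels["self"].append(
                three_point_velocity(rec.human_x, fs)[seg.retained])
            vels["other"].append(
                three_point_velocity(rec.vp_x, fs)[seg.retained])
        for key in ("self", "other"):
            real = cortico_motor_coherence(neural_trials, vels[key], fs,
                                           window)
            scram = [phase_scramble(v, seed=int(rng.integers(2 ** 31)))
                     for v in vels[key]]
            ctrl = cortico_motor_coherence(neural_trials, scram, fs,
                                           window)
            theta_coh[key][p, 0] = band_summarize(real.coh, real.freqs,
                                                  theta)["Theta"]
            theta_coh[key][p, 1] = band_summarize(ctrl.coh, ctrl.freqs,
                                                  theta)["Theta"]

    spec = PermSpec(mode="exhaustive")
    flagged = {}
    for key in ("self", "other"):
        res = sign_flip_test(theta_coh[key], spec)
        flagged[key] = tuple(
            int(i) for i in
            np.nonzero((res.p_maxstat < alpha) & (res.t > 0))[0]
        )

    overlap = set(neural.groups["overlap"])
    want_self = set(neural.groups["self"]) | overlap
    want_other = set(neural.groups["other"]) | overlap
    hits = (len(want_self & set(flagged["self"]))
            + len(want_other & set(flagged["other"])))
    total = len(want_self) + len(want_other)
    background = set(neural.groups["background"])
    fp = bool(background & (set(flagged["self"]) | set(flagged["other"])))
    return RecoveryResult(
        flagged_self=flagged["self"],
        flagged_other=flagged["other"],
        sensitivity=hits / total if total else 1.0,
        any_false_positive=fp,
    )


def recovery_study(n_replicates: int = 100, seed: int = 0,
                   **kwargs) -> Dict[str, float]:
    """Replicate the recovery experiment; summarize sensitivity and FWER.

    Returns mean sensitivity across replicates and the family-wise error
    rate (fraction of replicates with any background channel flagged).
    """
    sens, fps = [], []
    for r in range(n_replicates):
        res = planted_recovery_experiment(seed=seed + 104729 * (r + 1),
                                          **kwargs)
        sens.append(res.sensitivity)
        fps.append(res.any_false_positive)
    return {
        "n_replicates": float(n_replicates),
        "sensitivity": float(np.mean(sens)),
        "fwer": float(np.mean(fps)),
    }


def behavioral_effect_replication(
    n_sessions: int = 20,
    n_trials: int = 80,
    block_size: int = 10,
    hp: Optional[HumanParams] = None,
    vp: Optional[VPParams] = None,
    seed: int = 0,
) -> Dict[str, object]:
    """Directional behavioral effects across seeded synthetic sessions.

    For each session (one synthetic participant) computes (a) mean
    stability of cooperative minus competitive halves and (b) mean
    second-half stability of no-transition minus transition trials.
    Returns the per-session differences and the fraction of sessions in
    the expected direction (cooperation more stable; transitions less
    stable).
    """
    hp = hp or HumanParams()
    vp = vp or VPParams()
    coop_minus_comp: List[float] = []
    notrans_minus_trans: List[float] = []
    for s in range(n_sessions):
        configs = make_schedule(n_trials, block_size, seed=seed + 613 * s)
        records = simulate_session(configs, hp, vp, seed=seed + 7717 * s)
        table = session_table(records, participant=s)
        by_beh = table.groupby("vp_behavior")["stability"].mean()
        coop_minus_comp.append(float(by_beh["coop"] - by_beh["comp"]))
        second = table[table.half == "second"]
        by_trans = second.groupby("transition")["stability"].mean()
        notrans_minus_trans.append(float(by_trans["no"] - by_trans["yes"]))
    return {
        "coop_minus_comp": coop_minus_comp,
        "notrans_minus_trans": notrans_minus_trans,
        "frac_coop_more_stable": float(
            np.mean(np.asarray(coop_minus_comp) > 0)),
        "frac_transition_less_stable": float(
            np.mean(np.asarray(notrans_minus_trans) > 0)),
    }
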