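"""Cortico-motor coherence with a phase-scrambled control.

Synthetic neural channels are planted with theta-band coherence to the
human's own movement velocity ("self" channels) or the VP's ("other"),
then contrasted against a phase-scrambled velocity using Z-coherence.
"""

import numpy as np

from hdclamp import (HumanParams, NeuralSimConfig, TrialConfig, VPParams,
                     band_summarize, cortico_motor_coherence,
                     default_bands, interaction_segments, phase_scramble,
                     simulate_neural, simulate_session,
                     three_point_velocity, z_coherence)

FS = 500.0
neural_cfg = NeuralSimConfig(
    n_channels=8,
    groups={"self": (0, 1), "other": (2, 3), "overlap": (4,),
            "background": (5, 6, 7)},
)

records = simulate_session([TrialConfig() for _ in range(20)],
                           HumanParams(), VPParams(), seed=2)
neural, vel = [], []
for i, rec in enumerate(records):
    seg = interaction_segments(len(rec.human_x), FS, 10.0)
    nrec = simulate_neural(rec, neural_cfg, seed=50 + i)
    neural.append(nrec.data[:, seg.retained])
    vel.append(three_point_velocity(rec.human_x, FS)[seg.retained])

real = cortico_motor_coherence(neural, vel, FS)
ctrl = cortico_motor_coherence(
    neural, [phase_scramble(v, seed=900 + i) for i, v in enumerate(vel)],
    FS)
theta = [b for b in default_bands() if b.name == "Theta"]
coh_real = band_summarize(real.coh, real.freqs, theta)["Theta"]
coh_ctrl = band_summarize(ctrl.coh, ctrl.freqs, theta)["Theta"]
z = z_coherence(coh_real, real.df, coh_ctrl, ctrl.df)

print(f"pooled windows: {real.df // 2} (df = {real.df})")
print("channel  group       theta coh   scrambled   Z")
groups = {i: g for g, idx in neural_cfg.groups.items() for i in idx}
for ch in range(neural_cfg.n_channels):
    print(f"  ch{ch:02d}   {groups[ch]:<10s}  {coh_real[ch]:.3f}       "
          f"{coh_ctrl[ch]:.3f}       {z[ch]:+.2f}")

# Planted self/overlap channels show theta coherence near the 0.6
# target and strongly positive Z against the scrambled control;
# background channels hover at the estimator's null level with Z ~ 0.
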