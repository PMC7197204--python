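# Methods

## The virtual partner

The VP integrates the hybrid HKB oscillator

ẍ = −(α x² + β ẋ² − γ) ẋ − ω² x + [A + B (x − μ y)²] (ẋ − μ ẏ)

with α = 0.641 (Van der Pol), β = 0.007095 (Rayleigh), γ = 12.457
(negative linear damping), A = −0.5, B = −0.25 (coupling) and
ω = 2π·1.6 rad/s. Intention is implemented by substituting
(y, ẏ) → (μy, μẏ) inside the coupling, so μ = +1 attracts the VP toward
its partner's phase and μ = −1 toward anti-phase. The canonical
literature on this model family writes the linear damping with several
sign conventions; the form above (with −γẋ *inside* the parenthesized
damping factor, i.e. net positive feedback at small amplitude) is the
only one that sustains a limit cycle with these published magnitudes,
so it is adopted deliberately rather than guessed silently.

Harmonic balance puts the uncoupled limit-cycle amplitude at
A² = 4γ/(α + 3βω²) ≈ 4.2; the simulated amplitude is ≈ 3.92 because the
residual self term (A + Bx²)ẋ of the zero-input coupling also
dissipates energy. The simulated dominant frequency is 1.611 Hz — the
nonlinearities shift it ~0.7 % above ω/2π — which rounds to the paced
1.6 Hz.

Integration is classical fixed-step RK4 at dt = 2 ms (500 Hz), the
coupling input held constant across the four substeps (zero-order
hold): a real-time device cannot see future input, and the hold keeps
runs bit-deterministic. Against a dt = 2·10⁻⁵ s reference the endpoint
position after 1 s agrees to better than 10⁻⁴. A divergence guard
(|x|, |v| > 10⁶) aborts loudly with the offending step index instead of
propagating NaNs. The display mapping quantizes position linearly onto
the 119 position-indexed animation frames with round-half-up and
clamping; the quantizer is not specified by the paradigm description,
and any monotone rule within half a frame is equivalent downstream.

## The synthetic participant

No movement or neural recordings ship with the package; a generator
module produces the full experiment synthetically so that every
analysis stage can be tested against known ground truth.

The human mover is a second HKB oscillator with the instructed pattern
as its intention (task μ = +1 in-phase, −1 anti-phase) plus additive
Gaussian acceleration noise (Euler–Maruyama term of scale
noise_sd·√dt added to the velocity after each deterministic RK4 step).
The loop is truly closed: the human receives the VP's state, the VP
receives the human's position and a causal three-point-differentiated
velocity, exactly as the apparatus computes it. The VP's initial phase
is randomized per trial; the human starts metronome-locked at phase
zero.

Two human parameters are deliberate design choices rather than copies
of the VP's values:

* **coupling** coup_a = −1.5, coup_b = 0. With the VP's own symmetric
  coupling on both sides, competition *increases* phase locking: the
  quadratic B term grows as (x − μy)² when the pair is away from the
  preferred pattern (amplitudes ≈ 4 make it dominate A by an order of
  magnitude) and digs a deep compromise well near |φ| ≈ 90°. Instructed
  humans do the opposite — they keep correcting toward the task target
  regardless of the current pattern — so the synthetic human uses a
  strong *linear* corrective gain and no pattern-dependent boost. In
  this regime competition becomes a genuine tug-of-war: the pattern is
  dragged off-target and is visibly less stable.
* **noise_sd = 40 units/s^1.5**. No quantitative human movement noise
  level is available for this paradigm; the value is an explicit
  calibration choice, set (once, together with the coupling sweep
  above) so that default sessions reproduce the paradigm's qualitative
  phenomena with realistic margins: cooperative halves more stable than
  competitive ones (session mean difference ≈ 0.07 in stability, 20/20
  seeded sessions), a second-half stability drop after mid-trial
  intention switches (≈ 0.10, 20/20), and cooperative-trial stability
  around 0.9–0.95 with |mean RP| under ~20°.

The schedule generator reproduces the design: 80 trials in 8 blocks of
10, one task per block, tasks counterbalanced across blocks, the four
VP behavior types (cooperative, competitive, and the two mid-trial
switches) balanced at 20 each and shuffled per seed.

The observer model maps each half's goal congruence c (one minus the
coordination score) through a logistic, report =
clip(logistic(8(c − ½)) + ε, 0, 1) with ε ~ N(0, 0.3²); the humanness
judgment is Bernoulli with probability increasing in the trial's
half-to-half stability change (logistic slope 25, midpoint 0.10),
blended toward a coin flip by stability_weight. The noise level 0.3 was
picked from the package's own Monte-Carlo calibration curve to put
session attribution accuracy near 0.8, and the humanness midpoint puts
the humanness rate near 50 % — both plausible human levels for this
task, chosen for realism, not fitted to any dataset. The calibration
sweep itself is part of the public API
(`calibrate_observer_noise`).

The neural generator is sensor-free: abstract channels rather than an
electrode montage, because source reconstruction is outside the
package's scope. A channel is 1/f background noise (unit-variance,
spectrally shaped), plus an optional theta-band (4–7 Hz) filtered copy
of the human's or the VP's movement velocity, plus a 10.5 Hz alpha
sinusoid whose power is multiplied by alpha_power_ratio in the
"interaction" condition (emulating movement-related alpha
suppression). The signal gain is solved per trial from the closed-form
per-bin coherence of signal-plus-noise, coh(f) = √(Q/(1+Q)) with
Q = g²P_s(f)/P_n(f), evaluated on the same Hamming-window spectra the
analysis uses, so that the predicted theta-band mean equals the
configured target. Pooled over 20 trials the planted band coherence is
recovered within ±0.1 of the 0.6 default.

What the generator does **not** emulate: movement amplitude drift,
learning or fatigue across blocks, reaction times, non-stationary or
non-Gaussian EEG artifacts, volume conduction between channels, and any
cognitive model of the humanness judgment. Passing tests therefore
demonstrate that the *pipeline* is correct and calibrated on data with
known structure — not that real humans behave like the generator.

## Behavioral measures

Preprocessing: mean-center, linear detrend, 2nd-order Butterworth
low-pass at 20 Hz applied forward and backward (zero phase; the
magnitude response is squared, so the 2nd-order design yields 4th-order
attenuation), then z-normalization — "normalized" is read as unit
variance, which downstream phase estimation is insensitive to. Relative
phase is the difference of analytic-signal (Hilbert) phases, human
minus VP, wrapped to (−π, π]. The first and last second of each 10-s
interaction are discarded (transients), leaving 8 s analyzed whole and
as two 4-s halves. Circular variance is 1 − R with R the mean resultant
length; stability = R. The coordination score is the circular distance
of the segment's *circular-mean* RP from the task target (0 or π),
normalized by π; a per-sample variant (mean of per-sample distances) is
available via `coordination_score(rp_sample, task)` applied samplewise,
but the circular-mean form is the default summary.

Attribution: a half's true behavior is cooperative when the VP's μ
matches the task target; the attribution score is 1 − |perceived −
actual| and a report is "correct" when it falls on the true side of
0.5, ties counted correct (the tie rule is a documented convention —
it affects only measure-zero reports). Session aggregates include
accuracy and the false-cooperation / false-competition rates. Subjective
reports are z-scored within participant with the population-SD
convention.

The analysis-time velocity uses the same causal three-point backward
difference as the apparatus ((3x[n] − 4x[n−1] + x[n−2])·fs/2, exact
for quadratics); a caller can substitute any other differentiator since
velocities enter the spectral layer as plain arrays.

## Spectral estimation and contrasts

Non-overlapping 1-s Hamming windows tile the retained 8 s (8 windows
per trial, 1 Hz resolution). Cross-spectra are averaged over all pooled
windows — across trials *before* normalization, which keeps the df
bookkeeping honest (df = 2 × pooled windows) and has lower bias than
averaging per-trial coherences. Bins where either signal has
numerically zero power give NaN ("missing"), never 0 or 1. Band
summaries average bins with lower ≤ f ≤ higher inclusive; F0 and F1 are
f_move ± 1 Hz and 2f_move ± 1 Hz. Band power is linear (not dB) mean
|F|².

The cross-spectrum is S_ij = (1/N)Σ F_i F_j* (conjugate on the second
factor — the only reading that makes S_ii real and non-negative). The
Z-coherence applies Fisher's atanh to |COH| before subtracting the
1/(df − 2) small-sample bias term; the denominator is
√(1/(df_A−2) + 1/(df_B−2)). Two numerical notes. First, coherence
exactly 1 is clipped to 1 − 10⁻¹⁰ (with a warning) before atanh.
Second, the 1/(df − 2) variance describes the estimator at *nonzero*
coherence: under the null of no condition difference at equal true
coherence ≈ 0.5 the signed tail rate at the Gaussian 97.5 % quantile is
2.5 % (verified by Monte-Carlo through the package's own estimator);
for strictly independent signals the magnitude-coherence estimator has
smaller variance and the statistic is conservative (tail ≪ 2.5 %),
never anti-conservative. Phase-scrambled surrogates preserve the
amplitude spectrum exactly (random phases with conjugate symmetry; DC
kept, Nyquist sign randomized) and serve as the control condition for
cortico-motor coherence. Note that two series sharing one amplitude
spectrum have a windowed-coherence null level slightly above the
independent-noise 1/N floor (their per-window envelopes correlate), so
surrogate-based contrasts are compared against surrogate-vs-surrogate
nulls, not the independent floor.

## Permutation inference

Paired designs only: the null flips the sign of each participant's
condition difference. Sign flips leave every squared difference
unchanged, so the per-permutation t is computed from the flipped mean
alone — this makes exhaustive enumeration of 2^n assignments cheap
(chunked lazily, guarded above 2^26; Monte-Carlo mode with the identity
included otherwise). p-values count the identity assignment in both
numerator and denominator and therefore never reach zero. Family-wise
correction uses the permutation distribution of max |t| over features.
Cluster statistics threshold |t| at the two-tailed parametric quantile
(default α = 0.05), build connected components under a symmetric,
irreflexive adjacency separately for positive and negative signs, and
use cluster mass Σ|t| (size available by option) against the
permutation null of the maximum cluster statistic; chain adjacencies
take a vectorized run-labeling fast path that is tested to match the
generic graph path exactly. FDR correction is Benjamini–Hochberg
step-up (via statsmodels).

Calibration, verified in the test suite: type-I error of the
uncorrected test at α = 0.05 lies in [0.03, 0.07] over 1000 null
datasets; on 100 replicate synthetic experiments (8 participants × 20
trials, planted theta coherence 0.6) the max-stat pipeline recovers the
planted self/other/overlap channels with sensitivity ≥ 0.9 at
family-wise error ≤ 0.05.

## The experiment runner

`run_experiment` chains every stage — schedules, closed-loop
simulation, reports, tidy behavior table, synthetic neural data,
self/other cortico-motor coherence with scrambled controls, Z maps,
alpha-power contrast (interaction vs solo, FDR-corrected), max-stat
channel tests and frequency-axis cluster statistics — into an output
directory. All randomness derives from one master seed through named
SeedSequence spawns (each derived seed < 2³¹), and the manifest records
the config snapshot, per-stage seeds and SHA-256 checksums of every
file; re-running with the same master seed reproduces the checksums
bit-for-bit. The closed-loop integrator is vectorized over trials, so a
full 20-participant × 80-trial session batch integrates in seconds.

## Problem sizes used in validation

The package's own validation studies run at deliberately reduced scale
chosen to exercise the same statistics with comfortable margins: the
planted-recovery study uses 100 replicates of 8 participants × 20
trials × 8 channels with exhaustive 2^8 permutations; the behavioral
replication uses 20 sessions of the full 80-trial design; null
calibrations use 1000–2000 Monte-Carlo draws. The exhaustive 2^20
permutation group of the full design is enumerated (lazily) to verify
its size, while full max-stat inference at n = 20 uses the seeded
Monte-Carlo mode.

## Known limitations

* The VP equation's sign conventions are fixed by the limit-cycle
  argument above; if the original apparatus used a different γ
  convention the trajectories would differ in shape, though not in the
  paced frequency or the in-/anti-phase attractor structure.
* The human model is the simplest generator consistent with the
  phenomena (bistability, frustration under competition); its
  parameters are calibration choices, not estimates of human movers.
* Coherence assumes within-trial stationarity of the retained 8 s;
  there is no time-frequency resolution.
* Only paired two-condition designs are supported by the permutation
  module; unpaired and factorial inference are out of scope, as are
  source reconstruction and electrode-level EEG processing.
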