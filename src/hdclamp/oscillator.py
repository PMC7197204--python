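"""The virtual partner: a hybrid Van der Pol/Rayleigh (HKB) oscillator.

The VP is a single nonlinear oscillator whose acceleration is

    x'' = -(alpha x^2 + beta x'^2 - gamma) x' - omega^2 x
          + [A + B (x - mu y)^2] (x' - mu y')

where (y, y') is the partner's position and velocity, A and B set the
coupling, and mu in {-1, +1} is the VP's intention: +1 biases it toward
moving in-phase with the partner, -1 toward anti-phase. The Van der Pol
(alpha x^2 x') and Rayleigh (beta x'^3) terms shape and saturate the
cycle while the negative linear damping (-gamma x') sustains it, so the
uncoupled unit settles on a stable limit cycle at its intrinsic frequency.

Integration is classical fixed-step RK4 at 500 Hz with the coupling input
held constant across substeps (zero-order hold), mirroring a real-time
apparatus that cannot see future input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "VPParams",
    "OscState",
    "CouplingInput",
    "VPTrajectory",
    "FrameCalib",
    "NumericalBlowupError",
    "vp_derivative",
    "rk4_step",
    "simulate_vp",
    "frame_index",
    "limit_cycle_amplitude",
    "dominant_frequency",
    "latency_cycle_percent",
]

#: Default divergence guard on |x| and |v| (arbitrary position units).
BLOWUP_BOUND = 1e6


class NumericalBlowupError(RuntimeError):
    """Raised when the integrator diverges past the guard bound."""


class OscState(NamedTuple):
    """Oscillator state: position x (normalized units) and velocity v."""

    x: float
    v: float


class CouplingInput(NamedTuple):
    """Partner movement fed into the coupling: position y and velocity y_dot."""

    y: float
    y_dot: float


ZERO_INPUT = CouplingInput(0.0, 0.0)


@dataclass(frozen=True)
class VPParams:
    """Parameters of the VP oscillator.

    Defaults are the values used by the human-dynamic-clamp apparatus:
    intrinsic frequency 1.6 Hz (omega = 2*pi*1.6 rad/s), Van der Pol
    coefficient 0.641, Rayleigh coefficient 0.007095, linear damping
    12.457, coupling A = -0.5 and B = -0.25, integrated at dt = 2 ms.
    """

    f_intrinsic: float = 1.6
    omega: float = 2.0 * math.pi * 1.6
    alpha_vdp: float = 0.641
    beta_ray: float = 0.007095
    gamma_damp: float = 12.457
    coup_a: float = -0.5
    coup_b: float = -0.25
    mu: int = 1
    dt: float = 0.002

    def __post_init__(self) -> None:
        if self.mu not in (-1, 1):
            raise ValueError(f"mu must be +1 or -1, got {self.mu}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if not math.isclose(self.omega, 2.0 * math.pi * self.f_intrinsic,
                            rel_tol=1e-9):
            raise ValueError(
                "inconsistent parameters: omega must equal 2*pi*f_intrinsic "
                f"(omega={self.omega}, f_intrinsic={self.f_intrinsic})"
            )

    @classmethod
    def with_frequency(cls, f_intrinsic: float, **kw) -> "VPParams":
        return cls(f_intrinsic=f_intrinsic,
                   omega=2.0 * math.pi * f_intrinsic, **kw)


@dataclass(frozen=True)
class VPTrajectory:
    """A simulated trajectory on the uniform dt grid."""

    t: np.ndarray
    x_series: np.ndarray
    v_series: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.x_series) == len(self.v_series)):
            raise ValueError("trajectory arrays must have equal length")


@dataclass(frozen=True)
class FrameCalib:
    """Linear calibration from position to a display-frame index.

    The apparatus displayed one of n_frames (119) photographs of a finger,
    indexed by position over one movement cycle.
    """

    x_min: float
    x_max: float
    n_frames: int = 119

    def __post_init__(self) -> None:
        if not self.x_min < self.x_max:
            raise ValueError("x_min must be < x_max")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")


def _check_finite(*vals: float) -> None:
    for v in vals:
        if not math.isfinite(v):
            raise ValueError(f"non-finite input to VP equation: {v!r}")


def vp_derivative(state: OscState, inp: CouplingInput,
                  p: VPParams) -> OscState:
    """Time derivative (dx/dt, dv/dt) of the VP equation. Pure function."""
    x, v = state
    y, yd = inp
    _check_finite(x, v, y, yd)
    acc = (
        -(p.alpha_vdp * x * x + p.beta_ray * v * v - p.gamma_damp) * v
        - p.omega * p.omega * x
        + (p.coup_a + p.coup_b * (x - p.mu * y) ** 2) * (v - p.mu * yd)
    )
    return OscState(v, acc)


def rk4_step(state: OscState, inp: CouplingInput, p: VPParams,
             blowup_bound: float = BLOWUP_BOUND,
             step_index: Optional[int] = None) -> OscState:
    """One classical RK4 step of length p.dt with the input held constant."""
    dt = p.dt
    k1 = vp_derivative(state, inp, p)
    k2 = vp_derivative(OscState(state.x + dt / 2 * k1.x,
                                state.v + dt / 2 * k1.v), inp, p)
    k3 = vp_derivative(OscState(state.x + dt / 2 * k2.x,
                                state.v + dt / 2 * k2.v), inp, p)
    k4 = vp_derivative(OscState(state.x + dt * k3.x,
                                state.v + dt * k3.v), inp, p)
    new = OscState(
        state.x + dt / 6 * (k1.x + 2 * k2.x + 2 * k3.x + k4.x),
        state.v + dt / 6 * (k1.v + 2 * k2.v + 2 * k3.v + k4.v),
    )
    if (not math.isfinite(new.x) or not math.isfinite(new.v)
            or abs(new.x) > blowup_bound or abs(new.v) > blowup_bound):
        where = "" if step_index is None else f" at step {step_index}"
        raise NumericalBlowupError(
            f"VP integration diverged{where}: state ({new.x!r}, {new.v!r}) "
            f"exceeds bound {blowup_bound:g}"
        )
    return new


def simulate_vp(input_series: Optional[Sequence[Tuple[float, float]]],
                p: VPParams,
                init: OscState = OscState(0.1, 0.0),
                n_steps: Optional[int] = None,
                blowup_bound: float = BLOWUP_BOUND) -> VPTrajectory:
    """Integrate the VP driven by a sampled input series on the dt grid.

    input_series is a sequence of (y, y_dot) pairs, one per step; None (or
    an empty sequence) with n_steps set runs the oscillator with zero
    input, i.e. uncoupled up to the residual (A + B x^2) x' self term.
    """
    if input_series is None or len(input_series) == 0:
        if n_steps is None:
            raise ValueError("n_steps is required for an uncoupled run")
        inputs = None
    else:
        inputs = np.asarray(input_series, dtype=float)
        if inputs.ndim != 2 or inputs.shape[1] != 2:
            raise ValueError("input_series must be a sequence of (y, y_dot)")
        if n_steps is not None and n_steps != len(inputs):
            raise ValueError("n_steps conflicts with len(input_series)")
        n_steps = len(inputs)

    xs = np.empty(n_steps)
    vs = np.empty(n_steps)
    state = OscState(*init)
    for i in range(n_steps):
        xs[i] = state.x
        vs[i] = state.v
        inp = ZERO_INPUT if inputs is None else CouplingInput(*inputs[i])
        state = rk4_step(state, inp, p, blowup_bound=blowup_bound,
                         step_index=i)
    t = np.arange(n_steps) * p.dt
    return VPTrajectory(t=t, x_series=xs, v_series=vs)


def frame_index(x: float, calib: FrameCalib) -> int:
    """Display-frame index in [1, n_frames] for a position.

    Linear map over [x_min, x_max] quantized with round-half-up; positions
    outside the calibration span are clamped to the first/last frame.
    """
    if x <= calib.x_min:
        return 1
    if x >= calib.x_max:
        return calib.n_frames
    frac = (x - calib.x_min) / (calib.x_max - calib.x_min)
    idx = 1 + math.floor(frac * (calib.n_frames - 1) + 0.5)
    return min(max(idx, 1), calib.n_frames)


def limit_cycle_amplitude(p: VPParams) -> float:
    """Harmonic-balance estimate of the uncoupled limit-cycle amplitude.

    Setting the cycle-averaged damping power to zero for x = A sin(omega t)
    gives A^2 = 4 gamma / (alpha + 3 beta omega^2). Used for initial
    conditions; the simulated amplitude differs slightly because the
    residual self-coupling term also dissipates energy.
    """
    return math.sqrt(
        4.0 * p.gamma_damp
        / (p.alpha_vdp + 3.0 * p.beta_ray * p.omega ** 2)
    )


def dominant_frequency(x: np.ndarray, fs: float,
                       method: str = "cycles") -> float:
    """Dominant oscillation frequency (Hz) of a zero-mean-ish series.

    "cycles" counts upward zero crossings of the mean-centered signal
    (robust for narrow-band oscillations); "spectrum" takes the peak of a
    zero-padded periodogram.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("series too short for frequency estimation")
    xc = x - x.mean()
    if method == "cycles":
        s = np.signbit(xc)
        ups = np.nonzero(s[:-1] & ~s[1:])[0]
        if len(ups) < 2:
            raise ValueError("fewer than two cycles in the series")
        # count whole cycles between first and last upward crossing
        span = (ups[-1] - ups[0]) / fs
        return (len(ups) - 1) / span
    if method == "spectrum":
        n = int(2 ** math.ceil(math.log2(len(xc) * 4)))
        spec = np.abs(np.fft.rfft(np.hanning(len(xc)) * xc, n=n))
        freqs = np.fft.rfftfreq(n, 1.0 / fs)
        return float(freqs[np.argmax(spec)])
    raise ValueError(f"unknown method {method!r}")


def latency_cycle_percent(latency_s: float, f_move: float) -> float:
    """A latency expressed as a percentage of one movement cycle."""
    return 100.0 * latency_s * f_move
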