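"""Synthetic multichannel neural signals with planted cortico-motor coherence.

Channels are abstract sensors (no montage or source model). Each trial's
channels are built from three ingredients:

* a theta-band (4-7 Hz) filtered copy of a movement velocity -- the
  human's own ("self" channels), the VP's ("other" channels), or both
  ("overlap" channels) -- scaled so that the theta-band magnitude
  coherence between the channel and that velocity hits a configured
  target;
* 1/f^e background noise (all channels, and nothing else on
  "background" channels);
* a 10.5 Hz alpha sinusoid whose power is multiplied by
  alpha_power_ratio in the "interaction" condition relative to "solo",
  emulating movement/interaction-related alpha suppression.

The scaling uses the closed-form per-bin coherence of a
filtered-signal-plus-noise channel, coh(f) = sqrt(Q/(1+Q)) with
Q = g^2 P_s(f) / P_n(f), evaluated on the same Hamming-windowed spectra
the analysis uses, and solves for the gain g whose predicted theta-band
mean equals the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps
from scipy.optimize import brentq

from .behavior import interaction_segments, three_point_velocity
from .records import TrialRecord
from .spectral import WindowSpec, windowed_spectra

__all__ = [
    "NeuralSimConfig",
    "NeuralRecord",
    "simulate_neural",
    "one_over_f_noise",
]

THETA_BAND = (4.0, 7.0)
ALPHA_FREQ_HZ = 10.5


@dataclass(frozen=True)
class NeuralSimConfig:
    """Layout and targets for the synthetic neural recording.

    groups maps "self" / "other" / "overlap" / "background" to disjoint
    channel-index tuples covering range(n_channels).
    theta_coherence_target is the planted theta-band coherence between a
    coherent channel and its movement velocity; alpha_power_ratio < 1
    means alpha suppression during interaction; noise_exponent is the e
    of the 1/f^e background; alpha_amplitude is the solo-condition
    alpha-sinusoid amplitude relative to the noise standard deviation.
    """

    n_channels: int = 16
    groups: Dict[str, Tuple[int, ...]] = field(default_factory=lambda: {
        "self": (0, 1, 2),
        "other": (3, 4, 5),
        "overlap": (6, 7),
        "background": tuple(range(8, 16)),
    })
    theta_coherence_target: float = 0.6
    alpha_power_ratio: float = 0.5
    noise_exponent: float = 1.0
    noise_sd: float = 1.0
    alpha_amplitude: float = 1.0
    fs_neural: float = 500.0

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_coherence_target < 1.0:
            raise ValueError("theta_coherence_target must lie in (0, 1)")
        if self.alpha_power_ratio <= 0:
            raise ValueError("alpha_power_ratio must be positive")
        expected = set(range(self.n_channels))
        seen: set = set()
        for name in ("self", "other", "overlap", "background"):
            if name not in self.groups:
                raise ValueError(f"groups must define {name!r}")
            idx = set(self.groups[name])
            if idx & seen:
                raise ValueError(
                    f"channel groups must be disjoint; {sorted(idx & seen)} "
                    "assigned twice"
                )
            seen |= idx
        if seen != expected:
            raise ValueError(
                f"groups must cover all {self.n_channels} channels exactly"
            )


@dataclass
class NeuralRecord:
    """Multichannel synthetic recording aligned with one trial."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    labels: List[str]
    groups: Dict[str, Tuple[int, ...]]
    condition: str = "interaction"


def one_over_f_noise(n_samples: int, exponent: float,
                     rng: np.random.Generator,
                     size: int = 1) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum, unit variance.

    Returns (size, n_samples).
    """
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    white = rng.standard_normal((size, n_samples))
    shaped = np.fft.irfft(np.fft.rfft(white, axis=1) * scale, n=n_samples,
                          axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    return shaped / np.where(sd == 0, 1.0, sd)


@lru_cache(maxsize=8)
def _theta_sos(fs: float) -> np.ndarray:
    return sps.butter(4, [THETA_BAND[0] / (fs / 2),
                          THETA_BAND[1] / (fs / 2)],
                      btype="bandpass", output="sos")


def _theta_bandpass(x: np.ndarray, fs: float) -> np.ndarray:
    return sps.sosfiltfilt(_theta_sos(fs), x)


def _band_mask(freqs: np.ndarray) -> np.ndarray:
    return (freqs >= THETA_BAND[0]) & (freqs <= THETA_BAND[1])


def _window_power(x: np.ndarray, fs: float,
                  spec: WindowSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Mean Hamming-windowed power spectrum over the retained segment."""
    ss = windowed_spectra(x, fs, spec)
    return np.mean(np.abs(ss.F[0]) ** 2, axis=0), ss.freqs


def _solve_gain(p_signal: np.ndarray, p_noise: np.ndarray,
                mask: np.ndarray, target: float) -> float:
    """Gain g with predicted band-mean coherence = target.

    Predicted per-bin coherence: sqrt(Q/(1+Q)), Q = g^2 Ps/Pn; bins with
    negligible signal power contribute their (near-zero) coherence to the
    band mean just as they do in the analysis.
    """
    ps = p_signal[mask]
    pn = p_noise[mask]
    valid = (ps > 0) & (pn > 0)
    if not valid.any():
        raise ValueError("no usable theta-band signal power to plant")

    def band_coh(log_g: float) -> float:
        q = math.exp(2.0 * log_g) * ps[valid] / pn[valid]
        coh = np.sqrt(q / (1.0 + q))
        return float(np.sum(coh) / mask.sum())

    lo, hi = -12.0, 12.0
    if band_coh(hi) < target:
        return math.exp(hi)  # saturated: plant as coherent as possible
    if band_coh(lo) >= target:
        return math.exp(lo)  # noise-free: any gain gives full coherence
    return math.exp(brentq(lambda lg: band_coh(lg) - target, lo, hi,
                           xtol=1e-6))


def simulate_neural(rec: TrialRecord, cfg: NeuralSimConfig,
                    seed: Optional[int] = 0,
                    condition: str = "interaction",
                    window: WindowSpec = WindowSpec()) -> NeuralRecord:
    """Synthesize one trial's multichannel neural recording.

    Channel groups get theta-filtered copies of the human and/or VP
    movement velocity at the planted coherence target, on top of 1/f
    noise; the alpha sinusoid is attenuated in the "interaction"
    condition. Deterministic per seed.
    """
    if condition not in ("interaction", "solo"):
        raise ValueError(f"unknown condition {condition!r}")
    fs = cfg.fs_neural
    if not math.isclose(fs, rec.config.fs, rel_tol=1e-9):
        raise ValueError("fs_neural must match the trial sampling rate")
    rng = np.random.default_rng(seed)
    n = len(rec.human_x)
    seg = interaction_segments(n, fs, rec.config.interaction_s)

    v_self = three_point_velocity(rec.human_x, fs)
    v_other = three_point_velocity(rec.vp_x, fs)
    sigs = {}
    for name, v in (("self", v_self), ("other", v_other)):
        s = _theta_bandpass(v, fs)
        p_sig, freqs = _window_power(s[seg.retained], fs, window)
        sigs[name] = (s, p_sig)
    mask = _band_mask(freqs)

    noise = cfg.noise_sd * one_over_f_noise(n, cfg.noise_exponent, rng,
                                            size=cfg.n_channels)
    # channel-averaged noise spectrum for a stable gain estimate
    ns = windowed_spectra(noise[:, seg.retained], fs, window)
    p_noise = np.mean(np.abs(ns.F) ** 2, axis=(0, 1))
    p_noise = np.maximum(p_noise, 1e-30)

    gains = {
        name: _solve_gain(p_sig, p_noise, mask, cfg.theta_coherence_target)
        for name, (_, p_sig) in sigs.items()
    }

    data = noise.copy()
    for name, members in (("self", ("self",)), ("other", ("other",)),
                          ("overlap", ("self", "other"))):
        for ch in cfg.groups[name]:
            for m in members:
                data[ch] += gains[m] * sigs[m][0]

    amp = cfg.alpha_amplitude * cfg.noise_sd
    if condition == "interaction":
        amp *= math.sqrt(cfg.alpha_power_ratio)
    t = np.arange(n) / fs
    phases = rng.uniform(0, 2 * np.pi, cfg.n_channels)
    data += amp * np.sin(2 * np.pi * ALPHA_FREQ_HZ * t[None, :]
                         + phases[:, None])

    labels = [f"ch{idx:02d}" for idx in range(cfg.n_channels)]
    return NeuralRecord(data=data, fs=fs, labels=labels,
                        groups=dict(cfg.groups), condition=condition)
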