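"""Windowed spectra, coherence, Z-coherence, frequency bands, surrogates.

Spectra are estimated on non-overlapping 1-s Hamming-tapered windows
(frequency resolution 1 Hz), so an 8-s retained interaction yields 8
windows per trial. Coherence between channels i and j pools the
cross-spectrum over all supplied windows (optionally across trials):

    S_ij(f) = (1/N) sum_w F_i^w(f) conj(F_j^w(f))
    COH_ij(f) = |S_ij(f)| / sqrt(S_ii(f) S_jj(f))

with degrees of freedom df = 2 N tracked alongside. Two conditions are
contrasted with the variance-stabilized, bias-corrected Z-coherence

    Z = [(atanh|COH_A| - 1/(df_A - 2)) - (atanh|COH_B| - 1/(df_B - 2))]
        / sqrt(1/(df_A - 2) + 1/(df_B - 2))

whose sign says which condition is more coherent. Phase-scrambled
surrogates (amplitude spectrum preserved, Fourier phases randomized)
provide the control condition for cortico-motor coherence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "WindowSpec",
    "SpectralSet",
    "CoherenceResult",
    "Band",
    "default_bands",
    "windowed_spectra",
    "pool_spectra",
    "coherence",
    "coherence_with_reference",
    "z_coherence",
    "band_summarize",
    "band_power",
    "cortico_motor_coherence",
    "phase_scramble",
]

#: Coherence magnitudes are clipped here before atanh.
_COH_CLIP = 1.0 - 1e-10


@dataclass(frozen=True)
class WindowSpec:
    """Tapered-window layout for spectral estimation."""

    win_s: float = 1.0
    overlap_s: float = 0.0
    taper: str = "hamming"

    def n_samples(self, fs: float) -> int:
        n = self.win_s * fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"win_s * fs = {n} is not an integer")
        return int(round(n))


@dataclass(frozen=True)
class SpectralSet:
    """Complex Fourier coefficients F[channel, window, frequency]."""

    F: np.ndarray
    freqs: np.ndarray
    fs: float
    win_s: float

    def __post_init__(self) -> None:
        if self.F.ndim != 3:
            raise ValueError("F must be (n_channels, n_windows, n_freqs)")
        if self.F.shape[2] != len(self.freqs):
            raise ValueError("frequency axis mismatch")

    @property
    def n_channels(self) -> int:
        return self.F.shape[0]

    @property
    def n_windows(self) -> int:
        return self.F.shape[1]


@dataclass(frozen=True)
class CoherenceResult:
    """Pooled cross-spectrum and magnitude coherence with tracked df.

    coh has shape (..., n_freqs) in [0, 1]; bins where either channel has
    (numerically) zero power are NaN ("missing", neither 0 nor 1).
    """

    coh: np.ndarray
    freqs: np.ndarray
    df: int
    S: Optional[np.ndarray] = None


@dataclass(frozen=True)
class Band:
    name: str
    lower_hz: float
    higher_hz: float

    def __post_init__(self) -> None:
        if not self.lower_hz < self.higher_hz:
            raise ValueError(
                f"band {self.name}: lower bound must be below higher bound"
            )


def default_bands(f_move: float = 1.6) -> List[Band]:
    """Frequency bands of interest.

    F0 and F1 are centered on the movement fundamental and its first
    harmonic (+/- 1 Hz); the remaining bands are the conventional EEG
    divisions used by the study.
    """
    return [
        Band("F0", f_move - 1.0, f_move + 1.0),
        Band("F1", 2 * f_move - 1.0, 2 * f_move + 1.0),
        Band("Delta", 1.0, 4.0),
        Band("Theta", 4.0, 7.0),
        Band("Low-alpha", 7.0, 10.0),
        Band("High-alpha", 10.0, 13.0),
        Band("Beta", 13.0, 30.0),
        Band("Gamma", 30.0, 60.0),
    ]


def windowed_spectra(x: np.ndarray, fs: float,
                     spec: WindowSpec = WindowSpec()) -> SpectralSet:
    """Per-window tapered DFT of a (multi)channel segment.

    x: (n_channels, n_samples) or (n_samples,). The segment length must be
    an exact multiple of the window length (windows are non-overlapping
    and tile the segment).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if spec.overlap_s != 0.0:
        raise NotImplementedError("only non-overlapping windows supported")
    nwin = spec.n_samples(fs)
    n_ch, n = x.shape
    if n % nwin != 0:
        raise ValueError(
            f"segment length {n} is not a multiple of the window length "
            f"{nwin} (expected k * {nwin} samples)"
        )
    if spec.taper != "hamming":
        raise ValueError(f"unsupported taper {spec.taper!r}")
    taper = np.hamming(nwin)
    segs = x.reshape(n_ch, n // nwin, nwin) * taper
    F = np.fft.rfft(segs, axis=2)
    freqs = np.fft.rfftfreq(nwin, 1.0 / fs)
    return SpectralSet(F=F, freqs=freqs, fs=fs, win_s=spec.win_s)


def pool_spectra(sets: Sequence[SpectralSet]) -> SpectralSet:
    """Concatenate window axes of spectra from several trials."""
    if not sets:
        raise ValueError("no spectra to pool")
    first = sets[0]
    for s in sets[1:]:
        if (s.F.shape[0] != first.F.shape[0]
                or not np.allclose(s.freqs, first.freqs)):
            raise ValueError("incompatible spectra cannot be pooled")
    F = np.concatenate([s.F for s in sets], axis=1)
    return SpectralSet(F=F, freqs=first.freqs, fs=first.fs,
                       win_s=first.win_s)


def _pooled_cross(Fi: np.ndarray, Fj: np.ndarray) -> np.ndarray:
    return np.mean(Fi * np.conj(Fj), axis=-2)


def coherence(spectra: Union[SpectralSet, Sequence[SpectralSet]],
              i: int, j: int) -> CoherenceResult:
    """Magnitude coherence between channels i and j.

    Accepts one SpectralSet or a sequence (windows pooled across trials
    before normalization). df = 2 x total pooled windows.
    """
    if isinstance(spectra, SpectralSet):
        pooled = spectra
    else:
        pooled = pool_spectra(list(spectra))
    if pooled.n_windows < 2:
        raise ValueError("coherence needs at least 2 windows")
    Fi, Fj = pooled.F[i], pooled.F[j]
    Sij = _pooled_cross(Fi, Fj)
    Sii = np.real(_pooled_cross(Fi, Fi))
    Sjj = np.real(_pooled_cross(Fj, Fj))
    denom = Sii * Sjj
    scale = float(np.max(denom)) if np.max(denom) > 0 else 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(Sij) / np.sqrt(denom)
    coh = np.where(denom > scale * 1e-24, coh, np.nan)
    return CoherenceResult(coh=coh, freqs=pooled.freqs,
                           df=2 * pooled.n_windows, S=Sij)


def coherence_with_reference(
    spectra: Union[SpectralSet, Sequence[SpectralSet]],
    ref_spectra: Union[SpectralSet, Sequence[SpectralSet]],
    ref_channel: int = 0,
) -> CoherenceResult:
    """Coherence of every channel with one reference channel.

    Pools windows across trials; the reference windows must align
    one-to-one with the channel windows. Returns coh of shape
    (n_channels, n_freqs).
    """
    ch = (spectra if isinstance(spectra, SpectralSet)
          else pool_spectra(list(spectra)))
    ref = (ref_spectra if isinstance(ref_spectra, SpectralSet)
           else pool_spectra(list(ref_spectra)))
    if ch.n_windows != ref.n_windows:
        raise ValueError(
            f"channel spectra have {ch.n_windows} windows but the "
            f"reference has {ref.n_windows}"
        )
    if ch.n_windows < 2:
        raise ValueError("coherence needs at least 2 windows")
    Fr = ref.F[ref_channel]
    Sij = np.mean(ch.F * np.conj(Fr)[None, :, :], axis=1)
    Sii = np.mean(np.abs(ch.F) ** 2, axis=1)
    Srr = np.mean(np.abs(Fr) ** 2, axis=0)
    denom = Sii * Srr[None, :]
    scale = float(np.max(denom)) if np.max(denom) > 0 else 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(Sij) / np.sqrt(denom)
    coh = np.where(denom > scale * 1e-24, coh, np.nan)
    return CoherenceResult(coh=coh, freqs=ch.freqs,
                           df=2 * ch.n_windows, S=Sij)


def z_coherence(coh_a: np.ndarray, df_a: int,
                coh_b: np.ndarray, df_b: int) -> np.ndarray:
    """Bias-corrected, variance-stabilized coherence contrast.

    Positive Z means condition A is more coherent than B. Antisymmetric
    under swapping the conditions. Coherences of exactly 1 are clipped
    just below 1 (with a warning) so atanh stays finite.
    """
    if df_a <= 2 or df_b <= 2:
        raise ValueError("degrees of freedom must exceed 2")
    coh_a = np.abs(np.asarray(coh_a, dtype=float))
    coh_b = np.abs(np.asarray(coh_b, dtype=float))
    if np.nanmax(coh_a, initial=0.0) >= 1.0 or \
            np.nanmax(coh_b, initial=0.0) >= 1.0:
        warnings.warn("coherence of 1 clipped to 1 - 1e-10 before atanh",
                      RuntimeWarning, stacklevel=2)
    za = np.arctanh(np.clip(coh_a, 0.0, _COH_CLIP)) - 1.0 / (df_a - 2)
    zb = np.arctanh(np.clip(coh_b, 0.0, _COH_CLIP)) - 1.0 / (df_b - 2)
    return (za - zb) / np.sqrt(1.0 / (df_a - 2) + 1.0 / (df_b - 2))


def band_summarize(values: np.ndarray, freqs: np.ndarray,
                   bands: Sequence[Band]) -> Dict[str, np.ndarray]:
    """Mean over frequency bins with lower <= f <= higher, per band.

    values may have any leading shape; the last axis is frequency.
    NaN bins (missing coherence) are ignored within a band.
    """
    values = np.asarray(values, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    out: Dict[str, np.ndarray] = {}
    for band in bands:
        mask = (freqs >= band.lower_hz) & (freqs <= band.higher_hz)
        if not mask.any():
            raise ValueError(
                f"band {band.name} [{band.lower_hz}, {band.higher_hz}] Hz "
                f"contains no bins of the grid "
                f"[{freqs.min()}, {freqs.max()}] Hz"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[band.name] = np.nanmean(values[..., mask], axis=-1)
    return out


def band_power(spectra: Union[SpectralSet, Sequence[SpectralSet]],
               bands: Sequence[Band]) -> Dict[str, np.ndarray]:
    """Mean squared spectral magnitude per channel and band (linear power)."""
    pooled = (spectra if isinstance(spectra, SpectralSet)
              else pool_spectra(list(spectra)))
    power = np.mean(np.abs(pooled.F) ** 2, axis=1)  # (n_ch, n_freq)
    return band_summarize(power, pooled.freqs, bands)


def cortico_motor_coherence(
    neural_trials: Sequence[np.ndarray],
    velocity_trials: Sequence[np.ndarray],
    fs: float,
    spec: WindowSpec = WindowSpec(),
) -> CoherenceResult:
    """Coherence of each neural channel with a movement-velocity series.

    neural_trials: per trial, an (n_channels, n_samples) segment (already
    trimmed to the retained 8 s). velocity_trials: matching 1-d velocity
    segments on the same sampling grid. Windows are pooled across trials.
    """
    if len(neural_trials) != len(velocity_trials):
        raise ValueError("need one velocity series per neural trial")
    ch_sets = [windowed_spectra(n, fs, spec) for n in neural_trials]
    ref_sets = [windowed_spectra(v, fs, spec) for v in velocity_trials]
    return coherence_with_reference(ch_sets, ref_sets)


def phase_scramble(x: np.ndarray, seed: Optional[int] = None) -> np.ndarray:
    """Surrogate with the same amplitude spectrum but random phases.

    Positive-frequency phases are replaced by iid uniform draws with
    conjugate symmetry enforced; the DC and (for even length) Nyquist
    coefficients keep their magnitude with a random sign, so the output
    is exactly real. Deterministic for a fixed seed.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 samples to phase-scramble")
    rng = np.random.default_rng(seed)
    X = np.fft.rfft(x)
    mag = np.abs(X)
    phases = rng.uniform(0.0, 2.0 * np.pi, len(X))
    Xs = mag * np.exp(1j * phases)
    Xs[0] = mag[0] * np.sign(X.real[0]) if X.real[0] != 0 else 0.0
    if n % 2 == 0:
        Xs[-1] = mag[-1] * rng.choice([-1.0, 1.0])
    return np.fft.irfft(Xs, n=n)
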