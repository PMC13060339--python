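"""Stimulus synthesis: tones, band-limited noises, and fluctuation-controlled
narrow-band stimuli.

All stimuli follow the same conventions: 1-s duration at 44.1 kHz with
200-ms raised-cosine (Hann half-window) onset/offset ramps; samples are
sound pressures in pascals, so a level of L dB SPL corresponds to an RMS
pressure of ``20e-6 * 10**(L/20)`` Pa over the central steady-state segment
(the segment untouched by the ramps).  Every generator first normalizes the
steady-state RMS of the raw waveform to exactly 1, then scales to the
requested level, then applies the ramps; generators are pure functions of
(spec, seed).

Band-limited noises are synthesized in the frequency domain: bins strictly
inside the geometric passband ``[fc * 2**(-bw/2), fc * 2**(bw/2)]`` receive
independent Rayleigh magnitudes and uniform phases, all other bins are
exactly zero, and the real waveform is obtained by an inverse FFT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy.signal import hilbert

from .errors import DegenerateBandError, InvalidSpecError

P_REF = 20e-6  # Pa, reference pressure for dB SPL


class StimType(str, Enum):
    TONE = "tone"
    BAND_NOISE = "band_noise"
    FIVE_TONE = "five_tone"
    LOW_NOISE_NOISE = "low_noise_noise"
    SAM_TONE = "sam_tone"


@dataclass(frozen=True)
class StimulusSpec:
    """Parametric description of a test sound."""

    stim_type: StimType = StimType.TONE
    center_freq: float = 1000.0      # Hz
    bandwidth_oct: float = 0.0       # octaves; 0 for tone / SAM carrier
    level: float = 60.0              # dB SPL
    duration: float = 1.0            # s
    ramp: float = 0.2                # s
    sample_rate: float = 44100.0     # Hz
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "stim_type", StimType(self.stim_type))
        if self.bandwidth_oct < 0:
            raise InvalidSpecError("bandwidth_oct must be non-negative")
        if self.center_freq <= 0:
            raise InvalidSpecError("center_freq must be positive")
        if self.center_freq >= self.sample_rate / 2:
            raise InvalidSpecError("center_freq must be below the Nyquist frequency")
        if self.duration < 2 * self.ramp:
            raise InvalidSpecError("duration must be at least twice the ramp time")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    @property
    def band_edges(self) -> tuple[float, float]:
        """Geometric passband edges fc * 2**(+/- bw/2)."""
        half = 2.0 ** (self.bandwidth_oct / 2.0)
        return self.center_freq / half, self.center_freq * half

    @property
    def rms_pascal(self) -> float:
        return P_REF * 10.0 ** (self.level / 20.0)


@dataclass
class Waveform:
    """Sampled pressure waveform (pascals, 20 uPa reference)."""

    samples: np.ndarray
    sample_rate: float
    spec: StimulusSpec = field(repr=False, default=None)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def steady_slice(self) -> slice:
        """Index slice of the central segment untouched by the ramps."""
        n_ramp = int(round(self.spec.ramp * self.sample_rate)) if self.spec else 0
        return slice(n_ramp, len(self.samples) - n_ramp if n_ramp else None)

    def steady_rms(self) -> float:
        seg = self.samples[self.steady_slice()]
        return float(np.sqrt(np.mean(seg**2)))


def _time(spec: StimulusSpec) -> np.ndarray:
    return np.arange(spec.n_samples) / spec.sample_rate


def _steady_slice(spec: StimulusSpec) -> slice:
    n_ramp = int(round(spec.ramp * spec.sample_rate))
    return slice(n_ramp, spec.n_samples - n_ramp if n_ramp else None)


def _normalize_scale_ramp(x: np.ndarray, spec: StimulusSpec) -> Waveform:
    """Normalize steady-state RMS to 1, scale to level, apply ramps."""
    seg = x[_steady_slice(spec)]
    rms = np.sqrt(np.mean(seg**2))
    if rms == 0:
        raise InvalidSpecError("waveform has zero steady-state RMS")
    x = x * (spec.rms_pascal / rms)
    w = Waveform(samples=x, sample_rate=spec.sample_rate, spec=spec)
    return apply_ramps(w, spec.ramp)


def _band_bins(spec: StimulusSpec) -> tuple[np.ndarray, np.ndarray]:
    freqs = np.fft.rfftfreq(spec.n_samples, 1.0 / spec.sample_rate)
    f_lo, f_hi = spec.band_edges
    in_band = (freqs > f_lo) & (freqs < f_hi)
    return freqs, in_band


def make_band_noise(spec: StimulusSpec) -> Waveform:
    """Band-limited Gaussian noise from a Rayleigh-magnitude spectrum.

    In-band bins carry independent Rayleigh magnitudes and uniform [0, 2pi)
    phases; out-of-band bins are exactly zero before ramping.
    """
    if spec.stim_type != StimType.BAND_NOISE:
        raise InvalidSpecError("spec.stim_type must be 'band_noise'")
    if spec.bandwidth_oct <= 0:
        raise InvalidSpecError("band noise requires positive bandwidth")
    _, in_band = _band_bins(spec)
    n_bins = int(in_band.sum())
    if n_bins < 2:
        raise DegenerateBandError(
            f"passband contains {n_bins} spectrum bin(s); need at least 2"
        )
    rng = np.random.default_rng(spec.seed)
    mags = rng.rayleigh(scale=1.0, size=n_bins)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_bins)
    spectrum = np.zeros(in_band.size, dtype=complex)
    spectrum[in_band] = mags * np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n=spec.n_samples)
    return _normalize_scale_ramp(x, spec)


def make_pure_tone(spec: StimulusSpec) -> Waveform:
    if spec.stim_type != StimType.TONE:
        raise InvalidSpecError("spec.stim_type must be 'tone'")
    x = np.sin(2.0 * np.pi * spec.center_freq * _time(spec))
    return _normalize_scale_ramp(x, spec)


def five_tone_freqs(spec: StimulusSpec) -> np.ndarray:
    """Component frequencies fc * 2**(k*bw/4), k = -2..2 (log-spaced across
    the passband)."""
    k = np.arange(-2, 3)
    return spec.center_freq * 2.0 ** (k * spec.bandwidth_oct / 4.0)


def make_five_tone(spec: StimulusSpec, phases: str = "schroeder") -> Waveform:
    """Five equal-amplitude components log-spaced across the passband.

    ``phases`` selects the deterministic component-phase rule:
    'schroeder' (default; low-crest quadratic phases -pi*k^2/5), 'zero',
    or 'random' (seeded from spec.seed).  The low-crest default gives the
    five-tone complex the smallest envelope fluctuation of the four
    narrow-band stimulus types, which is what distinguishes it in the
    ensemble-averaging model.
    """
    if spec.stim_type != StimType.FIVE_TONE:
        raise InvalidSpecError("spec.stim_type must be 'five_tone'")
    freqs = five_tone_freqs(spec)
    n = len(freqs)
    if phases == "schroeder":
        phi = -np.pi * np.arange(n) ** 2 / n
    elif phases == "zero":
        phi = np.zeros(n)
    elif phases == "random":
        phi = np.random.default_rng(spec.seed).uniform(0, 2 * np.pi, n)
    else:
        raise InvalidSpecError(f"unknown phase rule {phases!r}")
    t = _time(spec)
    x = np.sum(np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phi[:, None]), axis=0)
    return _normalize_scale_ramp(x, spec)


def make_low_noise_noise(spec: StimulusSpec, n_iterations: int = 10,
                         flatness_target: float = 0.2) -> Waveform:
    """Low-noise noise: band noise with its envelope iteratively flattened.

    Each iteration divides the waveform by its Hilbert envelope, re-band-
    limits the result in the frequency domain, and renormalizes.  If the
    envelope fluctuation index (std/mean) has not reached
    ``flatness_target`` after ``n_iterations``, a warning is issued and the
    best iterate is returned.
    """
    if spec.stim_type != StimType.LOW_NOISE_NOISE:
        raise InvalidSpecError("spec.stim_type must be 'low_noise_noise'")
    base = replace(spec, stim_type=StimType.BAND_NOISE)
    _, in_band = _band_bins(base)
    if int(in_band.sum()) < 2:
        raise DegenerateBandError("passband contains fewer than 2 spectrum bins")
    rng = np.random.default_rng(spec.seed)
    mags = rng.rayleigh(scale=1.0, size=int(in_band.sum()))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=int(in_band.sum()))
    spectrum = np.zeros(in_band.size, dtype=complex)
    spectrum[in_band] = mags * np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n=spec.n_samples)
    x /= np.sqrt(np.mean(x**2))

    best_x, best_fi = x, _fluctuation_of(x)
    for _ in range(n_iterations):
        env = np.abs(hilbert(x))
        x = x / np.maximum(env, 1e-12)
        spec_x = np.fft.rfft(x)
        spec_x[~in_band] = 0.0
        x = np.fft.irfft(spec_x, n=spec.n_samples)
        x /= np.sqrt(np.mean(x**2))
        fi = _fluctuation_of(x)
        if fi < best_fi:
            best_x, best_fi = x, fi
    if best_fi > flatness_target:
        warnings.warn(
            f"low-noise-noise envelope flattening did not converge "
            f"(fluctuation index {best_fi:.3f} > {flatness_target}); "
            "returning best iterate",
            RuntimeWarning,
        )
    return _normalize_scale_ramp(best_x, spec)


def sam_default_rate(spec: StimulusSpec) -> float:
    """Default SAM rate: half the equivalent quarter-octave bandwidth (Hz)."""
    return 0.5 * spec.center_freq * (2.0 ** (1 / 8) - 2.0 ** (-1 / 8))


def make_sam_tone(spec: StimulusSpec, mod_rate: float | None = None,
                  depth: float = 1.0) -> Waveform:
    """Sinusoidally amplitude-modulated tone at the center frequency."""
    if spec.stim_type != StimType.SAM_TONE:
        raise InvalidSpecError("spec.stim_type must be 'sam_tone'")
    if mod_rate is None:
        mod_rate = sam_default_rate(spec)
    t = _time(spec)
    carrier = np.sin(2.0 * np.pi * spec.center_freq * t)
    env = 1.0 + depth * np.cos(2.0 * np.pi * mod_rate * t + np.pi)
    return _normalize_scale_ramp(carrier * env, spec)


_GENERATORS = {
    StimType.TONE: make_pure_tone,
    StimType.BAND_NOISE: make_band_noise,
    StimType.FIVE_TONE: make_five_tone,
    StimType.LOW_NOISE_NOISE: make_low_noise_noise,
    StimType.SAM_TONE: make_sam_tone,
}


def make_stimulus(spec: StimulusSpec, **kwargs) -> Waveform:
    """Dispatch to the generator for spec.stim_type."""
    return _GENERATORS[StimType(spec.stim_type)](spec, **kwargs)


def apply_ramps(w: Waveform, ramp: float) -> Waveform:
    """Apply raised-cosine (Hann half-window) onset/offset ramps in place
    conventions: gain 0 at sample 0, gain 1 at t = ramp."""
    n = len(w.samples)
    n_ramp = int(round(ramp * w.sample_rate))
    if 2 * n_ramp > n:
        raise InvalidSpecError("ramp longer than half the stimulus duration")
    x = w.samples.copy()
    if n_ramp > 0:
        t = np.arange(n_ramp) / w.sample_rate
        gain = np.sin(np.pi * t / (2.0 * ramp)) ** 2
        x[:n_ramp] *= gain
        x[n - n_ramp:] *= gain[::-1]
    return Waveform(samples=x, sample_rate=w.sample_rate, spec=w.spec)


def _fluctuation_of(x: np.ndarray) -> float:
    env = np.abs(hilbert(x))
    return float(np.std(env) / np.mean(env))


def envelope_fluctuation_index(w: Waveform) -> float:
    """std/mean of the Hilbert envelope over the central steady segment."""
    seg = w.samples[w.steady_slice()]
    return _fluctuation_of(seg)


def write_wav(path, w: Waveform) -> None:
    """Export as float-PCM WAV with a sidecar JSON of the StimulusSpec."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    from scipy.io import wavfile

    path = Path(path)
    wavfile.write(path, int(w.sample_rate), w.samples.astype(np.float32))
    if w.spec is not None:
        d = asdict(w.spec)
        d["stim_type"] = str(w.spec.stim_type.value)
        path.with_suffix(".json").write_text(json.dumps(d, indent=2))
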