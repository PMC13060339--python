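"""Stimulus-synthesis contracts: levels, spectra, ramps, envelope statistics."""

import numpy as np
import pytest

from neacls.errors import DegenerateBandError, InvalidSpecError
from neacls.stimuli import (
    StimulusSpec,
    Waveform,
    apply_ramps,
    envelope_fluctuation_index,
    five_tone_freqs,
    make_band_noise,
    make_five_tone,
    make_low_noise_noise,
    make_pure_tone,
    make_sam_tone,
    make_stimulus,
)

ALL_TYPES = ["tone", "band_noise", "five_tone", "low_noise_noise", "sam_tone"]


def spec_for(stim_type, **kw):
    bw = 0.0 if stim_type == "tone" else 0.25
    kw.setdefault("bandwidth_oct", bw)
    kw.setdefault("level", 60.0)
    kw.setdefault("seed", 7)
    return StimulusSpec(stim_type=stim_type, center_freq=1000.0, **kw)


@pytest.mark.parametrize("stim_type", ALL_TYPES)
def test_steady_rms_matches_level(stim_type):
    """Steady-state RMS equals the dB SPL level within 0.01 dB (the
    normalized pre-scaling waveform has RMS exactly 1)."""
    spec = spec_for(stim_type)
    w = make_stimulus(spec)
    err_db = 20 * np.log10(w.steady_rms() / spec.rms_pascal)
    assert abs(err_db) < 1e-6


@pytest.mark.parametrize("stim_type", ALL_TYPES)
def test_level_linearity(stim_type):
    """+20 dB multiplies the RMS by exactly 10."""
    lo = make_stimulus(spec_for(stim_type, level=50.0))
    hi = make_stimulus(spec_for(stim_type, level=70.0))
    assert np.isclose(hi.steady_rms() / lo.steady_rms(), 10.0, rtol=1e-9)


@pytest.mark.parametrize("stim_type", ALL_TYPES)
def test_seeded_determinism(stim_type):
    a = make_stimulus(spec_for(stim_type))
    b = make_stimulus(spec_for(stim_type))
    assert np.array_equal(a.samples, b.samples)
    assert np.all(np.isfinite(a.samples))


def test_duration_and_sample_count():
    w = make_pure_tone(StimulusSpec(stim_type="tone", center_freq=1000.0))
    assert len(w.samples) == 44100
    assert w.duration == pytest.approx(1.0)


def test_band_noise_passband_edges_and_zero_outside():
    """Quarter-octave band at 1 kHz spans ~[917, 1090.5] Hz; all spectrum
    bins outside the band are exactly zero before ramping."""
    spec = StimulusSpec(stim_type="band_noise", center_freq=1000.0,
                        bandwidth_oct=0.25, level=60.0, seed=3, ramp=0.0)
    lo, hi = spec.band_edges
    assert lo == pytest.approx(917.0, abs=0.1)
    assert hi == pytest.approx(1090.5, abs=0.1)
    w = make_band_noise(spec)
    spectrum = np.fft.rfft(w.samples)
    freqs = np.fft.rfftfreq(len(w.samples), 1 / spec.sample_rate)
    out_of_band = (freqs <= lo) | (freqs >= hi)
    total = np.sum(np.abs(spectrum) ** 2)
    assert np.sum(np.abs(spectrum[out_of_band]) ** 2) < 1e-20 * total


def test_band_noise_passband_power_fraction_with_ramps():
    """Even after ramping, in-band power stays >= 99% of the total."""
    for seed in range(5):
        spec = StimulusSpec(stim_type="band_noise", center_freq=1000.0,
                            bandwidth_oct=0.25, level=60.0, seed=seed)
        w = make_band_noise(spec)
        spectrum = np.abs(np.fft.rfft(w.samples)) ** 2
        freqs = np.fft.rfftfreq(len(w.samples), 1 / spec.sample_rate)
        lo, hi = spec.band_edges
        in_band = (freqs > lo * 0.99) & (freqs < hi * 1.01)
        assert spectrum[in_band].sum() / spectrum.sum() >= 0.99


def test_band_noise_mean_spectrum_flat():
    """Across many seeds the expected in-band bin power is flat (10%)."""
    spec0 = StimulusSpec(stim_type="band_noise", center_freq=1000.0,
                         bandwidth_oct=0.25, level=60.0, ramp=0.0)
    freqs = np.fft.rfftfreq(spec0.n_samples, 1 / spec0.sample_rate)
    lo, hi = spec0.band_edges
    in_band = (freqs > lo) & (freqs < hi)
    acc = np.zeros(int(in_band.sum()))
    n_seeds = 200
    for seed in range(n_seeds):
        w = make_band_noise(StimulusSpec(stim_type="band_noise",
                                         center_freq=1000.0, bandwidth_oct=0.25,
                                         level=60.0, ramp=0.0, seed=seed))
        acc += np.abs(np.fft.rfft(w.samples)[in_band]) ** 2
    acc /= n_seeds
    # average the 200-seed bin means over sub-bands to separate spectral
    # tilt (what flatness is about) from per-bin sampling noise
    n_sub = 8
    edges = np.linspace(0, len(acc), n_sub + 1).astype(int)
    sub_means = np.array([acc[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    rel = sub_means / acc.mean()
    assert rel.max() < 1.10 and rel.min() > 0.90


def test_degenerate_band_raises():
    with pytest.raises(DegenerateBandError):
        make_band_noise(StimulusSpec(stim_type="band_noise", center_freq=1000.0,
                                     bandwidth_oct=1e-4, level=60.0,
                                     duration=0.5, ramp=0.1))


def test_invalid_specs_raise():
    with pytest.raises(InvalidSpecError):
        StimulusSpec(stim_type="band_noise", bandwidth_oct=-0.25)
    with pytest.raises(InvalidSpecError):
        StimulusSpec(stim_type="tone", center_freq=30000.0)
    with pytest.raises(InvalidSpecError):
        StimulusSpec(stim_type="tone", duration=0.3, ramp=0.2)


def test_pure_tone_level_and_spectral_purity():
    """60 dB SPL -> RMS 0.02 Pa; unramped spectrum peaks only at 1 kHz."""
    spec = StimulusSpec(stim_type="tone", center_freq=1000.0, level=60.0,
                        ramp=0.0)
    w = make_pure_tone(spec)
    assert w.steady_rms() == pytest.approx(0.02, rel=1e-9)
    spectrum = np.abs(np.fft.rfft(w.samples))
    freqs = np.fft.rfftfreq(len(w.samples), 1 / spec.sample_rate)
    peak = freqs[np.argmax(spectrum)]
    assert peak == pytest.approx(1000.0, abs=1.0)
    others = spectrum[np.abs(freqs - 1000.0) > 5.0]
    assert others.max() < 1e-6 * spectrum.max()


def test_five_tone_component_frequencies():
    spec = spec_for("five_tone")
    f = five_tone_freqs(spec)
    expected = 1000.0 * 2.0 ** (np.arange(-2, 3) / 16)
    assert np.allclose(f, expected)
    assert np.allclose(expected.round(1), [917.0, 957.6, 1000.0, 1044.3, 1090.5])


def test_five_tone_fluctuates_less_than_band_noise():
    """Envelope fluctuation index (std/mean of the Hilbert envelope) of the
    five-tone complex is below that of band noise, across noise seeds."""
    ft = envelope_fluctuation_index(make_five_tone(spec_for("five_tone")))
    noise_fi = [
        envelope_fluctuation_index(
            make_band_noise(spec_for("band_noise", seed=s)))
        for s in range(20)
    ]
    assert ft < min(noise_fi)


def test_envelope_fluctuation_ordering():
    """SAM (full depth) > band noise > low-noise noise."""
    sam = envelope_fluctuation_index(make_sam_tone(spec_for("sam_tone")))
    bn = np.median([
        envelope_fluctuation_index(make_band_noise(spec_for("band_noise", seed=s)))
        for s in range(10)
    ])
    lnn = envelope_fluctuation_index(make_low_noise_noise(spec_for("low_noise_noise")))
    assert sam > bn > lnn


def test_low_noise_noise_is_flat_after_iterations():
    w = make_low_noise_noise(spec_for("low_noise_noise"), n_iterations=10)
    assert envelope_fluctuation_index(w) < 0.2


def test_sam_envelope_minimum_near_zero():
    from scipy.signal import hilbert

    w = make_sam_tone(spec_for("sam_tone"))
    env = np.abs(hilbert(w.samples[w.steady_slice()]))
    assert env.min() < 0.02 * env.max()


def test_ramps_raised_cosine():
    """Gain 0 at sample 0, 1 at t=ramp, 0.5 at the ramp midpoint; ramping
    removes energy."""
    spec = StimulusSpec(stim_type="tone", center_freq=1000.0, ramp=0.2)
    fs = spec.sample_rate
    const = Waveform(samples=np.ones(spec.n_samples), sample_rate=fs, spec=spec)
    ramped = apply_ramps(const, spec.ramp)
    n_ramp = int(round(spec.ramp * fs))
    assert ramped.samples[0] == 0.0
    assert ramped.samples[n_ramp] == pytest.approx(1.0)
    assert ramped.samples[n_ramp // 2] == pytest.approx(0.5, abs=1e-3)
    assert np.sum(ramped.samples**2) < np.sum(const.samples**2)
    with pytest.raises(InvalidSpecError):
        apply_ramps(const, 0.6)


def test_wav_roundtrip(tmp_path):
    from scipy.io import wavfile

    from neacls.stimuli import write_wav

    w = make_pure_tone(spec_for("tone"))
    path = tmp_path / "tone.wav"
    write_wav(path, w)
    fs, data = wavfile.read(path)
    assert fs == 44100
    assert np.allclose(data, w.samples.astype(np.float32))
    assert (tmp_path / "tone.json").exists()
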