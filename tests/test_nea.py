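"""Ensemble-averaging loudness model: periphery, synapse, spiking,
ensemble averaging, and equal-loudness matching."""

import numpy as np
import pytest

from neacls.errors import InvalidConfigError, InvalidWindowError
from neacls.nea import (
    AdaptationParams,
    EnsembleConfig,
    NeaModel,
    PeripheryParams,
    adapt,
    bin_drive,
    ensemble_partition,
    equal_loudness_level,
    greenwood_cf,
    greenwood_place,
    nea_loudness,
    periphery_drive,
    spike_rates,
)
from neacls.stimuli import StimulusSpec, Waveform, make_stimulus


@pytest.fixture(scope="module")
def small_model():
    return NeaModel(periphery=PeripheryParams(n_channels=20),
                    ensemble=EnsembleConfig(n_fibers=20))


def tone_wave(level, freq=1000.0):
    return make_stimulus(StimulusSpec(stim_type="tone", center_freq=freq,
                                      level=level))


def test_greenwood_map_monotone_and_invertible():
    x = np.linspace(5.0, 31.5, 50)
    cf = greenwood_cf(x)
    assert np.all(np.diff(cf) > 0)
    assert np.allclose(greenwood_place(cf), x, atol=1e-9)


def test_ensemble_partition_tiles_without_overlap():
    per = PeripheryParams(n_channels=70)
    tiles = ensemble_partition(per, 2.0)
    flat = np.concatenate(tiles)
    assert len(np.unique(flat)) == len(flat)
    # each tile spans about 2 mm of the place axis
    span = (tiles[0][-1] - tiles[0][0] + 1) * per.channel_spacing_mm
    assert span == pytest.approx(2.0, abs=per.channel_spacing_mm)


def test_silence_gives_zero_drive(small_model):
    spec = StimulusSpec(stim_type="tone", center_freq=1000.0, level=60.0)
    w = Waveform(samples=np.zeros(spec.n_samples), sample_rate=44100.0,
                 spec=spec)
    d = periphery_drive(w, small_model.periphery)
    assert np.allclose(d, 0.0)


def test_bandpass_selectivity(small_model):
    d = bin_drive(periphery_drive(tone_wave(60.0), small_model.periphery),
                  44100.0, 1e-3)
    cfs = small_model.periphery.cfs
    on = int(np.argmin(np.abs(cfs - 1000.0)))
    off = int(np.argmin(np.abs(cfs - 4000.0)))
    steady = d[:, 300:700].mean(axis=1)
    assert steady[off] < 0.05 * steady[on]


def test_peripheral_compression(small_model):
    """A 40-dB level increase raises the on-CF drive far less than the
    100x a linear system would give."""
    per = small_model.periphery
    on = int(np.argmin(np.abs(per.cfs - 1000.0)))
    d40 = bin_drive(periphery_drive(tone_wave(40.0), per), 44100.0, 1e-3)
    d80 = bin_drive(periphery_drive(tone_wave(80.0), per), 44100.0, 1e-3)
    ratio = d80[on, 300:700].mean() / d40[on, 300:700].mean()
    assert 1.0 < ratio < 100.0


def test_sample_rate_mismatch_rejected(small_model):
    w = tone_wave(60.0)
    bad = Waveform(samples=w.samples, sample_rate=48000.0, spec=w.spec)
    with pytest.raises(InvalidConfigError):
        periphery_drive(bad, small_model.periphery)


def test_adaptation_onset_decay_and_equilibrium():
    """Constant drive: the rate decays from an onset peak toward the
    closed-form three-store equilibrium."""
    ad = AdaptationParams()
    drive = np.full(3000, 2e-3)
    r = adapt(drive, ad, dt=1e-3)
    peak = r[:50].max()
    steady = r[-200:].mean()
    expected = float(ad.steady_rate(2e-3))
    assert peak > steady
    assert steady == pytest.approx(expected, rel=0.01)
    # monotone decay after the onset peak (coarse-grained)
    seg = r[int(np.argmax(r)):]
    coarse = seg[: len(seg) // 100 * 100].reshape(-1, 100).mean(axis=1)
    assert np.all(np.diff(coarse) <= 1e-6)


def test_forward_masking_signature():
    """After masker offset the rate dips below the spontaneous rate, and a
    probe right after a masker evokes a weaker onset than an unmasked
    probe."""
    ad = AdaptationParams()
    spont = ad.spont_rate
    masker_probe = np.concatenate([
        np.full(300, 2e-3), np.zeros(20), np.full(100, 5e-4)])
    probe_alone = np.concatenate([np.zeros(320), np.full(100, 5e-4)])
    r_mp = adapt(masker_probe, ad, dt=1e-3)
    r_pa = adapt(probe_alone, ad, dt=1e-3)
    assert r_mp[305:315].min() < spont
    assert r_mp[320:340].max() < r_pa[320:340].max()


def test_adaptation_rejects_bad_params():
    with pytest.raises(InvalidConfigError):
        AdaptationParams(p_local=-1.0)
    with pytest.raises(ValueError):
        adapt(np.array([-1.0, 0.0]), AdaptationParams())


def test_spike_rates_poisson_statistics():
    rng = np.random.default_rng(0)
    rate = np.full((1, 500), 180.0)
    R = spike_rates(rate, 1000, rng, dt=1e-3)
    counts = R * 1e-3
    assert counts.mean() == pytest.approx(0.18, rel=0.02)
    fano = counts.var() / counts.mean()
    assert fano == pytest.approx(1.0, abs=0.1)
    assert np.all(spike_rates(np.zeros((1, 100)), 1, 0) == 0.0)


def test_nea_loudness_degenerate_and_identity():
    cfg = EnsembleConfig(n_fibers=4, compress_exponent=0.5,
                         expand_exponent=2.0, expand_scale=1.5)
    R = np.full((4, 6, 50), 120.0)
    est = nea_loudness(R, cfg)
    expected = 6 * 1.5 * (120.0**0.5) ** 2.0
    assert est.L == pytest.approx(expected, rel=1e-12)
    # identity compress/expand: L = N2 x grand-mean rate (brute force)
    cfg_id = EnsembleConfig(n_fibers=4, compress_exponent=1.0,
                            expand_exponent=1.0, expand_scale=1.0)
    rng = np.random.default_rng(1)
    R = rng.poisson(3.0, size=(4, 6, 50)).astype(float)
    est = nea_loudness(R, cfg_id)
    assert est.L == pytest.approx(6 * R.mean(axis=(0, 2)).mean()
                                  * 1.0, rel=1e-12)
    with pytest.raises(InvalidWindowError):
        nea_loudness(R, cfg_id, window=slice(60, 60))


def test_jensen_fluctuation_penalty():
    """Equal-time-mean rate streams: the fluctuating one is never louder
    under a strictly concave compressive stage (paired seeds)."""
    cfg = EnsembleConfig(n_fibers=1, compress_exponent=0.4,
                         expand_exponent=2.5)
    t = np.arange(600)
    const = np.full((1, 1, 600), 150.0)
    for phase in (0.0, 1.0, 2.0):
        fluct = 150.0 * (1.0 + np.sin(0.3 * t + phase))[None, None, :]
        assert nea_loudness(fluct, cfg).L <= nea_loudness(const, cfg).L


def test_variance_scales_inversely_with_fibers():
    """log-variance of loudness vs log-N1 has slope -1 (+-0.15)."""
    rng = np.random.default_rng(2)
    cfg_base = dict(compress_exponent=0.5, expand_exponent=2.0)
    n1s = [4, 16, 64]
    variances = []
    for n1 in n1s:
        cfg = EnsembleConfig(n_fibers=n1, **cfg_base)
        ls = []
        for _ in range(150):
            lam = np.full((n1, 5, 300), 180.0) * 1e-3
            R = rng.poisson(lam) / 1e-3
            ls.append(nea_loudness(R, cfg).L)
        variances.append(np.var(ls))
    slope = np.polyfit(np.log(n1s), np.log(variances), 1)[0]
    assert slope == pytest.approx(-1.0, abs=0.15)


def test_loudness_monotone_in_level(small_model):
    l50 = small_model.loudness(tone_wave(50.0), n_reps=6, seed=0,
                               cache_key=("t", 50)).L
    l70 = small_model.loudness(tone_wave(70.0), n_reps=6, seed=1,
                               cache_key=("t", 70)).L
    assert l70 > l50


def test_mbld_curve_stimulus_type_ordering(calibrated_nea):
    """Stimulus types with stronger envelope fluctuation show at least as
    much narrow-band loudness reduction: the five-tone complex (lowest
    fluctuation) is reduced less than band noise and the fully modulated
    SAM tone.  Replicate SEs are reported alongside."""
    from neacls.nea import mbld_curve

    model, _ = calibrated_nea
    df = mbld_curve(model, stim_types=["five_tone", "band_noise", "sam_tone"],
                    bandwidths=(0.25,), seed=31, n_reps=6)
    red = dict(zip(df.stim_type, df.reduction_db))
    fi = dict(zip(df.stim_type, df.fluctuation_index))
    assert fi["sam_tone"] > fi["band_noise"] > fi["five_tone"]
    assert red["five_tone"] < red["band_noise"]
    assert red["five_tone"] < red["sam_tone"] + 1.0
    assert (df.se_db > 0).all()


def test_equal_loudness_of_reference_tone_is_zero(small_model):
    """Matching the reference tone against itself gives ~0 dB."""
    spec = StimulusSpec(stim_type="tone", center_freq=1000.0, level=60.0)
    res = equal_loudness_level(small_model, spec, n_reps=8, seed=4)
    assert abs(res["difference_db"]) < 1.0
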