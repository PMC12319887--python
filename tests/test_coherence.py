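import numpy as np
import pytest

from dyadcoh import (
    make_protocol,
    wtc,
)
from dyadcoh.coherence import (
    FOURIER_FACTOR,
    band_condition_average,
    band_scale_mask,
    cwt_morlet,
    enumerate_pairs,
    morlet_scales,
    roi_average_signals,
    roi_validity,
    CoherenceMap,
)
from dyadcoh.errors import AlignmentError, InvalidConfigError
from dyadcoh.channels import default_montage
from dyadcoh.recording import HemoTimeSeries

FS = 2.5


def test_cwt_localises_pure_tone(rng):
    t = np.arange(1500) / FS
    f0 = 0.05
    x = np.sin(2 * np.pi * f0 * t)
    scales = morlet_scales(FS, x.size)
    W = cwt_morlet(x, FS, scales)
    power = (np.abs(W) ** 2).mean(axis=1)
    freqs = 1.0 / (FOURIER_FACTOR * scales)
    assert freqs[np.argmax(power)] == pytest.approx(f0, rel=0.08)
    # zero track -> zero coefficients
    assert np.abs(cwt_morlet(np.zeros_like(x), FS, scales)).max() == 0.0


def test_cwt_energy_reconstructs_variance(rng):
    """Scale-integrated wavelet power approximates broadband-noise variance
    (Parseval-style, within 5%) when the scale grid covers the noise support."""
    from scipy import signal as sig

    x = rng.standard_normal(4096)
    sos = sig.butter(4, (0.02, 0.5), btype="bandpass", fs=FS, output="sos")
    x = sig.sosfiltfilt(sos, x)
    dt = 1.0 / FS
    dj = 1.0 / 12.0
    scales = morlet_scales(FS, x.size, dj=dj, min_period=1.0, max_period=400.0)
    W = cwt_morlet(x, FS, scales)
    # Morlet(6) reconstruction constant: Cdelta = 0.776
    var_est = dj * dt / (0.776 * x.size) * np.sum(np.abs(W) ** 2 / scales[:, None])
    assert var_est == pytest.approx(x.var(), rel=0.05)


def test_self_coherence_is_one(rng):
    for _ in range(3):
        x = rng.standard_normal(800)
        m = wtc(x, x, FS)
        assert np.abs(m.values - 1.0).max() <= 1e-9


def test_symmetry_and_amplitude_invariance(rng):
    x = rng.standard_normal(700)
    y = rng.standard_normal(700)
    mxy = wtc(x, y, FS)
    myx = wtc(y, x, FS)
    np.testing.assert_allclose(mxy.values, myx.values, atol=1e-10)
    scaled = wtc(5.0 * x, 0.3 * y, FS)
    np.testing.assert_allclose(mxy.values, scaled.values, atol=1e-9)


def test_constant_phase_shift_invariance():
    """sin/cos at 0.05 Hz: band coherence outside the COI stays ~1 despite
    the 90-degree phase offset."""
    t = np.arange(int(1880 * FS)) / FS
    x = np.sin(2 * np.pi * 0.05 * t)
    y = np.cos(2 * np.pi * 0.05 * t)
    m = wtc(x, y, FS)
    sel = (m.freqs >= 0.04) & (m.freqs <= 0.06)
    outside = m.freqs[sel][:, None] >= m.coi[None, :]
    assert m.values[sel][outside].mean() >= 0.95


def test_length_mismatch_rejected(rng):
    with pytest.raises(AlignmentError):
        wtc(rng.standard_normal(100), rng.standard_normal(99), FS)


def test_band_condition_average_trivial_maps():
    tl = make_protocol(1, 40.0, 20.0, seed=0)
    n = int(tl.duration * FS)
    scales = morlet_scales(FS, n, min_period=8.0, max_period=64.0)
    freqs = 1.0 / (FOURIER_FACTOR * scales)
    coi = np.full(n, 0.0)  # everything trustworthy
    const = CoherenceMap(np.full((scales.size, n), 0.6), scales, freqs, coi, FS)
    tab = band_condition_average(const, (0.02, 0.10), tl)
    assert np.allclose(tab["mean_wtc"], 0.6)
    assert set(tab["condition"]) == set(tl.conditions())

    # map = 1 inside one condition's epochs, 0 elsewhere
    vals = np.zeros((scales.size, n))
    target = tl.task_epochs[0]
    vals[:, int(target.onset * FS) + 1 : int(target.end * FS) - 1] = 1.0
    m = CoherenceMap(vals, scales, freqs, coi, FS)
    tab = band_condition_average(m, (0.02, 0.10), tl)
    by_cond = tab.set_index("condition")["mean_wtc"]
    assert by_cond[target.condition] == pytest.approx(1.0, abs=0.05)
    others = [c for c in tl.conditions() if c != target.condition]
    assert all(by_cond[c] == pytest.approx(0.0, abs=1e-12) for c in others)


def test_coi_exclusion_reduces_samples():
    tl = make_protocol(1, 40.0, 20.0, seed=1)
    n = int(tl.duration * FS)
    scales = morlet_scales(FS, n, min_period=8.0, max_period=64.0)
    freqs = 1.0 / (FOURIER_FACTOR * scales)
    from dyadcoh.coherence import coi_min_frequency

    cmap = CoherenceMap(np.full((scales.size, n), 0.5), scales, freqs,
                        coi_min_frequency(n, FS), FS)
    inc = band_condition_average(cmap, (0.02, 0.10), tl, "include")
    exc = band_condition_average(cmap, (0.02, 0.10), tl, "exclude")
    assert (exc["n_samples_used"] <= inc["n_samples_used"]).all()
    with pytest.raises(InvalidConfigError):
        band_condition_average(cmap, (0.02, 0.10), tl, "sometimes")


def _hemo(role, n_lsc=16, n_ssc=2, n=100):
    channels = default_montage(role, n_lsc, n_ssc)
    z = np.zeros((n, len(channels)))
    return HemoTimeSeries(fs=FS, hbo=z, hbr=z.copy(), channels=channels)


def test_pair_enumeration_counts_and_ssc_exclusion():
    child = _hemo("child")
    mother = _hemo("mother")
    pairs = enumerate_pairs(child, mother, "channel")
    assert len(pairs) == 256  # 16 x 16 valid long channels
    ssc_ids = {c.id for c in child.channels + mother.channels if c.kind == "short"}
    assert all(cu not in ssc_ids and mu not in ssc_ids for cu, mu in pairs)
    # two invalid child channels -> 14 x 16
    child.channels[0] = child.channels[0].invalidated()
    child.channels[1] = child.channels[1].invalidated()
    assert len(enumerate_pairs(child, mother, "channel")) == 224
    # no valid units on one side -> empty list
    for i, c in enumerate(mother.channels):
        mother.channels[i] = c.invalidated()
    assert enumerate_pairs(child, mother, "channel") == []


def test_roi_validity_and_averaging(rng):
    hemo = _hemo("child", n_lsc=8, n_ssc=0, n=50)  # 2 channels per ROI
    hemo.hbo[:] = rng.standard_normal(hemo.hbo.shape)
    v = roi_validity(hemo.channels)
    assert all(v.values())
    rois = roi_average_signals(hemo)
    assert [c.id for c in rois.channels] == ["lPFC", "rPFC", "lTPJ", "rTPJ"]
    members = [i for i, c in enumerate(hemo.channels) if c.roi == "lPFC"]
    np.testing.assert_allclose(rois.hbo[:, 0], hemo.hbo[:, members].mean(axis=1))
    # invalidate one lPFC channel -> only 1 valid -> ROI excluded entirely
    hemo.channels[members[0]] = hemo.channels[members[0]].invalidated()
    rois2 = roi_average_signals(hemo)
    assert "lPFC" not in [c.id for c in rois2.channels]


def test_band_scale_mask_endpoints_inclusive():
    freqs = np.array([0.15, 0.10, 0.05, 0.02, 0.01])
    mask = band_scale_mask(freqs, (0.02, 0.10))
    assert mask.tolist() == [False, True, True, True, False]
    with pytest.raises(InvalidConfigError):
        band_scale_mask(np.array([0.5, 0.4]), (0.02, 0.10))
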