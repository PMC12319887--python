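import numpy as np
import pytest
from scipy import signal

from dyadcoh import InvalidConfigError, bandpass, bandpass_gain, wavelet_motion_correct
from dyadcoh.errors import InsufficientDataError
from dyadcoh.preprocess import downsample, preprocess_recording, wavelet_outlier_mask

FS = 25.0


def _band_power(x, fs=FS, band=(0.02, 0.10)):
    f, p = signal.welch(x, fs=fs, nperseg=min(len(x), 4096))
    m = (f >= band[0]) & (f <= band[1])
    return np.trapezoid(p[m], f[m])


# ---------------------------------------------------------------------------
# wavelet motion correction
# ---------------------------------------------------------------------------

def test_smooth_sinusoid_passes_through():
    t = np.arange(int(600 * FS)) / FS
    x = np.sin(2 * np.pi * 0.05 * t)
    for alpha in (1.5, 0.8):
        y = wavelet_motion_correct(x, alpha, FS)
        assert y.shape == x.shape
        np.testing.assert_allclose(y, x, atol=1e-6)


@pytest.mark.parametrize("alpha", [1.5, 0.8])
def test_spikes_suppressed_band_preserved(alpha):
    """10x-SD spikes attenuated by >= 80% while the clean signal's in-band
    power moves by < 10%."""
    t = np.arange(int(600 * FS)) / FS
    clean = np.sin(2 * np.pi * 0.05 * t)
    spiky = clean.copy()
    for st in (100.0, 300.0, 500.0):
        spiky += 10 * clean.std() * np.exp(-0.5 * ((t - st) / 0.3) ** 2)
    corrected = wavelet_motion_correct(spiky, alpha, FS)
    residual_before = np.abs(spiky - clean).max()
    residual_after = np.abs(corrected - clean).max()
    assert residual_after <= 0.2 * residual_before
    assert abs(_band_power(corrected) / _band_power(clean) - 1) < 0.10


def test_iqr_thresholds_nested(rng):
    """The child multiplier (0.8) flags a superset of the mother's (1.5)."""
    coeffs = rng.standard_normal(2000)
    m_child = wavelet_outlier_mask(coeffs, 0.8)
    m_mother = wavelet_outlier_mask(coeffs, 1.5)
    assert np.all(m_child[m_mother])  # mother outliers ⊆ child outliers
    assert m_child.sum() >= m_mother.sum()


def test_too_short_track_rejected():
    with pytest.raises(InsufficientDataError):
        wavelet_motion_correct(np.zeros(4), 1.5, FS)


# ---------------------------------------------------------------------------
# band-pass
# ---------------------------------------------------------------------------

def test_bandpass_gain_contract():
    """Pass-band gain at 0.05 Hz within [0.95, 1]; >= 20 dB down at 1.5 Hz;
    DC removed."""
    g = bandpass_gain(FS, np.array([0.05, 1.5]))
    assert 0.95 <= g[0] <= 1.0
    assert 10 * np.log10(g[0] / g[1]) >= 20.0
    t = np.arange(int(400 * FS)) / FS
    filtered = bandpass(np.ones_like(t) * 5.0, FS)
    assert np.abs(filtered[int(50 * FS):-int(50 * FS)]).max() < 1e-6


def test_bandpass_is_linear_and_length_preserving(rng):
    x = rng.standard_normal(3000)
    y = rng.standard_normal(3000)
    lhs = bandpass(2.0 * x + 3.0 * y, FS)
    rhs = 2.0 * bandpass(x, FS) + 3.0 * bandpass(y, FS)
    np.testing.assert_allclose(lhs, rhs, atol=1e-10)
    assert lhs.shape == x.shape


def test_bandpass_band_outside_nyquist_rejected():
    with pytest.raises(InvalidConfigError):
        bandpass(np.zeros(100), FS, low=0.01, high=13.0)


# ---------------------------------------------------------------------------
# whole chain
# ---------------------------------------------------------------------------

def test_chain_preserves_shape_and_sets_provenance(small_dyad):
    child, _, _ = small_dyad
    hemo = preprocess_recording(child)
    assert hemo.n_times == child.n_times
    assert hemo.fs == child.fs
    for flag in ("od_converted", "motion_corrected", "filtered", "conc_converted"):
        assert hemo.provenance[flag]
    assert not hemo.provenance["ssr_applied"]


def test_downsample_preserves_band_content(small_dyad):
    child, _, _ = small_dyad
    hemo = preprocess_recording(child)
    dec = downsample(hemo, 2.5)
    assert dec.fs == pytest.approx(2.5)
    assert dec.n_times == hemo.n_times // 10
    # in-band power per channel agrees before/after decimation
    p_full = _band_power(hemo.hbo[:, 0], fs=hemo.fs)
    p_dec = _band_power(dec.hbo[:, 0], fs=dec.fs)
    assert p_dec == pytest.approx(p_full, rel=0.15)
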