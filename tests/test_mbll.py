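import numpy as np
import pytest

from dyadcoh import DEFAULT_EXTINCTION, DpfTable, HemoTimeSeries, forward_mbll
from dyadcoh.channels import default_montage
from dyadcoh.errors import CorruptDataError, NumericalConfigError
from dyadcoh.mbll import conc_to_od, od_to_conc_tracks
from dyadcoh.preprocess import intensity_to_od, od_to_conc


def _hemo(n=500, role="child", amp=1e-7, fs=25.0, n_lsc=16, n_ssc=2, seed=0):
    rng = np.random.default_rng(seed)
    channels = default_montage(role, n_lsc, n_ssc)
    hbo = amp * rng.standard_normal((n, len(channels)))
    hbr = amp * rng.standard_normal((n, len(channels)))
    hbo -= hbo.mean(axis=0)
    hbr -= hbr.mean(axis=0)
    return HemoTimeSeries(fs=fs, hbo=hbo, hbr=hbr, channels=channels)


def test_zero_concentration_gives_constant_intensity():
    hemo = _hemo()
    hemo.hbo[:] = 0.0
    hemo.hbr[:] = 0.0
    rec = forward_mbll(hemo, "child")
    assert np.ptp(rec.intensity) == 0.0


@pytest.mark.parametrize("role", ["child", "mother"])
def test_roundtrip_recovers_concentrations(role):
    """conc -> intensity -> OD -> conc is the identity to 1e-6 relative error
    (mean-referenced) on a full 18-channel cap."""
    hemo = _hemo(role=role)
    rec = forward_mbll(hemo, role)
    od = intensity_to_od(rec)
    back = od_to_conc(od, rec.channels, role, rec.fs)
    # The intensity-mean reference shifts each channel by a constant, so the
    # identity holds on mean-centred tracks.
    scale = np.abs(hemo.hbo).max()
    np.testing.assert_allclose(
        back.hbo - back.hbo.mean(0), hemo.hbo, atol=1e-6 * scale
    )
    np.testing.assert_allclose(
        back.hbr - back.hbr.mean(0), hemo.hbr, atol=1e-6 * scale
    )


def test_od_scaling_invariance():
    hemo = _hemo(n_lsc=2, n_ssc=0)
    rec = forward_mbll(hemo, "child")
    od1 = intensity_to_od(rec)
    rec.intensity *= 3.7  # rescaling the detector gain
    od2 = intensity_to_od(rec)
    np.testing.assert_allclose(od1, od2, atol=1e-12)


def test_od_worked_example():
    """I = [2,2,8,8] has mean 5, so dOD = -ln(I/5)."""
    od = -np.log(np.array([2.0, 2.0, 8.0, 8.0]) / 5.0)
    np.testing.assert_allclose(od, [0.9163, 0.9163, -0.4700, -0.4700], atol=5e-5)
    channels = default_montage("child", 1, 0)
    rec_like = np.array([2.0, 2.0, 8.0, 8.0])[:, None, None].repeat(2, axis=2)
    from dyadcoh import OpticalRecording

    rec = OpticalRecording(
        role="child", fs=1.0, wavelengths=(760.0, 850.0),
        intensity=rec_like, channels=channels,
    )
    got = intensity_to_od(rec)
    np.testing.assert_allclose(got[:, 0, 0], od, atol=1e-12)


def test_single_chromophore_pulse_wavelength_ratio():
    """A pure HbO2 pulse maps to the two wavelengths in the ratio of the HbO2
    extinction coefficients (per unit pathlength)."""
    hemo = _hemo(n=100, n_lsc=1, n_ssc=0)
    hemo.hbo[:] = 0.0
    hemo.hbr[:] = 0.0
    hemo.hbo[50, 0] = 1e-6
    dpf = DpfTable({"child": (1.0, 1.0)})  # equal pathlengths isolate epsilon
    od = conc_to_od(hemo, "child", dpf=dpf)
    ratio = od[50, 0, 0] / od[50, 0, 1]
    assert ratio == pytest.approx(DEFAULT_EXTINCTION[0, 0] / DEFAULT_EXTINCTION[1, 0])


def test_diagonal_extinction_decouples_chromophores():
    """With a diagonal test extinction table each wavelength maps to exactly
    one chromophore scaled by 1/(eps * d * DPF)."""
    ext = np.diag([500.0, 800.0])
    channels = default_montage("mother", 1, 0)
    d_cm = channels[0].separation / 10.0
    dpf = DpfTable({"mother": (6.0, 6.0)})
    od = np.zeros((10, 1, 2))
    od[:, 0, 0] = 0.01  # wavelength 1 only
    hbo, hbr = od_to_conc_tracks(od, channels, "mother", dpf, ext)
    np.testing.assert_allclose(hbo[:, 0], 0.01 / (500.0 * d_cm * 6.0))
    np.testing.assert_allclose(hbr[:, 0], 0.0, atol=1e-18)


def test_singular_extinction_rejected():
    hemo = _hemo(n_lsc=1, n_ssc=0)
    with pytest.raises(NumericalConfigError):
        forward_mbll(hemo, "child", extinction=np.ones((2, 2)))


def test_nonpositive_intensity_rejected():
    from dyadcoh import OpticalRecording

    with pytest.raises(CorruptDataError):
        OpticalRecording(
            role="child", fs=1.0, wavelengths=(760.0, 850.0),
            intensity=np.zeros((4, 1, 2)), channels=default_montage("child", 1, 0),
        )
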