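import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dyadcoh import make_protocol, phase_scramble, pseudodyad_ensemble
from dyadcoh.channels import default_montage
from dyadcoh.recording import HemoTimeSeries
from dyadcoh.surrogate import ensemble_table, iteration_seeds


def test_amplitude_spectrum_preserved_exactly(rng):
    for _ in range(20):
        x = rng.standard_normal(rng.integers(64, 400))
        y = phase_scramble(x, int(rng.integers(0, 2**31)))
        np.testing.assert_allclose(
            np.abs(np.fft.rfft(y)), np.abs(np.fft.rfft(x)), atol=1e-8
        )
        assert abs(y.mean() - x.mean()) <= 1e-10


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    n=st.integers(min_value=16, max_value=257),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_scramble_spectrum_property(n, seed):
    """For any track length (odd or even) and seed, the surrogate keeps the
    amplitude spectrum and the mean."""
    x = np.random.default_rng(seed ^ 0xABCD).standard_normal(n)
    y = phase_scramble(x, seed)
    np.testing.assert_allclose(np.abs(np.fft.rfft(y)), np.abs(np.fft.rfft(x)), atol=1e-8)
    assert abs(y.mean() - x.mean()) <= 1e-10
    assert y.shape == x.shape


def test_seeded_scramble_determinism(rng):
    x = rng.standard_normal(256)
    a = phase_scramble(x, 123)
    b = phase_scramble(x, 123)
    c = phase_scramble(x, 124)
    np.testing.assert_array_equal(a, b)
    assert not np.allclose(a, c)


def _dyad_hemos(n=1700, n_lsc=2, seed=0):
    # 1700 samples at 2.5 Hz = 680 s, matching a 1-trial protocol timeline.
    rng = np.random.default_rng(seed)
    out = []
    for role in ("child", "mother"):
        channels = default_montage(role, n_lsc, 0)
        hbo = rng.standard_normal((n, n_lsc))
        out.append(
            HemoTimeSeries(fs=2.5, hbo=hbo, hbr=hbo.copy(), channels=channels)
        )
    return out


def test_ensemble_child_untouched_and_reproducible():
    child, mother = _dyad_hemos()
    child_before = child.hbo.copy()
    tl = make_protocol(1, 120.0, 80.0, seed=4)
    pairs = [(child.channels[0].id, mother.channels[0].id)]
    kwargs = dict(n_iter=3, master_seed=5, min_period=8.0, max_period=64.0)
    ens1 = pseudodyad_ensemble(child, mother, pairs, tl, **kwargs)
    ens2 = pseudodyad_ensemble(child, mother, pairs, tl, **kwargs)
    np.testing.assert_array_equal(child.hbo, child_before)
    for e1, e2 in zip(ens1, ens2):
        np.testing.assert_array_equal(e1.values, e2.values)
        assert e1.iteration_seeds == iteration_seeds(5, 3)
        assert e1.mean == pytest.approx(np.mean(e1.values))
        assert len(e1.values) == 3


def test_single_iteration_matches_direct_computation():
    from dyadcoh import wtc
    from dyadcoh.coherence import band_condition_average

    child, mother = _dyad_hemos(seed=2)
    tl = make_protocol(1, 120.0, 80.0, seed=1)
    pairs = [(child.channels[0].id, mother.channels[0].id)]
    ens = pseudodyad_ensemble(
        child, mother, pairs, tl, n_iter=1, master_seed=9,
        min_period=8.0, max_period=64.0,
    )
    seed0 = iteration_seeds(9, 1)[0]
    y_s = phase_scramble(mother.hbo[:, 0], seed0)
    m = wtc(child.hbo[:, 0], y_s, 2.5, min_period=8.0, max_period=64.0)
    tab = band_condition_average(m, (0.02, 0.10), tl)
    expected = tab.groupby("condition")["mean_wtc"].mean()
    for e in ens:
        assert e.values[0] == pytest.approx(expected[e.condition], abs=1e-12)


def test_empty_pairs_signalled():
    child, mother = _dyad_hemos()
    tl = make_protocol(1, 120.0, 80.0, seed=0)
    assert pseudodyad_ensemble(child, mother, [], tl, n_iter=2, master_seed=0) == []


def test_ensemble_table_layout():
    child, mother = _dyad_hemos(seed=5)
    tl = make_protocol(1, 120.0, 80.0, seed=2)
    pairs = [
        (child.channels[0].id, mother.channels[0].id),
        (child.channels[1].id, mother.channels[1].id),
    ]
    ens = pseudodyad_ensemble(
        child, mother, pairs, tl, n_iter=2, master_seed=1,
        min_period=8.0, max_period=64.0,
    )
    tab = ensemble_table(ens)
    assert len(tab) == len(pairs) * len(tl.conditions())
    assert set(tab.columns) >= {"child_unit", "mother_unit", "condition", "pseudo_mean_wtc"}
    assert tab["pseudo_mean_wtc"].between(0, 1).all()
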