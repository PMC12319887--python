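import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dyadcoh import (
    DegenerateTestError,
    InvalidInputError,
    apply_inclusion,
    fdr_adjust,
    fit_mixed_model,
    likelihood_ratio_test,
    paired_onesided_test,
    pss_outlier_filter,
    pss_score,
    stepwise_lrt,
)
from dyadcoh.stats import condition_effects


# ---------------------------------------------------------------------------
# paired one-sided tests
# ---------------------------------------------------------------------------

def test_paired_test_worked_example():
    """Differences [0.2, 0.1, 0.3, 0.2]: t = 4.9 on 3 df, one-sided p ~ .008."""
    a = np.array([0.5, 0.4, 0.6, 0.5])
    b = a - np.array([0.2, 0.1, 0.3, 0.2])
    t, df, p = paired_onesided_test(a, b, "greater")
    assert t == pytest.approx(4.899, abs=0.01)
    assert df == 3
    assert p == pytest.approx(0.008, abs=0.002)


def test_paired_test_degenerate_and_direction(rng):
    with pytest.raises(DegenerateTestError):
        paired_onesided_test(np.array([2.0, 2.0, 2.0]), np.array([1.0, 1.0, 1.0]))
    a = rng.standard_normal(10)
    b = a + 1.0  # b clearly larger
    _, _, p = paired_onesided_test(a, b, "greater")
    assert p > 0.5
    _, _, p_less = paired_onesided_test(a, b, "less")
    assert p_less < 0.05


def test_unpaired_welch_option(rng):
    a = rng.standard_normal(30) + 1.0
    b = rng.standard_normal(30)
    t, df, p = paired_onesided_test(a, b, "greater", paired=False)
    assert p < 0.01
    assert df != len(a) - 1  # Welch df is not the paired df


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def test_fdr_worked_example_and_trivia():
    adj = fdr_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
    np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])
    assert fdr_adjust(np.array([0.2]))[0] == pytest.approx(0.2)
    np.testing.assert_allclose(fdr_adjust(np.array([0.3, 0.3, 0.3])), 0.3)
    with pytest.raises(InvalidInputError):
        fdr_adjust(np.array([0.5, 1.2]))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=12))
def test_fdr_monotone_and_dominates_raw(ps):
    p = np.array(ps)
    adj = fdr_adjust(p)
    assert np.all(adj >= p - 1e-12)
    assert np.all(adj <= 1.0 + 1e-12)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# PSS
# ---------------------------------------------------------------------------

def test_pss_scoring_bounds():
    assert pss_score([3] * 18).total == 54
    assert pss_score([1] * 18).total == 18
    assert pss_score([5] * 18).total == 90
    with pytest.raises(InvalidInputError):
        pss_score([3] * 17)
    with pytest.raises(InvalidInputError):
        pss_score([0] + [3] * 17)


def test_pss_cohort_outlier_flagging():
    cohort = [30] * 12 + [90]
    flagged = pss_outlier_filter(cohort)
    assert [s.outlier for s in flagged] == [False] * 12 + [True]
    assert flagged[-1].total == 90


# ---------------------------------------------------------------------------
# inclusion rules
# ---------------------------------------------------------------------------

def _coherence_rows(dyad_id, trials_by_cond):
    rows = []
    for cond, n in trials_by_cond.items():
        for tr in range(1, n + 1):
            rows.append(
                {"dyad_id": dyad_id, "condition": cond, "trial": tr, "mean_wtc": 0.4}
            )
    return rows


def test_inclusion_rules_edge_cases():
    all_ok = {r: True for r in ("lPFC", "rPFC", "lTPJ", "rTPJ")}
    none_ok = {r: False for r in all_ok}
    table = pd.DataFrame(
        _coherence_rows("d1", {"individual": 2, "collaboration": 2})
        + _coherence_rows("d2", {"individual": 2, "collaboration": 2})
        + _coherence_rows("d3", {"individual": 1, "collaboration": 2})
    )
    validity = {
        "d1": {"child": all_ok, "mother": all_ok},
        "d2": {"child": none_ok, "mother": all_ok},  # child has 0 valid ROIs
        "d3": {"child": all_ok, "mother": all_ok},  # only 1 trial of a condition
    }
    filtered, decisions = apply_inclusion(table, validity)
    by_id = {d.dyad_id: d for d in decisions}
    assert by_id["d1"].included
    assert not by_id["d2"].included and "child" in " ".join(by_id["d2"].reasons)
    assert not by_id["d3"].included and "trials" in " ".join(by_id["d3"].reasons)
    assert set(filtered["dyad_id"]) == {"d1"}
    # determinism: same inputs, same decisions
    _, again = apply_inclusion(table, validity)
    assert [(d.dyad_id, d.included) for d in again] == [
        (d.dyad_id, d.included) for d in decisions
    ]


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------

def _simulated_table(n_dyads=16, effect=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n_dyads):
        intercept = 0.4 + 0.05 * rng.standard_normal()
        for cond in ("individual", "collaboration_screen", "collaboration"):
            for tr in (1, 2):
                delta = effect if cond != "individual" else 0.0
                rows.append(
                    {
                        "dyad_id": f"d{d}", "condition": cond, "trial": tr,
                        "mean_wtc": intercept + delta + 0.03 * rng.standard_normal(),
                    }
                )
    return pd.DataFrame(rows)


def test_lrt_of_model_against_itself_is_zero():
    tab = _simulated_table()
    m = fit_mixed_model(tab, ("condition",))
    res = likelihood_ratio_test(m, m)
    assert res.chi2 == 0.0 and res.p == 1.0 and res.df == 0


def test_stepwise_retains_strong_condition_effect():
    tab = _simulated_table(effect=0.08, seed=1)
    best, history = stepwise_lrt(tab, candidate_terms=("trial", "condition"))
    terms = {h.term: h for h in history}
    assert terms["condition"].retained and terms["condition"].p < 1e-6
    assert not terms["trial"].retained
    eff = condition_effects(best)
    assert eff["collaboration"][0] == pytest.approx(0.08, abs=0.02)
    assert eff["collaboration"][0] > 0 and eff["collaboration_screen"][0] > 0


def test_stepwise_null_simulation_keeps_null_model():
    keep_null = 0
    for seed in range(8):
        tab = _simulated_table(effect=0.0, seed=100 + seed)
        _, history = stepwise_lrt(tab, candidate_terms=("condition",))
        keep_null += int(not history[0].retained)
    assert keep_null >= 6  # most replicates retain the null


def test_effect_recovery_within_two_se():
    errors = []
    for seed in range(5):
        tab = _simulated_table(effect=0.05, seed=200 + seed)
        fit = fit_mixed_model(tab, ("condition",))
        eff = condition_effects(fit)
        beta, se, _ = eff["collaboration"]
        errors.append(abs(beta - 0.05) <= 2 * se)
    assert np.mean(errors) >= 0.8
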