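import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from antimir.errors import ConfigurationError
from antimir.synergy import (
    MedianEffectFit,
    classify_ci,
    combination_index,
    median_effect_fit,
    mine_conditions,
    required_dose,
    screen_combinations,
)


def me_effects(doses, dm, m):
    ratio = (np.asarray(doses) / dm) ** m
    return ratio / (1.0 + ratio)


def test_median_effect_identity_case():
    doses = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
    fit = median_effect_fit(doses, me_effects(doses, dm=1.0, m=1.0))
    assert fit.m == pytest.approx(1.0, rel=1e-9)
    assert fit.dm == pytest.approx(1.0, rel=1e-9)
    assert fit.fa_at(1.0) == pytest.approx(0.5)


def test_median_effect_exact_recovery():
    doses = np.logspace(-1, 1, 7)
    fit = median_effect_fit(doses, me_effects(doses, dm=0.5, m=2.0))
    assert fit.dm == pytest.approx(0.5, rel=1e-6)
    assert fit.m == pytest.approx(2.0, rel=1e-6)
    assert fit.r == pytest.approx(1.0, abs=1e-9)


def test_median_effect_nonmonotone_flagged_not_fatal():
    doses = [0.1, 1.0, 10.0, 100.0]
    with pytest.warns(UserWarning, match="slope"):
        fit = median_effect_fit(doses, [0.9, 0.5, 0.3, 0.1])
    assert fit.m < 0


def test_median_effect_needs_three_usable_points():
    with pytest.raises(ConfigurationError):
        median_effect_fit([1.0, 2.0], [0.4, 0.6])


def test_required_dose_closed_forms():
    fit = MedianEffectFit(dm=2.0, m=1.0, r=1.0, n_points=5)
    assert required_dose(fit, 0.5) == pytest.approx(2.0)
    assert required_dose(fit, 0.9) == pytest.approx(18.0)
    with pytest.raises(ConfigurationError):
        required_dose(fit, 1.0)


def test_required_dose_matches_numeric_inversion():
    fit = MedianEffectFit(dm=0.7, m=1.6, r=1.0, n_points=5)
    for fa in [0.2, 0.5, 0.8, 0.95]:
        numeric = brentq(lambda d: fit.fa_at(d) - fa, 1e-9, 1e9, xtol=1e-12)
        assert required_dose(fit, fa) == pytest.approx(numeric, rel=1e-8)


def test_sham_self_combination_is_additive():
    """One drug split into two pseudo-drugs sharing a fit, with doses that
    sum to D_x(fa), must give CI = 1 exactly."""
    fit = MedianEffectFit(dm=1.3, m=0.9, r=1.0, n_points=6)
    fa = 0.7
    dx = required_dose(fit, fa)
    ci = combination_index({"a": 0.3 * dx, "b": 0.7 * dx}, fa, {"a": fit, "b": fit})
    assert ci == pytest.approx(1.0, rel=1e-9)


def test_ci_linear_in_doses():
    fits = {"a": MedianEffectFit(1.0, 1.0, 1.0, 5),
            "b": MedianEffectFit(2.0, 1.5, 1.0, 5)}
    doses = {"a": 0.4, "b": 0.9}
    full = combination_index(doses, 0.6, fits)
    half = combination_index({k: v / 2 for k, v in doses.items()}, 0.6, fits)
    assert half == pytest.approx(full / 2.0, rel=1e-12)


def test_ci_worked_two_drug_case():
    """Hand-computed CI: D_x,a = 1*(0.6/0.4)^(1/1) = 1.5,
    D_x,b = 2*(1.5)^(1/2) ~ 2.4495; CI = 0.5/1.5 + 1.0/2.4495."""
    fits = {"a": MedianEffectFit(1.0, 1.0, 1.0, 5),
            "b": MedianEffectFit(2.0, 2.0, 1.0, 5)}
    ci = combination_index({"a": 0.5, "b": 1.0}, 0.6, fits)
    expected = 0.5 / 1.5 + 1.0 / (2.0 * 1.5 ** 0.5)
    assert ci == pytest.approx(expected, rel=1e-12)


def test_ci_invariant_to_consistent_unit_rescaling():
    fits = {"a": MedianEffectFit(1.0, 1.2, 1.0, 5),
            "b": MedianEffectFit(0.3, 0.8, 1.0, 5)}
    doses = {"a": 0.7, "b": 0.1}
    base = combination_index(doses, 0.55, fits)
    scale = 1000.0    # e.g. mg/kg -> ug/kg applied everywhere
    fits_scaled = {k: MedianEffectFit(f.dm * scale, f.m, f.r, f.n_points)
                   for k, f in fits.items()}
    scaled = combination_index({k: v * scale for k, v in doses.items()}, 0.55,
                               fits_scaled)
    assert scaled == pytest.approx(base, rel=1e-12)


@pytest.mark.parametrize("ci, label", [
    (0.25, "strong-synergy"),
    (0.3, "synergy"),
    (0.89, "synergy"),
    (0.95, "additive"),
    (1.0, "additive"),
    (1.1, "additive"),
    (1.2, "antagonism"),
    (5.0, "antagonism"),
])
def test_ci_classification_thresholds(ci, label):
    assert classify_ci(ci) == label


@given(st.floats(1e-6, 1e6))
@settings(max_examples=200, deadline=None)
def test_ci_classes_partition_the_positive_axis(ci):
    assert classify_ci(ci) in {"strong-synergy", "synergy", "additive", "antagonism"}


def test_classify_rejects_nonpositive():
    with pytest.raises(ConfigurationError):
        classify_ci(0.0)


# ---------------------------------------------------------------------------
# cohort screening
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def tiny_screen(human_params):
    from antimir.cohort import sample_cohort

    cohort = sample_cohort(human_params, n=4, seed=21)
    return screen_combinations(cohort, ("anti_mir155_np", "cisplatin"),
                               n_samples=4, seed=2, follow_up_months=8.0)


def test_screen_output_schema(tiny_screen):
    expected = {"dose_anti_mir155_np", "dose_cisplatin", "fraction_anti_mir155_np",
                "fraction_cisplatin", "total_dose", "fa", "ci", "ci_class",
                "median_pfs_months"}
    assert expected <= set(tiny_screen.columns)
    ok = tiny_screen[~tiny_screen.failed]
    assert len(ok) == 4
    assert ((ok.fa > 0) & (ok.fa < 1)).all()
    assert (ok.ci > 0).all()


def test_screen_is_seed_deterministic(human_params, tiny_screen):
    from antimir.cohort import sample_cohort

    cohort = sample_cohort(human_params, n=4, seed=21)
    again = screen_combinations(cohort, ("anti_mir155_np", "cisplatin"),
                                n_samples=4, seed=2, follow_up_months=8.0)
    assert np.allclose(again.ci, tiny_screen.ci, equal_nan=True)
    assert np.allclose(again.dose_anti_mir155_np, tiny_screen.dose_anti_mir155_np)


def test_condition_mining_emits_threshold_rules(tiny_screen):
    present = tiny_screen.ci_class.value_counts().idxmax()
    rules = mine_conditions(tiny_screen, present)
    assert isinstance(rules, list) and rules
    assert any(tok in rules[0] for tok in ("dose_", "fraction_", "total_", "class"))
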