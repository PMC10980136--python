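import numpy as np
import pytest

from antimir.errors import ConfigurationError, UndefinedMetricError
from antimir.survival import (
    hazard_ratio,
    kaplan_meier,
    median_pfs,
    pfs_dose_hill,
)


def brute_force_product_limit(times, events, grid):
    """Independent product-limit computation by direct counting."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    out = []
    for t in grid:
        s = 1.0
        for ti in np.unique(times[events]):
            if ti <= t:
                at_risk = np.sum(times >= ti)
                d = np.sum((times == ti) & events)
                s *= 1.0 - d / at_risk
        out.append(s)
    return np.array(out)


def test_km_four_events_no_censoring():
    curve = kaplan_meier([1.0, 2.0, 3.0, 4.0])
    assert curve.probability_at(2.0) == pytest.approx(0.5)
    assert median_pfs(curve) == pytest.approx(2.0)
    assert curve.probability_at(4.0) == pytest.approx(0.0)


def test_km_all_censored_median_not_reached():
    curve = kaplan_meier([5.0, 7.0, 9.0], [False, False, False])
    assert np.allclose(curve.survival, 1.0)
    assert median_pfs(curve) is None


def test_km_single_subject_steps_to_zero():
    curve = kaplan_meier([3.5])
    assert curve.probability_at(3.4) == 1.0
    assert curve.probability_at(3.5) == 0.0


def test_km_matches_brute_force_with_censoring():
    """Six-subject mixed-censoring case against the independent
    product-limit oracle."""
    times = [1.0, 2.0, 2.0, 3.0, 4.0, 6.0]
    events = [True, True, False, True, False, True]
    curve = kaplan_meier(times, events)
    grid = [0.5, 1.0, 2.0, 3.0, 5.0, 6.0]
    expected = brute_force_product_limit(times, events, grid)
    got = [curve.probability_at(t) for t in grid]
    assert np.allclose(got, expected, rtol=1e-12)


def test_km_without_censoring_equals_empirical_survival():
    rng = np.random.default_rng(0)
    times = np.round(rng.exponential(3.0, 40), 2)
    curve = kaplan_meier(times)
    for t in [0.5, 1.0, 2.5, 5.0]:
        assert curve.probability_at(t) == pytest.approx(np.mean(times > t))


def test_median_invariant_to_late_censoring():
    base = kaplan_meier([1.0, 2.0, 3.0, 4.0, 5.0])
    censored = kaplan_meier([1.0, 2.0, 3.0, 4.5, 4.8],
                            [True, True, True, False, False])
    assert median_pfs(base) == median_pfs(censored) == pytest.approx(3.0)


def test_km_input_validation():
    with pytest.raises(ConfigurationError):
        kaplan_meier([])
    with pytest.raises(ConfigurationError):
        kaplan_meier([-1.0])


# ---------------------------------------------------------------------------
# hazard ratio
# ---------------------------------------------------------------------------


def test_hr_identical_groups_is_unity():
    t = [1.0, 2.0, 3.0, 4.0]
    res = hazard_ratio(t, [True] * 4, t, [True] * 4)
    assert res.hr == pytest.approx(1.0)
    assert not res.separated


def test_hr_direction_for_doubled_times():
    rng = np.random.default_rng(2)
    ctrl = rng.exponential(2.0, 80)
    res = hazard_ratio(2.0 * ctrl, [True] * 80, ctrl, [True] * 80)
    assert res.hr < 1.0


def test_hr_recovers_simulated_rate_ratio():
    """Exponential groups with rate ratio 0.5 at n = 500/arm give
    HR ~ 0.5 +- 0.1 (simulation oracle)."""
    rng = np.random.default_rng(42)
    ctrl = rng.exponential(1.0, 500)
    trt = rng.exponential(2.0, 500)
    res = hazard_ratio(trt, [True] * 500, ctrl, [True] * 500)
    assert res.hr == pytest.approx(0.5, abs=0.1)
    assert res.ci_lower < res.hr < res.ci_upper


def test_hr_label_swap_is_reciprocal():
    rng = np.random.default_rng(5)
    a = rng.exponential(1.0, 60)
    b = rng.exponential(1.6, 60)
    fwd = hazard_ratio(a, [True] * 60, b, [True] * 60)
    rev = hazard_ratio(b, [True] * 60, a, [True] * 60)
    assert fwd.hr == pytest.approx(1.0 / rev.hr, rel=1e-9)


def test_hr_flags_complete_separation():
    ctrl = np.linspace(0.5, 2.0, 30)
    trt = np.linspace(50.0, 60.0, 30)
    res = hazard_ratio(trt, [True] * 30, ctrl, [True] * 30)
    assert res.separated
    assert res.hr is None


def test_hr_rejects_eventless_group():
    with pytest.raises(UndefinedMetricError):
        hazard_ratio([1.0, 2.0], [False, False], [1.0, 2.0], [True, True])


# ---------------------------------------------------------------------------
# median PFS versus dose
# ---------------------------------------------------------------------------


def test_pfs_dose_hill_exact_recovery():
    doses = np.logspace(-2, 1.5, 8)
    emax, ec50, n = 7.6, 0.05, 0.9
    medians = emax / (1.0 + (ec50 / doses) ** n)
    fit = pfs_dose_hill(doses, medians)
    assert fit.emax == pytest.approx(emax, rel=1e-6)
    assert fit.ec50 == pytest.approx(ec50, rel=1e-5)
    assert fit.ec_p(50.0) == pytest.approx(fit.ec50)


def test_pfs_dose_hill_excludes_not_reached():
    doses = np.logspace(-2, 1.5, 8)
    medians = list(7.6 / (1.0 + (0.05 / doses) ** 0.9))
    medians[-1] = None
    with pytest.warns(UserWarning, match="not-reached"):
        fit = pfs_dose_hill(doses, medians)
    assert len(fit.doses) == 7


def test_pfs_dose_hill_saturation_at_ec85():
    """A median-PFS Hill with E_max 7.6 months evaluated at its EC_85 dose
    returns 85% of the plateau: ~6.5 months."""
    doses = np.logspace(-2, 2, 10)
    medians = 7.6 / (1.0 + (0.1 / doses) ** 0.8)
    fit = pfs_dose_hill(doses, medians)
    value = fit.predict(fit.ec_p(85.0))
    assert value == pytest.approx(0.85 * 7.6, rel=1e-9)
    assert round(value, 1) == 6.5
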