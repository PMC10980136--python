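import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from antimir.errors import ConfigurationError, UndefinedMetricError
from antimir.response import (
    diameter_from_volume,
    recist_stream,
    time_to_progression,
    tumor_growth_inhibition,
    volume_from_diameter,
)


def grow(times, v0, rate):
    return v0 * np.exp(rate * np.asarray(times, dtype=float))


# ---------------------------------------------------------------------------
# TGI
# ---------------------------------------------------------------------------


def test_tgi_zero_when_treated_equals_control(volume_traj_factory):
    t = np.linspace(0, 60, 61)
    ctrl = volume_traj_factory(t, grow(t, 1.0, 0.02))
    trt = volume_traj_factory(t, grow(t, 1.0, 0.02))
    assert tumor_growth_inhibition(trt, ctrl, 60.0) == pytest.approx(0.0)


def test_tgi_hundred_when_volume_pinned(volume_traj_factory):
    t = np.linspace(0, 60, 61)
    ctrl = volume_traj_factory(t, grow(t, 1.0, 0.02))
    trt = volume_traj_factory(t, np.full_like(t, 1.0))
    assert tumor_growth_inhibition(trt, ctrl, 60.0) == pytest.approx(100.0)


def test_tgi_undefined_without_control_growth(volume_traj_factory):
    t = np.linspace(0, 30, 31)
    ctrl = volume_traj_factory(t, np.full_like(t, 1.0))
    trt = volume_traj_factory(t, grow(t, 1.0, -0.01))
    with pytest.raises(UndefinedMetricError):
        tumor_growth_inhibition(trt, ctrl, 30.0)


def test_tgi_requires_shared_baseline(volume_traj_factory):
    t = np.linspace(0, 30, 31)
    ctrl = volume_traj_factory(t, grow(t, 1.0, 0.02))
    trt = volume_traj_factory(t, grow(t, 2.0, 0.01))
    with pytest.raises(ConfigurationError):
        tumor_growth_inhibition(trt, ctrl, 30.0)


# ---------------------------------------------------------------------------
# diameter
# ---------------------------------------------------------------------------


def test_diameter_reference_values():
    assert diameter_from_volume(math.pi / 6.0) == pytest.approx(1.0)
    assert diameter_from_volume(10.0) == pytest.approx(2.68, abs=0.01)
    assert diameter_from_volume(0.0) == 0.0
    with pytest.raises(ConfigurationError):
        diameter_from_volume(-1.0)


@given(st.floats(1e-6, 1e3))
@settings(max_examples=100, deadline=None)
def test_diameter_volume_round_trip(d):
    assert diameter_from_volume(volume_from_diameter(d)) == pytest.approx(d, rel=1e-12)


# ---------------------------------------------------------------------------
# RECIST stream / TTP
# ---------------------------------------------------------------------------


def ramp_to_diameter(v0_d, d_end, days=120):
    t = np.arange(0.0, days + 1.0)
    d = np.linspace(v0_d, d_end, len(t))
    return t, volume_from_diameter(d)


def test_pd_threshold_small_baseline_uses_absolute_floor(volume_traj_factory):
    """Baseline 1.5 cm: 20% is 0.3 cm < the 0.5 cm floor, so PD fires only
    at 2.0 cm."""
    t, v = ramp_to_diameter(1.5, 2.2)
    traj = volume_traj_factory(t, v)
    stream = recist_stream(traj)
    first_pd = stream[stream.category == "PD"].diameter_cm.iloc[0]
    assert first_pd == pytest.approx(2.0, abs=0.02)


def test_pd_threshold_large_baseline_uses_relative_rule(volume_traj_factory):
    """Baseline 3.0 cm: 20% is 0.6 cm > floor, so PD fires at 3.6 cm."""
    t, v = ramp_to_diameter(3.0, 4.0)
    traj = volume_traj_factory(t, v)
    stream = recist_stream(traj)
    first_pd = stream[stream.category == "PD"].diameter_cm.iloc[0]
    assert first_pd == pytest.approx(3.6, abs=0.02)


def test_thirty_percent_shrinkage_is_partial_response(volume_traj_factory):
    t, v = ramp_to_diameter(1.5, 0.9)
    traj = volume_traj_factory(t, v)
    stream = recist_stream(traj)
    assert stream.category.iloc[-1] == "PR"
    assert stream.change_from_baseline_percent.iloc[-1] == pytest.approx(-40.0, abs=0.5)


def test_pd_uses_nadir_not_baseline(volume_traj_factory):
    """A tumor that shrinks to 1.0 cm then regrows progresses at
    max(1.2 cm, 1.5 cm) = 1.5 cm, i.e. before exceeding baseline + 0.5."""
    t = np.arange(0.0, 201.0)
    d = np.concatenate([np.linspace(1.8, 1.0, 100), np.linspace(1.0, 1.9, 101)])
    traj = volume_traj_factory(t, volume_from_diameter(d))
    stream = recist_stream(traj)
    first_pd = stream[stream.category == "PD"]
    assert len(first_pd)
    assert first_pd.diameter_cm.iloc[0] == pytest.approx(1.5, abs=0.02)


def test_stream_invariant_to_supersampling(volume_traj_factory):
    t = np.arange(0.0, 121.0)
    v = grow(t, 1.767, 0.012)
    coarse = recist_stream(volume_traj_factory(t, v), assessment_grid=t[::7])
    t_fine = np.arange(0.0, 120.1, 0.25)
    traj_fine = volume_traj_factory(t_fine, grow(t_fine, 1.767, 0.012))
    fine = recist_stream(traj_fine, assessment_grid=t[::7])
    assert list(coarse.category) == list(fine.category)


def test_empty_assessment_grid_rejected(volume_traj_factory):
    t = np.arange(0.0, 10.0)
    traj = volume_traj_factory(t, grow(t, 1.0, 0.01))
    with pytest.raises(ConfigurationError):
        recist_stream(traj, assessment_grid=[])


def test_shrinking_tumor_is_censored(volume_traj_factory):
    t = np.arange(0.0, 200.0)
    traj = volume_traj_factory(t, grow(t, 1.767, -0.005))
    ttp, censored = time_to_progression(traj)
    assert censored and ttp is None


def test_ttp_unit_conversion_on_handmade_crossing(volume_traj_factory):
    """Diameter crosses its PD threshold at day 61 -> TTP 2.0 months."""
    t = np.arange(0.0, 100.0)
    d0 = 1.5
    d = np.where(t < 61, d0, 2.01)   # jumps past the 2.0 cm threshold at day 61
    traj = volume_traj_factory(t, volume_from_diameter(d))
    ttp, censored = time_to_progression(traj)
    assert not censored
    assert ttp == pytest.approx(61.0 / 30.44, abs=1e-9)
    assert round(ttp, 1) == 2.0


def test_ttp_nondecreasing_under_pointwise_shrinkage(volume_traj_factory):
    t = np.arange(0.0, 301.0)
    fast = volume_from_diameter(np.linspace(1.5, 2.6, len(t)))
    slow = volume_from_diameter(np.linspace(1.5, 2.2, len(t)))
    ttp_fast, _ = time_to_progression(volume_traj_factory(t, fast))
    ttp_slow, _ = time_to_progression(volume_traj_factory(t, slow))
    assert ttp_slow >= ttp_fast


def test_control_patient_progresses_within_six_weeks(human_params, volume_traj_factory):
    """The untreated average patient progresses in under six weeks."""
    from antimir.model import untreated_volume
    from antimir.dosing import HUMAN_INCEPTION_TO_TREATMENT

    v0 = float(untreated_volume(human_params, HUMAN_INCEPTION_TO_TREATMENT))
    t = np.arange(0.0, 120.0)
    traj = volume_traj_factory(t, untreated_volume(human_params, t, v0=v0))
    ttp, censored = time_to_progression(traj)
    assert not censored
    assert ttp * 30.44 / 7.0 < 6.5
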