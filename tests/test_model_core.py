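import numpy as np
import pytest
from scipy.optimize import brentq

from antimir import (
    load_default_parameters,
    preclinical_regimen,
    simulate,
    percent_injected_dose,
    checkpoint_occupancy,
)
from antimir.dosing import DoseEvent, Regimen, periodic_regimen
from antimir.errors import ConfigurationError, UndefinedMetricError
from antimir.model import (
    STATE_NAMES,
    build_rhs,
    initial_state,
    molecular_equilibrium,
    untreated_volume,
)

IDX = {n: i for i, n in enumerate(STATE_NAMES)}


# ---------------------------------------------------------------------------
# right-hand side structure
# ---------------------------------------------------------------------------


def test_logistic_brake_at_carrying_capacity(mouse_params):
    rhs = build_rhs(mouse_params)
    y = initial_state(mouse_params, mouse_params.growth.carrying_capacity)
    dv = rhs(0.0, y)[IDX["tumor_volume"]]
    assert dv <= 0.0


def test_mir155_equilibrium_is_stationary(mouse_params):
    rhs = build_rhs(mouse_params)
    y = initial_state(mouse_params, 0.5)
    dy = rhs(0.0, y)
    assert dy[IDX["mir155_cancer"]] == pytest.approx(0.0, abs=1e-10)
    assert dy[IDX["mir155_tam"]] == pytest.approx(0.0, abs=1e-10)
    assert dy[IDX["pd1"]] == pytest.approx(0.0, abs=1e-12)


def test_antagonist_saturation_approaches_full_gain(mouse_params):
    """With intracellular anti-miR-155 far above its potency the miR-155
    degradation multiplier approaches 1 + A (closed-form Hill limit)."""
    mir = mouse_params.mirna
    rhs = build_rhs(mouse_params)
    y = initial_state(mouse_params, 0.5)
    y[IDX["antimir_cancer"]] = mir.antagonist_potency * 1e6
    m = y[IDX["mir155_cancer"]]
    dm = rhs(0.0, y)[IDX["mir155_cancer"]]
    # dm = g0_c - delta * mult * m + k_exo * m_t  ->  solve for mult
    g0_c = mir.production_rate - mir.exosomal_transfer_rate * mir.equilibrium
    mult = (g0_c + mir.exosomal_transfer_rate * y[IDX["mir155_tam"]] - dm) / (
        mir.degradation_rate * m)
    assert mult == pytest.approx(1.0 + mir.antagonist_gain, rel=1e-4)


def test_rhs_finite_for_random_nonnegative_states(mouse_params):
    rhs = build_rhs(mouse_params)
    rng = np.random.default_rng(1)
    for _ in range(50):
        y = rng.exponential(1.0, len(STATE_NAMES))
        assert np.all(np.isfinite(rhs(0.0, y)))


# ---------------------------------------------------------------------------
# checkpoint occupancy
# ---------------------------------------------------------------------------


def test_occupancy_trivial_limits():
    assert checkpoint_occupancy(0.0, 1.0) == 1.0
    # saturating antibody on either target restores the factor to ~1
    assert checkpoint_occupancy(10.0, 1.0, atezolizumab_pm=1e12) == pytest.approx(1.0, abs=1e-6)
    assert checkpoint_occupancy(10.0, 1.0, pembrolizumab_pm=1e12) == pytest.approx(1.0, abs=1e-6)
    # more ligand -> more complex -> smaller factor
    assert checkpoint_occupancy(10.0, 1.0) < checkpoint_occupancy(1.0, 1.0)


@pytest.mark.parametrize("l_tot, r_tot, ate, pem", [
    (1.0, 1.0, 0.0, 0.0),
    (10.0, 1.0, 400.0, 0.0),      # atezolizumab at its Kd
    (10.0, 1.0, 0.0, 29.0),       # pembrolizumab at its Kd
    (5.0, 2.0, 123.0, 45.0),
])
def test_occupancy_matches_brute_force_equilibrium(l_tot, r_tot, ate, pem):
    """The closed-form quadratic solution equals an independent numerical
    solution of the competitive binding equilibrium."""
    kd, kd_a, kd_p, k_inh = 1.0, 400.0, 29.0, 0.5

    def residual(l_free):
        r_free = r_tot / (1.0 + pem / kd_p + l_free / kd)
        return l_free * (1.0 + ate / kd_a + r_free / kd) - l_tot

    l_free = brentq(residual, 0.0, l_tot, xtol=1e-14)
    r_free = r_tot / (1.0 + pem / kd_p + l_free / kd)
    complex_rl = r_free * l_free / kd
    expected = k_inh / (k_inh + complex_rl)
    got = checkpoint_occupancy(l_tot, r_tot, ate, pem, kd_pd1_pdl1=kd,
                               kd_atezolizumab=kd_a, kd_pembrolizumab=kd_p,
                               inhibition_constant=k_inh)
    assert got == pytest.approx(expected, rel=1e-10)


# ---------------------------------------------------------------------------
# simulation invariants
# ---------------------------------------------------------------------------


def test_control_arm_grows_monotonically(mouse_control):
    assert np.all(np.diff(mouse_control.volume) > 0)


def test_nanoparticle_mass_conservation(mouse_params):
    """With clearance, degradation and cellular uptake all zeroed, plasma +
    interstitial NP mass equals the injected mass at every output time."""
    p = mouse_params.copy()
    p.nanoparticle.clearance_rate = 0.0
    p.nanoparticle.degradation_rate = 0.0
    p.transport.diffusivity_scale = 1e-30    # no uptake
    reg = periodic_regimen("anti_mir155_np", 0.2, 3.5, 4, treatment_start=0.0,
                           follow_up_end=21.0)
    traj = simulate(p, reg, t_grid=0.25)
    # samples at an event time are pre-dose; the t=0 dose lands before step 1
    n_doses = 1 + np.searchsorted([3.5, 7.0, 10.5], traj.time, side="left")
    injected = n_doses * 0.2 * p.species.body_weight
    total = traj["np_plasma"] + traj["np_interstitium"]
    assert np.allclose(total[traj.time > 0], injected[traj.time > 0], rtol=1e-6)


def test_cisplatin_mass_conservation(mouse_params):
    p = mouse_params.copy()
    p.chemo.clearance_rate = 0.0
    p.chemo.interstitial_degradation = 0.0
    reg = periodic_regimen("cisplatin", 8.0, 7.0, 1, follow_up_end=14.0)
    traj = simulate(p, reg, t_grid=0.25)
    total = traj["cisplatin_plasma"] + traj["cisplatin_interstitium"]
    assert np.allclose(total, 8.0 * p.species.body_weight, rtol=1e-6)


@pytest.mark.parametrize("arm", ["anti_mir155", "cisplatin", "combination",
                                 "atezolizumab", "pembrolizumab"])
def test_states_stay_nonnegative(mouse_params, arm):
    traj = simulate(mouse_params, preclinical_regimen(arm))
    assert traj.states.min() >= 0.0
    assert traj.volume.min() > 0.0


def test_pretreatment_molecular_equilibria(mouse_control):
    """miR-155 sits at ~1.5 pM in both cell types and PD-1 at exactly 1 pM
    before any drug arrives."""
    pre = mouse_control.time <= 7.0
    assert np.allclose(mouse_control["mir155_cancer"][pre], 1.5, rtol=1e-3)
    assert np.allclose(mouse_control["mir155_tam"][pre], 1.5, rtol=1e-3)
    assert np.allclose(mouse_control["pd1"], 1.0, rtol=1e-6)


def test_treatment_suppresses_mir155_and_raises_pdl1(mouse_antimir):
    """Sustained anti-miR-155 exposure drives miR-155 below 0.05 pM while
    free PD-L1 rises by roughly an order of magnitude."""
    during = (mouse_antimir.time > 9.0) & (mouse_antimir.time < 28.0)
    assert mouse_antimir["mir155_cancer"][during].max() < 0.05
    assert mouse_antimir["mir155_tam"][during].max() < 0.05
    baseline = mouse_antimir["pdl1_cancer"][0] + mouse_antimir["pdl1_tam"][0]
    peak = (mouse_antimir["pdl1_cancer"] + mouse_antimir["pdl1_tam"]).max()
    assert 7.0 < peak / baseline < 12.0


def test_grid_refinement_convergence(mouse_params):
    reg = preclinical_regimen("anti_mir155")
    coarse = simulate(mouse_params, reg, rtol=1e-7)
    fine = simulate(mouse_params, reg, rtol=5e-8)
    assert fine.volume_at(28.0) == pytest.approx(coarse.volume_at(28.0), rel=1e-3)


def test_end_volume_nonincreasing_in_dose(mouse_params):
    """Anti-miR-155 monotherapy: more drug never means more tumor."""
    vols = []
    for dose in [0.02, 0.1, 0.2, 1.0]:
        reg = periodic_regimen("anti_mir155_np", dose, 3.5, 6,
                               treatment_start=7.0, follow_up_end=28.0)
        vols.append(simulate(mouse_params, reg).volume_at(28.0))
    assert np.all(np.diff(vols) <= 1e-6)


def test_untreated_closed_form_matches_ode(human_params):
    traj = simulate(human_params, Regimen(events=[], follow_up_end=400.0), v0=1.0)
    closed = untreated_volume(human_params, traj.time, v0=1.0)
    assert np.allclose(traj.volume, closed, rtol=1e-5)


def test_dose_outside_window_rejected(mouse_params):
    with pytest.raises(ConfigurationError):
        Regimen(events=[DoseEvent("cisplatin", 8.0, 30.0)], follow_up_end=28.0)
    with pytest.raises(ConfigurationError):
        simulate(mouse_params, preclinical_regimen("control"),
                 t_grid=np.array([0.0, 40.0]))


# ---------------------------------------------------------------------------
# percent injected dose
# ---------------------------------------------------------------------------


def test_percent_id_zero_without_extravasation(mouse_params):
    p = mouse_params.copy()
    p.nanoparticle.vascular_permeability_ref = 0.0
    traj = simulate(p, preclinical_regimen("anti_mir155"), t_grid=0.5)
    pid = percent_injected_dose(traj)
    assert np.allclose(pid.percent_id, 0.0)


def test_percent_id_peaks_near_three_percent(mouse_params, mouse_antimir):
    """Per-injection interstitial peaks average ~3 %ID with the default
    mouse parameterization (soft anchor, +-1.5)."""
    reg = preclinical_regimen("anti_mir155")
    peaks = [percent_injected_dose(mouse_antimir, e).percent_id.max()
             for e in reg.events]
    assert np.all(np.array(peaks) <= 100.0)
    assert 1.5 <= np.mean(peaks) <= 4.5


def test_percent_id_is_100_when_all_mass_interstitial(mouse_params):
    from antimir.model import Trajectory

    reg = preclinical_regimen("anti_mir155")
    injected = reg.events[0].dose * mouse_params.species.body_weight
    t = np.array([7.0, 8.0])
    states = np.tile(initial_state(mouse_params, 0.1), (2, 1))
    states[:, IDX["np_interstitium"]] = injected
    probe = Trajectory(time=t, states=states, params=mouse_params, regimen=reg)
    pid = percent_injected_dose(probe, reg.events[0])
    assert np.allclose(pid.percent_id, 100.0)


def test_percent_id_rejects_zero_dose(mouse_antimir):
    with pytest.raises(UndefinedMetricError):
        percent_injected_dose(mouse_antimir, DoseEvent("anti_mir155_np", 0.0, 0.0))
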