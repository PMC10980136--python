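"""The multiscale PK/PD ODE system and its numerical solution.

The model couples two compartments.  The plasma compartment carries the
systemic pharmacokinetics of anti-miR-155-loaded nanoparticles (NPs),
cisplatin, and the immune-checkpoint antibodies; each agent reaches the tumor
interstitium through a permeation-limited exchange across the tumor
microvasculature (permeability x vascular surface area x tumor volume, driven
by the plasma/interstitium concentration difference).  Inside the tumor, NPs
diffuse over the intercapillary distance and are taken up by cancer cells and
tumor-associated macrophages (TAMs), releasing anti-miR-155 into an effective
cytosolic volume.  Anti-miR-155 accelerates miR-155 degradation through a
saturable multiplier; miR-155 in turn (i) stimulates tumor proliferation,
(ii) inflates the cisplatin IC50 (the lumped miR-155/TP53 resistance
feedback), and (iii) represses PD-L1 expression.  T-cell-mediated tumor kill
is attenuated by PD-1:PD-L1 complex formation, computed at each step from the
competitive binding equilibrium with atezolizumab (anti-PD-L1) and
pembrolizumab (anti-PD-1).  Tumor volume follows logistic growth minus
chemotherapy- and immune-mediated death.

All equations follow mass-action kinetics and conserve mass across
compartments; dosing is applied as instantaneous plasma-mass increments with
the integration restarted at every event.

State vector (16 states)::

    0  NP_pl    NP-borne anti-miR-155 mass in plasma              mg
    1  NP_int   NP-borne anti-miR-155 mass in tumor interstitium  mg
    2  AM_c     intracellular anti-miR-155, cancer cells          mg/mL
    3  AM_t     intracellular anti-miR-155, TAMs                  mg/mL
    4  M_c      miR-155, cancer cells                             pM
    5  M_t      miR-155, TAMs                                     pM
    6  L_c      free PD-L1, cancer cells                          pM
    7  L_t      free PD-L1, TAMs                                  pM
    8  PD1      free PD-1 on T cells                              pM
    9  C_pl     cisplatin mass in plasma                          mg
    10 C_int    cisplatin mass in tumor interstitium              mg
    11 A_pl     atezolizumab mass in plasma                       mg
    12 A_int    atezolizumab mass in tumor interstitium           mg
    13 E_pl     pembrolizumab mass in plasma                      mg
    14 E_int    pembrolizumab mass in tumor interstitium          mg
    15 V        tumor volume                                      cm^3
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dosing import Regimen
from .errors import (
    ConfigurationError,
    NumericalIntegrityError,
    SimulationError,
    UndefinedMetricError,
)
from .parameters import ModelParameters

__all__ = [
    "STATE_NAMES",
    "Trajectory",
    "build_rhs",
    "simulate",
    "percent_injected_dose",
    "checkpoint_occupancy",
    "molecular_equilibrium",
    "untreated_net_growth",
    "untreated_volume",
]

STATE_NAMES = (
    "np_plasma", "np_interstitium",
    "antimir_cancer", "antimir_tam",
    "mir155_cancer", "mir155_tam",
    "pdl1_cancer", "pdl1_tam", "pd1",
    "cisplatin_plasma", "cisplatin_interstitium",
    "atezolizumab_plasma", "atezolizumab_interstitium",
    "pembrolizumab_plasma", "pembrolizumab_interstitium",
    "tumor_volume",
)

_PLASMA_STATE = {
    "anti_mir155_np": 0,
    "cisplatin": 9,
    "atezolizumab": 11,
    "pembrolizumab": 13,
}

#: tolerated negative excursion before a NumericalIntegrityError is raised
NEGATIVITY_TOLERANCE = -1e-6


def checkpoint_occupancy(
    free_pdl1: float,
    free_pd1: float,
    atezolizumab_pm: float = 0.0,
    pembrolizumab_pm: float = 0.0,
    *,
    kd_pd1_pdl1: float = 1.0,
    kd_atezolizumab: float = 400.0,
    kd_pembrolizumab: float = 29.0,
    inhibition_constant: float = 0.5,
) -> float:
    """Immune-kill attenuation factor psi in (0, 1].

    Solves the competitive binding equilibrium between PD-1 (total
    ``free_pd1``), PD-L1 (total ``free_pdl1``) and the two antibodies (held at
    their interstitial concentrations, pM) and maps the resulting PD-1:PD-L1
    complex concentration through ``psi = K / (K + complex)``.  With no ligand
    the factor is 1 (no immune escape); saturating antibody drives it back to
    1 (full blockade).
    """
    if free_pdl1 < 0 or free_pd1 < 0 or atezolizumab_pm < 0 or pembrolizumab_pm < 0:
        raise ConfigurationError("checkpoint occupancy inputs must be nonnegative")
    if free_pdl1 == 0.0 or free_pd1 == 0.0:
        return 1.0
    a = 1.0 + pembrolizumab_pm / kd_pembrolizumab   # PD-1 sequestration factor
    b = 1.0 + atezolizumab_pm / kd_atezolizumab     # PD-L1 sequestration factor
    kd = kd_pd1_pdl1
    # free ligand from  b*Lf + R*Lf/(kd*a + Lf) = L  (quadratic in Lf)
    bq = b * kd * a + free_pd1 - free_pdl1
    l_free = (-bq + math.sqrt(bq * bq + 4.0 * b * free_pdl1 * kd * a)) / (2.0 * b)
    r_free = free_pd1 / (a + l_free / kd)
    complex_rl = r_free * l_free / kd
    return inhibition_constant / (inhibition_constant + complex_rl)


def molecular_equilibrium(params: ModelParameters) -> dict[str, float]:
    """Drug-free steady state of the molecular sub-system (used for initial
    conditions and for the closed-form untreated growth law)."""
    mir = params.mirna
    cp = params.checkpoint
    m_eq = mir.equilibrium
    l_eq = cp.pdl1_production * cp.pdl1_repression_constant / (
        (cp.pdl1_repression_constant + m_eq) * cp.pdl1_degradation
    )
    return {
        "mir155": m_eq,
        "pdl1_per_type": l_eq,
        "pd1": cp.pd1_equilibrium,
    }


def _psi_at_equilibrium(params: ModelParameters) -> float:
    eq = molecular_equilibrium(params)
    cp = params.checkpoint
    return checkpoint_occupancy(
        2.0 * eq["pdl1_per_type"], eq["pd1"],
        kd_pd1_pdl1=cp.kd_pd1_pdl1, kd_atezolizumab=cp.kd_atezolizumab,
        kd_pembrolizumab=cp.kd_pembrolizumab,
        inhibition_constant=cp.inhibition_constant,
    )


def untreated_net_growth(params: ModelParameters) -> tuple[float, float]:
    """Return ``(r, K_eff)`` of the untreated tumor volume law.

    With molecular states at their drug-free equilibria the volume equation
    collapses to a scalar logistic ODE ``dV/dt = r V (1 - V/K_eff)`` with
    ``r = a - b`` and ``K_eff = K (1 - b/a)``, where ``a`` is the
    miR-155-boosted proliferation rate and ``b`` the baseline immune kill.
    """
    eq = molecular_equilibrium(params)
    mir = params.mirna
    m = eq["mir155"]
    phi = 1.0 + (mir.proliferation_gain - 1.0) * m / (mir.potency + m)
    a = params.growth.intrinsic_growth_rate * phi
    b = params.checkpoint.immune_kill_max * _psi_at_equilibrium(params)
    if b >= a:
        raise ConfigurationError(
            "baseline immune kill exceeds proliferation: untreated tumor cannot grow"
        )
    r = a - b
    return r, params.growth.carrying_capacity * r / a


def untreated_volume(params: ModelParameters, t, v0: float | None = None):
    """Closed-form untreated tumor volume at time(s) ``t`` days from a volume
    ``v0`` (default: the single founding cell)."""
    r, k = untreated_net_growth(params)
    v0 = params.growth.initial_cell_volume if v0 is None else v0
    e = np.exp(np.clip(r * np.asarray(t, dtype=float), None, 700.0))
    return k * v0 * e / (k + v0 * (e - 1.0))


@dataclass
class Trajectory:
    """Time-indexed record of all model states for one simulated subject."""

    time: np.ndarray
    states: np.ndarray                    # shape (len(time), 16)
    params: ModelParameters
    regimen: Regimen
    arm: str = ""
    patient_id: str = ""
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    @property
    def volume(self) -> np.ndarray:
        return self[STATE_NAMES[-1]]

    @property
    def diameter(self) -> np.ndarray:
        """Spherical-equivalent tumor diameter, cm."""
        return np.cbrt(6.0 * self.volume / math.pi)

    def at(self, t: float) -> np.ndarray:
        """Linearly interpolated state vector at time ``t``."""
        return np.array([np.interp(t, self.time, self.states[:, j])
                         for j in range(self.states.shape[1])])

    def volume_at(self, t: float) -> float:
        return float(np.interp(t, self.time, self.volume))

    def to_frame(self, tidy: bool = True) -> pd.DataFrame:
        wide = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        wide.insert(0, "time_day", self.time)
        if not tidy:
            return wide
        long = wide.melt(id_vars="time_day", var_name="variable", value_name="value")
        long["arm"] = self.arm
        long["patient_id"] = self.patient_id
        return long


def build_rhs(params: ModelParameters):
    """Compile the parameter set into a fast ``f(t, y) -> dy`` evaluator.

    All derived quantities (effective NP permeability, diffusive delivery
    rate, equilibrium-preserving cancer-cell miR-155 production, unit
    conversions) are evaluated once; the returned closure works on plain
    floats and returns finite derivatives for any nonnegative state.
    """
    params.validate()
    sp, npp, tr = params.species, params.nanoparticle, params.transport
    mir, cp, ch, gr = params.mirna, params.checkpoint, params.chemo, params.growth

    v_pl = sp.plasma_volume
    phi_int = sp.tumor_interstitial_fraction

    p_np = npp.vascular_permeability
    s = tr.vascular_surface_density
    len_cm = tr.intercapillary_length * 1e-4
    k_diff = (tr.diffusivity_scale / npp.diameter) / (len_cm * len_cm)
    k_el_np = npp.clearance_rate + npp.degradation_rate
    d_np = npp.degradation_rate
    w_am = npp.payload_mass_fraction
    f_c, f_t = tr.uptake_fraction_cancer, 1.0 - tr.uptake_fraction_cancer
    fcyt_c, fcyt_t = tr.cytosol_fraction_cancer, tr.cytosol_fraction_tam

    g0 = mir.production_rate
    d_m = mir.degradation_rate
    k_exo = mir.exosomal_transfer_rate
    m_eq = mir.equilibrium
    g0_c = g0 - k_exo * m_eq           # keeps both cell types at the same equilibrium
    a_am, ec_am, d_am = mir.antagonist_gain, mir.antagonist_potency, mir.antagonist_degradation
    k_m = mir.potency
    a_ml = mir.proliferation_gain

    g_l, d_l, k_ml = cp.pdl1_production, cp.pdl1_degradation, cp.pdl1_repression_constant
    g_p = cp.pd1_turnover * cp.pd1_equilibrium
    d_p = cp.pd1_turnover
    kd_rl, kd_a, kd_p = cp.kd_pd1_pdl1, cp.kd_atezolizumab, cp.kd_pembrolizumab
    k_inh, d_t = cp.inhibition_constant, cp.immune_kill_max
    kcl_i, p_i, dint_i = cp.ici_clearance_rate, cp.ici_permeability, cp.ici_interstitial_degradation
    # mg/mL -> pM: (mg/mL == g/L); / MW (g/mol) -> mol/L; * 1e12 -> pM
    to_pm = 1e12 / cp.ici_molecular_weight

    kcl_c, p_c, dint_c = ch.clearance_rate, ch.tumor_permeability, ch.interstitial_degradation
    d_chemo_max, ic50, r_c = ch.kill_max, ch.base_ic50, ch.resistance_gain

    gamma, cap = gr.intrinsic_growth_rate, gr.carrying_capacity

    def rhs(t, y):
        np_pl, np_int = y[0], y[1]
        am_c, am_t = y[2], y[3]
        m_c, m_t = y[4], y[5]
        l_c, l_t, pd1 = y[6], y[7], y[8]
        c_pl, c_int = y[9], y[10]
        a_pl, a_int = y[11], y[12]
        e_pl, e_int = y[13], y[14]
        v = y[15]
        if v < 1e-12:
            v = 1e-12
        v_int = phi_int * v

        # -- nanoparticle transport --
        j_np = p_np * s * v * (np_pl / v_pl - np_int / v_int)
        uptake = k_diff * np_int
        d_np_pl = -k_el_np * np_pl - j_np
        d_np_int = j_np - d_np * np_int - uptake

        # -- intracellular anti-miR-155 --
        d_am_c = f_c * uptake * w_am / (fcyt_c * v) - d_am * am_c
        d_am_t = f_t * uptake * w_am / (fcyt_t * v) - d_am * am_t

        # -- miR-155 --
        am_c_pos = am_c if am_c > 0.0 else 0.0
        am_t_pos = am_t if am_t > 0.0 else 0.0
        mult_c = 1.0 + a_am * am_c_pos / (ec_am + am_c_pos)
        mult_t = 1.0 + a_am * am_t_pos / (ec_am + am_t_pos)
        d_m_c = g0_c - d_m * mult_c * m_c + k_exo * m_t
        d_m_t = g0 - d_m * mult_t * m_t

        # -- checkpoint molecules --
        m_c_pos = m_c if m_c > 0.0 else 0.0
        m_t_pos = m_t if m_t > 0.0 else 0.0
        d_l_c = g_l * k_ml / (k_ml + m_c_pos) - d_l * l_c
        d_l_t = g_l * k_ml / (k_ml + m_t_pos) - d_l * l_t
        d_pd1 = g_p - d_p * pd1

        # -- cisplatin PK --
        j_c = p_c * s * v * (c_pl / v_pl - c_int / v_int)
        d_c_pl = -kcl_c * c_pl - j_c
        d_c_int = j_c - dint_c * c_int

        # -- antibody PK --
        j_a = p_i * s * v * (a_pl / v_pl - a_int / v_int)
        d_a_pl = -kcl_i * a_pl - j_a
        d_a_int = j_a - dint_i * a_int
        j_e = p_i * s * v * (e_pl / v_pl - e_int / v_int)
        d_e_pl = -kcl_i * e_pl - j_e
        d_e_int = j_e - dint_i * e_int

        # -- pharmacodynamics on tumor volume --
        phi = 1.0 + (a_ml - 1.0) * m_c_pos / (k_m + m_c_pos)
        c_conc = (c_int / v_int) if c_int > 0.0 else 0.0
        ic50_eff = ic50 * (1.0 + r_c * m_c_pos / (k_m + m_c_pos))
        d_chemo = d_chemo_max * c_conc / (ic50_eff + c_conc)
        l_tot = (l_c if l_c > 0.0 else 0.0) + (l_t if l_t > 0.0 else 0.0)
        psi = checkpoint_occupancy(
            l_tot, pd1 if pd1 > 0.0 else 0.0,
            (a_int / v_int) * to_pm if a_int > 0.0 else 0.0,
            (e_int / v_int) * to_pm if e_int > 0.0 else 0.0,
            kd_pd1_pdl1=kd_rl, kd_atezolizumab=kd_a,
            kd_pembrolizumab=kd_p, inhibition_constant=k_inh,
        )
        d_v = gamma * phi * v * (1.0 - v / cap) - (d_chemo + d_t * psi) * v

        return (
            d_np_pl, d_np_int, d_am_c, d_am_t, d_m_c, d_m_t,
            d_l_c, d_l_t, d_pd1, d_c_pl, d_c_int,
            d_a_pl, d_a_int, d_e_pl, d_e_int, d_v,
        )

    return rhs


def initial_state(params: ModelParameters, v0: float) -> np.ndarray:
    """Drug-free initial condition with molecular species at equilibrium."""
    eq = molecular_equilibrium(params)
    y0 = np.zeros(len(STATE_NAMES))
    y0[4] = y0[5] = eq["mir155"]
    y0[6] = y0[7] = eq["pdl1_per_type"]
    y0[8] = eq["pd1"]
    y0[15] = v0
    return y0


def simulate(
    params: ModelParameters,
    regimen: Regimen,
    t_grid: np.ndarray | float | None = None,
    v0: float | None = None,
    *,
    rtol: float = 1e-7,
    atol: float | None = None,
    arm: str = "",
    patient_id: str = "",
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model under a dosing regimen.

    Parameters
    ----------
    params
        Validated model parameters.
    regimen
        Doses and observation window.  Simulation time starts at 0; doses
        land at ``treatment_start + event.time``.
    t_grid
        Output sampling grid (days).  A scalar is interpreted as a grid step;
        default is daily sampling of ``[0, follow_up_end]``.
    v0
        Tumor volume at t = 0 (defaults to the packaged preclinical
        inoculum for mice and to a single founding cell otherwise).

    Dosing is handled as an instantaneous plasma-mass increment
    (``dose [mg/kg] x body weight``) with the integrator restarted at each
    event; a dose at t = 0 is applied before the first step and simultaneous
    same-drug events are summed.  Sub-tolerance negative excursions are
    clipped to zero; excursions beyond ``NEGATIVITY_TOLERANCE`` raise
    :class:`NumericalIntegrityError`.
    """
    from .dosing import PRECLINICAL_V0

    rhs = build_rhs(params)
    t_end = regimen.follow_up_end
    if t_grid is None or np.isscalar(t_grid):
        step = 1.0 if t_grid is None else float(t_grid)
        t_grid = np.arange(0.0, t_end + 1e-9, step)
        if t_end - t_grid[-1] > 1e-9:
            t_grid = np.append(t_grid, t_end)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] < 0 or t_grid[-1] > t_end + 1e-9:
        raise ConfigurationError("t_grid must lie within [0, follow_up_end]")

    if v0 is None:
        v0 = PRECLINICAL_V0 if params.species.name == "mouse" else params.growth.initial_cell_volume
    y = initial_state(params, v0)
    bw = params.species.body_weight
    if atol is None:
        atol_vec = np.full(len(STATE_NAMES), 1e-12)
        atol_vec[15] = 1e-12
    else:
        atol_vec = np.full(len(STATE_NAMES), atol)

    events = regimen.absolute_events()
    breakpoints = sorted({t for t, _, _ in events if 0.0 <= t <= t_end} | {0.0, t_end})
    out_t: list[np.ndarray] = []
    out_y: list[np.ndarray] = []
    t_now = 0.0
    for t0, t1 in zip(breakpoints, breakpoints[1:] + [None]):
        for t_e, drug, dose in events:
            if abs(t_e - t0) < 1e-12:
                y[_PLASMA_STATE[drug]] += dose * bw
        if t1 is None:
            break
        seg_mask = (t_grid >= t0 - 1e-12) & (t_grid <= t1 + 1e-12) if t0 == 0.0 else \
                   (t_grid > t0 + 1e-12) & (t_grid <= t1 + 1e-12)
        t_eval = t_grid[seg_mask]
        sol = solve_ivp(
            rhs, (t0, t1), y, method=method, t_eval=t_eval if t_eval.size else None,
            rtol=rtol, atol=atol_vec, dense_output=False,
        )
        if not sol.success:
            raise SimulationError(
                f"integration failed in [{t0:g}, {t1:g}]: {sol.message}",
                last_time=float(sol.t[-1]) if sol.t.size else t0,
            )
        if t_eval.size:
            out_t.append(sol.t)
            out_y.append(sol.y.T)
        y = sol.y[:, -1].copy()
        t_now = t1

    states = np.vstack(out_y) if out_y else np.empty((0, len(STATE_NAMES)))
    times = np.concatenate(out_t) if out_t else np.empty(0)
    # de-duplicate grid points that coincide with breakpoints
    keep = np.concatenate([[True], np.diff(times) > 1e-12]) if times.size else np.empty(0, bool)
    times, states = times[keep], states[keep]

    worst = states.min(initial=0.0)
    if worst < NEGATIVITY_TOLERANCE:
        raise NumericalIntegrityError(
            f"state excursion to {worst:.3e} exceeds the negativity tolerance"
        )
    states = np.clip(states, 0.0, None)
    if np.any(states[:, 15] <= 0.0):
        raise NumericalIntegrityError("tumor volume reached zero")
    return Trajectory(time=times, states=states, params=params, regimen=regimen,
                      arm=arm, patient_id=patient_id)


def percent_injected_dose(traj: Trajectory, event=None) -> pd.DataFrame:
    """Interstitial NP payload as percent of an injected dose (%ID).

    For the given ``DoseEvent`` (default: the first NP event of the
    trajectory's regimen) returns a frame of ``time_day``/``percent_id`` over
    that event's window (event time until the next NP event or follow-up
    end).  Values lie in [0, 100].
    """
    reg = traj.regimen
    np_events = [e for e in reg.events if e.drug == "anti_mir155_np"]
    if event is None:
        if not np_events:
            raise UndefinedMetricError("regimen has no nanoparticle dose events")
        event = np_events[0]
    if event.dose <= 0:
        raise UndefinedMetricError("%ID is undefined for a zero dose")
    t_abs = reg.treatment_start + event.time
    later = [reg.treatment_start + e.time for e in np_events
             if e.time > event.time + 1e-12]
    t_stop = min(later) if later else reg.follow_up_end
    mask = (traj.time >= t_abs - 1e-9) & (traj.time <= t_stop + 1e-9)
    injected = event.dose * traj.params.species.body_weight
    pid = 100.0 * traj["np_interstitium"][mask] / injected
    return pd.DataFrame({"time_day": traj.time[mask], "percent_id": pid})
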