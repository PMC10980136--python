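"""Treatment-response endpoints: TGI, spherical diameter, RECIST 1.1
categories and time to progression.

The model tracks a single spherical lesion; RECIST 1.1 is applied to its
equivalent diameter.  Progressive disease (PD) requires a >= 20% diameter
increase over the nadir (the smallest diameter recorded since treatment
start, baseline included) with an absolute minimum increase of 0.5 cm;
partial response (PR) is a >= 30% decrease from baseline; complete response
(CR) is disappearance below a 1 mm detectability floor.  Time to progression
(TTP) is the first PD assessment, reported in months (30.44 days/month).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dosing import DAYS_PER_MONTH
from .errors import ConfigurationError, UndefinedMetricError
from .model import Trajectory

__all__ = [
    "ResponseAssessment",
    "tumor_growth_inhibition",
    "diameter_from_volume",
    "volume_from_diameter",
    "recist_stream",
    "time_to_progression",
    "CR_DIAMETER_FLOOR",
    "PD_RELATIVE_INCREASE",
    "PD_ABSOLUTE_INCREASE",
    "PR_RELATIVE_DECREASE",
]

#: RECIST 1.1 constants (cm / fractions)
CR_DIAMETER_FLOOR = 0.1
PD_RELATIVE_INCREASE = 0.20
PD_ABSOLUTE_INCREASE = 0.5
PR_RELATIVE_DECREASE = 0.30


@dataclass
class ResponseAssessment:
    """Endpoint bundle for one subject."""

    tgi_percent: float | None
    diameter_change_percent: float
    best_response: str
    ttp_months: float | None      # None when censored
    censored: bool


def tumor_growth_inhibition(treated: Trajectory, control: Trajectory,
                            t: float | None = None) -> float:
    """Percent inhibition of tumor growth relative to the control arm.

    ``TGI(t) = 100 * [(V_ctrl(t) - V0) - (V_trt(t) - V0)] / (V_ctrl(t) - V0)``
    with ``V0`` the shared volume at treatment start.  Defined only while the
    control arm has grown.  ``t`` defaults to the treated arm's end of
    treatment.
    """
    if t is None:
        t = treated.regimen.end_of_treatment
    ts = treated.regimen.treatment_start
    v0_t = treated.volume_at(ts)
    v0_c = control.volume_at(control.regimen.treatment_start)
    if abs(v0_t - v0_c) > 1e-6 * max(v0_t, v0_c, 1e-12):
        raise ConfigurationError(
            "treated and control trajectories do not share a baseline volume"
        )
    denom = control.volume_at(t) - v0_c
    if denom <= 0:
        raise UndefinedMetricError("TGI undefined: control arm has not grown")
    return 100.0 * (denom - (treated.volume_at(t) - v0_t)) / denom


def diameter_from_volume(volume):
    """Spherical-equivalent diameter ``d = (6V/pi)^(1/3)`` (cm from cm^3)."""
    v = np.asarray(volume, dtype=float)
    if np.any(v < 0):
        raise ConfigurationError("volume must be >= 0")
    out = np.cbrt(6.0 * v / math.pi)
    return float(out) if np.isscalar(volume) else out


def volume_from_diameter(diameter):
    d = np.asarray(diameter, dtype=float)
    out = math.pi / 6.0 * d ** 3
    return float(out) if np.isscalar(diameter) else out


def recist_stream(traj: Trajectory, assessment_grid=None) -> pd.DataFrame:
    """Per-assessment RECIST 1.1 categories for one trajectory.

    Assessments default to every trajectory grid point from treatment start
    onward (continuous in-silico monitoring); pass ``assessment_grid`` (days,
    subset of the trajectory span) for trial-realistic cadences.  Returns a
    frame with time, diameter, nadir, baseline-change percent and category.
    """
    ts = traj.regimen.treatment_start
    if assessment_grid is None:
        mask = traj.time >= ts - 1e-9
        times = traj.time[mask]
        diam = traj.diameter[mask]
    else:
        times = np.asarray(assessment_grid, dtype=float)
        if times.size == 0:
            raise ConfigurationError("assessment grid is empty")
        if times.min() < ts - 1e-9 or times.max() > traj.time.max() + 1e-9:
            raise ConfigurationError("assessment grid outside the trajectory span")
        diam = np.interp(times, traj.time, traj.diameter)

    baseline = float(np.interp(ts, traj.time, traj.diameter))
    nadir = np.minimum.accumulate(np.minimum(diam, baseline))
    pd_flag = (diam >= nadir * (1.0 + PD_RELATIVE_INCREASE)) & \
              (diam - nadir >= PD_ABSOLUTE_INCREASE)
    cr_flag = diam < CR_DIAMETER_FLOOR
    pr_flag = diam <= baseline * (1.0 - PR_RELATIVE_DECREASE)
    category = np.where(pd_flag, "PD",
                np.where(cr_flag, "CR", np.where(pr_flag, "PR", "SD")))
    return pd.DataFrame({
        "time_day": times,
        "diameter_cm": diam,
        "nadir_cm": nadir,
        "change_from_baseline_percent": 100.0 * (diam - baseline) / baseline,
        "category": category,
    })


def time_to_progression(traj: Trajectory, follow_up_end: float | None = None,
                        assessment_grid=None) -> tuple[float | None, bool]:
    """First progressive-disease assessment, months from treatment start.

    Returns ``(ttp_months, censored)``; censored subjects carry the follow-up
    end as their observation time.
    """
    stream = recist_stream(traj, assessment_grid)
    if follow_up_end is None:
        follow_up_end = traj.regimen.follow_up_end
    within = stream[stream.time_day <= follow_up_end + 1e-9]
    hits = within[within.category == "PD"]
    ts = traj.regimen.treatment_start
    if len(hits):
        return float((hits.time_day.iloc[0] - ts) / DAYS_PER_MONTH), False
    return None, True


def assess(traj: Trajectory, control: Trajectory | None = None) -> ResponseAssessment:
    """Full endpoint bundle: end-of-treatment TGI (when a control is given),
    end-of-treatment diameter change, best overall response and TTP."""
    stream = recist_stream(traj)
    eot = traj.regimen.end_of_treatment
    row = stream.iloc[(stream.time_day - eot).abs().argmin()]
    ttp, censored = time_to_progression(traj)
    order = {"CR": 0, "PR": 1, "SD": 2, "PD": 3}
    best = min(stream.category, key=lambda c: order[c])
    tgi = None
    if control is not None:
        tgi = tumor_growth_inhibition(traj, control, eot)
    return ResponseAssessment(
        tgi_percent=tgi,
        diameter_change_percent=float(row.change_from_baseline_percent),
        best_response=best,
        ttp_months=ttp,
        censored=censored,
    )
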