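"""Virtual-trial execution: simulate a cohort under treatment arms and
collect per-patient progression endpoints."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import Cohort
from .dosing import Regimen, clinical_regimen
from .errors import SimulationError
from .model import Trajectory, simulate
from .response import time_to_progression

__all__ = ["simulate_patient", "run_arm", "monotherapy_trial"]


def simulate_patient(patient, regimen: Regimen, arm: str = "", **simulate_kw) -> Trajectory:
    """Simulate one virtual patient from treatment start (t = 0) at their
    accepted baseline tumor volume."""
    return simulate(
        patient.params, regimen, v0=patient.baseline_volume,
        arm=arm, patient_id=patient.patient_id, **simulate_kw,
    )


def run_arm(
    cohort: Cohort,
    regimen: Regimen,
    arm: str,
    doses: dict[str, float] | None = None,
    collect_mean_volume: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Run one arm over a cohort; returns the tidy endpoint table
    (patient_id, arm, per-drug doses, ttp_months, event, baseline).

    Per-patient failures are isolated and recorded with ``event = False`` and
    ``failed = True`` rather than aborting the arm.  With
    ``collect_mean_volume`` the cohort-mean tumor-volume trajectory is
    returned alongside (used for cohort-level TGI).
    """
    doses = doses or {}
    rows = []
    vol_sum = None
    vol_n = 0
    t_axis = None
    for patient in cohort:
        row = {
            "patient_id": patient.patient_id,
            "arm": arm,
            "baseline_diameter_cm": patient.baseline_diameter,
            "failed": False,
        }
        for drug, dose in doses.items():
            row[f"dose_{drug}"] = dose
        try:
            traj = simulate_patient(patient, regimen, arm=arm)
            ttp, censored = time_to_progression(traj)
            horizon = (regimen.follow_up_end - regimen.treatment_start) / 30.44
            row["ttp_months"] = ttp if not censored else horizon
            row["event"] = not censored
            if collect_mean_volume:
                if vol_sum is None:
                    t_axis = traj.time
                    vol_sum = np.zeros_like(traj.volume)
                vol_sum += np.interp(t_axis, traj.time, traj.volume)
                vol_n += 1
        except SimulationError as exc:
            row["ttp_months"] = np.nan
            row["event"] = False
            row["failed"] = True
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    if collect_mean_volume:
        mean = pd.DataFrame({"time_day": t_axis, "mean_volume_cm3": vol_sum / max(vol_n, 1)})
        return table, mean
    return table


def monotherapy_trial(
    cohort: Cohort,
    drug: str = "anti_mir155_np",
    doses=(0.026, 0.25, 2.5),
    schedule: str = "Q3W",
    follow_up_months: float = 36.0,
) -> pd.DataFrame:
    """Dose-ladder monotherapy trial (control arm included)."""
    frames = [run_arm(
        cohort, clinical_regimen({}, schedule=schedule, follow_up_months=follow_up_months),
        arm="control",
    )]
    for dose in doses:
        reg = clinical_regimen({drug: dose}, schedule=schedule,
                               follow_up_months=follow_up_months)
        frames.append(run_arm(cohort, reg, arm=f"{drug}@{dose:g}", doses={drug: dose}))
    return pd.concat(frames, ignore_index=True)
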