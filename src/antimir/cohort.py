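"""Synthetic-data engine: the virtual patient cohort and paper-like
preclinical growth datasets.

The virtual cohort emulates a stage-IA NSCLC population (Allen-style
plausible-patient sampling reduced to the single published acceptance
criterion): biological parameters receive independent lognormal
multiplicative perturbations, the untreated tumor is grown from a single
founding cell to the 124-week treatment start, and the proposal is accepted
iff the baseline spherical diameter lies in [1.0, 2.68] cm (volumes of
roughly 0.52-10 cm^3).  Generation is fully seed-deterministic.

The preclinical generator produces mouse xenograft tumor-growth tables
(time, volume, arm, replicate) under the packaged treatment protocols with
lognormal replicate noise, standing in for the digitized literature datasets
the original calibration used, which are not redistributable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import GrowthDataset
from .dosing import (
    HUMAN_INCEPTION_TO_TREATMENT,
    PRECLINICAL_ARMS,
    PRECLINICAL_V0,
    preclinical_regimen,
)
from .errors import ConfigurationError
from .model import simulate, untreated_volume
from .parameters import ModelParameters

__all__ = [
    "VirtualPatient",
    "Cohort",
    "sample_cohort",
    "synth_preclinical_dataset",
    "DEFAULT_SAMPLED_PARAMETERS",
    "DEFAULT_SIGMA_LOG",
    "BASELINE_DIAMETER_RANGE",
]

#: parameters perturbed across patients: the GSA-sensitive biological set
DEFAULT_SAMPLED_PARAMETERS = (
    "growth.intrinsic_growth_rate",
    "mirna.proliferation_gain",
    "mirna.production_rate",
    "mirna.degradation_rate",
    "mirna.potency",
    "mirna.antagonist_gain",
    "mirna.antagonist_degradation",
    "mirna.antagonist_potency",
    "transport.vascular_surface_density",
    "checkpoint.immune_kill_max",
)

#: sigma of the lognormal multipliers; ~95% of proposals within +-30%
DEFAULT_SIGMA_LOG = math.log(1.3) / 1.96

#: stage-IA acceptance window on baseline spherical diameter, cm
BASELINE_DIAMETER_RANGE = (1.0, 2.68)


@dataclass
class VirtualPatient:
    patient_id: str
    multipliers: dict[str, float]
    baseline_volume: float      # cm^3 at treatment start
    baseline_diameter: float    # cm
    base_params: ModelParameters = field(repr=False, default=None)

    @property
    def params(self) -> ModelParameters:
        return self.base_params.with_multipliers(self.multipliers)

    def to_record(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "multipliers": self.multipliers,
            "baseline_volume": self.baseline_volume,
            "baseline_diameter": self.baseline_diameter,
        }


@dataclass
class Cohort:
    patients: list[VirtualPatient]
    seed: int
    n_proposed: int
    base_params: ModelParameters

    def __len__(self):
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    @property
    def acceptance_rate(self) -> float:
        return len(self.patients) / self.n_proposed if self.n_proposed else float("nan")

    def baseline_diameters(self) -> np.ndarray:
        return np.array([p.baseline_diameter for p in self.patients])

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            header = {"seed": self.seed, "n_proposed": self.n_proposed,
                      "base_params": self.base_params.to_dict()}
            fh.write(json.dumps({"cohort_meta": header}, sort_keys=True) + "\n")
            for p in self.patients:
                fh.write(json.dumps(p.to_record(), sort_keys=True) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "Cohort":
        with open(path) as fh:
            meta = json.loads(fh.readline())["cohort_meta"]
            base = ModelParameters.from_dict(meta["base_params"])
            patients = []
            for line in fh:
                rec = json.loads(line)
                patients.append(VirtualPatient(
                    patient_id=rec["patient_id"],
                    multipliers=rec["multipliers"],
                    baseline_volume=rec["baseline_volume"],
                    baseline_diameter=rec["baseline_diameter"],
                    base_params=base,
                ))
        return cls(patients=patients, seed=meta["seed"],
                   n_proposed=meta["n_proposed"], base_params=base)


def sample_cohort(
    base_params_human: ModelParameters,
    n: int = 1000,
    sampling: dict[str, float] | None = None,
    seed: int = 0,
    *,
    inception_to_treatment: float = HUMAN_INCEPTION_TO_TREATMENT,
    max_proposals: int = 100_000,
) -> Cohort:
    """Accept-reject sampling of ``n`` virtual patients.

    ``sampling`` maps parameter names to lognormal sigmas (defaults:
    :data:`DEFAULT_SAMPLED_PARAMETERS` at :data:`DEFAULT_SIGMA_LOG`).  Each
    proposal perturbs the base human parameters, grows the untreated tumor
    (closed-form logistic solution of the drug-free model) from a single
    cell to the treatment start, and is accepted iff the baseline diameter
    falls within the stage-IA window.
    """
    if n < 1:
        raise ConfigurationError("cohort size must be >= 1")
    if sampling is None:
        sampling = {name: DEFAULT_SIGMA_LOG for name in DEFAULT_SAMPLED_PARAMETERS}
    for name, sig in sampling.items():
        base_params_human.get(name)
        if sig < 0:
            raise ConfigurationError(f"negative sampling sigma for '{name}'")
    names = sorted(sampling)
    sigmas = np.array([sampling[k] for k in names])

    rng = np.random.default_rng(seed)
    d_lo, d_hi = BASELINE_DIAMETER_RANGE
    patients: list[VirtualPatient] = []
    proposed = 0
    while len(patients) < n:
        if proposed >= max_proposals:
            raise ConfigurationError(
                f"acceptance rate {len(patients)}/{proposed} too low; "
                "widen the growth-rate prior or the acceptance window"
            )
        proposed += 1
        mult = dict(zip(names, np.exp(rng.normal(0.0, sigmas))))
        try:
            params = base_params_human.with_multipliers(mult)
            v = float(untreated_volume(params, inception_to_treatment))
        except ConfigurationError:
            continue    # implausible proposal (e.g. immune kill exceeds growth)
        d = (6.0 * v / math.pi) ** (1.0 / 3.0)
        if d_lo <= d <= d_hi:
            patients.append(VirtualPatient(
                patient_id=f"vp{len(patients):04d}",
                multipliers=mult,
                baseline_volume=v,
                baseline_diameter=d,
                base_params=base_params_human,
            ))
        if proposed >= 1000 and len(patients) < 0.01 * proposed:
            raise ConfigurationError(
                f"acceptance rate {len(patients)}/{proposed} below 1%; "
                "widen the growth-rate prior"
            )
    return Cohort(patients=patients, seed=seed, n_proposed=proposed,
                  base_params=base_params_human)


def synth_preclinical_dataset(
    true_params_mouse: ModelParameters,
    arms: tuple[str, ...] | None = None,
    noise_sigma: float = 0.05,
    replicates: int = 8,
    seed: int = 0,
    v0: float = PRECLINICAL_V0,
) -> list[GrowthDataset]:
    """Paper-like mouse growth tables: model means under the packaged
    protocols times lognormal replicate noise at twice-weekly caliper times.

    Default arms mirror the pooled calibration design: five treatments and
    two control arms (the second control re-labelled, emulating the separate
    control groups of the source studies).
    """
    if noise_sigma < 0:
        raise ConfigurationError("noise sigma must be >= 0")
    if replicates < 1:
        raise ConfigurationError("at least one replicate is required")
    if arms is None:
        arms = PRECLINICAL_ARMS + ("control_b",)
    rng = np.random.default_rng(seed)
    datasets = []
    for arm in arms:
        proto = "control" if arm.startswith("control") else arm
        reg = preclinical_regimen(proto)
        times = np.arange(reg.treatment_start, reg.follow_up_end + 1e-9, 3.5)
        traj = simulate(true_params_mouse, reg,
                        t_grid=np.unique(np.concatenate([[0.0], times])), v0=v0)
        mean_mm3 = np.array([traj.volume_at(t) for t in times]) * 1000.0
        rows = []
        for rep in range(replicates):
            noise = np.exp(rng.normal(0.0, noise_sigma, size=len(times))) if noise_sigma else 1.0
            rows.append(pd.DataFrame({
                "time_day": times,
                "volume_mm3": mean_mm3 * noise,
                "replicate": rep,
            }))
        datasets.append(GrowthDataset(
            arm=arm, regimen=reg,
            observations=pd.concat(rows, ignore_index=True), v0=v0,
        ))
    return datasets


def datasets_to_csv(datasets: list[GrowthDataset], path) -> None:
    """Write a list of growth datasets as one tidy CSV."""
    frames = []
    for ds in datasets:
        f = ds.observations.copy()
        f["arm"] = ds.arm
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
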