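"""Local and global sensitivity analysis of tumor growth inhibition.

LSA sweeps one parameter at a time over a +-50% multiplier range and records
TGI under the reference anti-miR-155 regimen.  GSA perturbs many parameters
simultaneously via Latin Hypercube sampling; sensitivity indices (SI) are
the standardized coefficients of a multivariate linear regression of TGI on
the multipliers, replicated over re-sampled designs, and parameters are
rank-ordered into homogeneous groups by one-way ANOVA with Tukey's HSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import qmc
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .dosing import clinical_regimen
from .errors import ConfigurationError, SimulationError, UndefinedMetricError
from .model import simulate, untreated_volume
from .parameters import ModelParameters
from .response import tumor_growth_inhibition
from .dosing import HUMAN_INCEPTION_TO_TREATMENT

__all__ = [
    "SensitivityReport",
    "local_sensitivity",
    "global_sensitivity",
    "GSA_DEFAULT_PARAMETERS",
    "REFERENCE_DOSE",
]

#: reference regimen for sensitivity endpoints: the human-equivalent dose Q3W
REFERENCE_DOSE = 0.026

#: the 28-parameter default GSA set (biology, transport, drug effects)
GSA_DEFAULT_PARAMETERS = (
    "growth.intrinsic_growth_rate",
    "growth.carrying_capacity",
    "mirna.proliferation_gain",
    "mirna.production_rate",
    "mirna.degradation_rate",
    "mirna.potency",
    "mirna.antagonist_gain",
    "mirna.antagonist_potency",
    "mirna.antagonist_degradation",
    "mirna.exosomal_transfer_rate",
    "nanoparticle.diameter",
    "nanoparticle.degradation_rate",
    "nanoparticle.clearance_rate",
    "nanoparticle.vascular_permeability_ref",
    "transport.vascular_surface_density",
    "transport.intercapillary_length",
    "transport.diffusivity_scale",
    "transport.uptake_fraction_cancer",
    "transport.cytosol_fraction_cancer",
    "checkpoint.pdl1_production",
    "checkpoint.pdl1_degradation",
    "checkpoint.pdl1_repression_constant",
    "checkpoint.kd_pd1_pdl1",
    "checkpoint.immune_kill_max",
    "checkpoint.inhibition_constant",
    "chemo.kill_max",
    "chemo.base_ic50",
    "chemo.resistance_gain",
)


def _reference_tgi(params: ModelParameters, dose: float, baseline_volume: float | None = None):
    """End-of-treatment TGI of the reference Q3W anti-miR-155 regimen for a
    given parameter set (its own control arm is simulated alongside).

    Sensitivity analyses pass the unperturbed patient's baseline volume so
    that perturbations act on treatment dynamics from a common diagnosed
    tumor rather than re-growing the baseline itself."""
    if baseline_volume is None:
        baseline_volume = float(untreated_volume(params, HUMAN_INCEPTION_TO_TREATMENT))
    eot_months = 190.0 / 30.44
    control = simulate(params, clinical_regimen({}, follow_up_months=eot_months),
                       v0=baseline_volume)
    reg = clinical_regimen({"anti_mir155_np": dose}, follow_up_months=eot_months)
    treated = simulate(params, reg, v0=baseline_volume)
    return tumor_growth_inhibition(treated, control, reg.end_of_treatment)


@dataclass
class SensitivityReport:
    """GSA output: SI samples, ANOVA/Tukey ranking, and baseline TGI."""

    si_samples: pd.DataFrame          # columns: parameter, replicate, si
    ranking: pd.DataFrame             # parameter, mean_si, se_si, rank, group
    baseline_tgi: float
    anova_f: float
    anova_p: float
    n_samples: int
    n_replicates: int
    seed: int
    lsa_curves: dict[str, pd.DataFrame] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"Global sensitivity analysis: {self.ranking.shape[0]} parameters, "
            f"{self.n_samples} LHS samples x {self.n_replicates} replicates",
            f"baseline TGI {self.baseline_tgi:.2f}%   one-way ANOVA "
            f"F = {self.anova_f:.1f}, p = {self.anova_p:.3g}",
            f"{'parameter':<40}{'SI':>9}{'SE':>8}  group",
        ]
        for _, row in self.ranking.iterrows():
            lines.append(f"{row.parameter:<40}{row.mean_si:>9.3f}{row.se_si:>8.3f}  {row.group}")
        return "\n".join(lines)


def local_sensitivity(
    params: ModelParameters,
    name: str,
    span: float = 0.5,
    n_points: int = 11,
    dose: float = REFERENCE_DOSE,
) -> pd.DataFrame:
    """One-at-a-time sweep: TGI versus multiplier in [1-span, 1+span].

    Simulation failures at individual grid points are flagged (NaN TGI,
    ``failed`` column) and the sweep continues.
    """
    if n_points < 3:
        raise ConfigurationError("n_points must be >= 3")
    if params.get(name) <= 0:
        raise ConfigurationError(f"'{name}' must be positive at baseline for a sweep")
    base_v0 = float(untreated_volume(params, HUMAN_INCEPTION_TO_TREATMENT))
    rows = []
    for mult in np.linspace(1.0 - span, 1.0 + span, n_points):
        row = {"multiplier": float(mult), "failed": False}
        try:
            row["tgi_percent"] = _reference_tgi(
                params.with_multipliers({name: float(mult)}), dose, base_v0)
        except (SimulationError, ConfigurationError, UndefinedMetricError):
            row["tgi_percent"] = np.nan
            row["failed"] = True
        rows.append(row)
    out = pd.DataFrame(rows)
    out.insert(0, "parameter", name)
    return out


def _compact_letters(names: list[str], means: dict[str, float], tukey) -> dict[str, str]:
    """Greedy compact-letter display from a Tukey HSD result: parameters not
    significantly different share a letter; ordering by |mean SI|."""
    reject: dict[frozenset, bool] = {}
    res = tukey.summary().data[1:]
    for row in res:
        reject[frozenset((str(row[0]), str(row[1])))] = bool(row[6])
    ordered = sorted(names, key=lambda p: -abs(means[p]))
    groups: list[list[str]] = []
    for p in ordered:
        placed = False
        for g in groups:
            if all(not reject.get(frozenset((p, q)), False) for q in g):
                g.append(p)
                placed = True
                break
        if not placed:
            groups.append([p])
    letters = {}
    for gi, g in enumerate(groups):
        letter = chr(ord("a") + gi) if gi < 26 else f"g{gi}"
        for p in g:
            letters[p] = letters.get(p, "") + letter
    return letters


def global_sensitivity(
    params: ModelParameters,
    names: tuple[str, ...] | None = None,
    n_samples: int = 500,
    n_replicates: int = 20,
    seed: int = 155,
    span: float = 0.5,
    dose: float = REFERENCE_DOSE,
    response=None,
) -> SensitivityReport:
    """Regression-based GSA of TGI with ANOVA/Tukey parameter ranking.

    Each replicate draws a fresh LHS design of multipliers in
    ``[1-span, 1+span]``, simulates TGI per sample, standardizes inputs and
    output, and takes OLS coefficients as that replicate's SI vector.
    Deterministic for a fixed seed.  ``response`` replaces the default
    reference-regimen TGI with a custom ``f(perturbed_params) -> float``
    endpoint.
    """
    names = GSA_DEFAULT_PARAMETERS if names is None else tuple(names)
    if not names:
        raise ConfigurationError("GSA parameter set may not be empty")
    for n in names:
        params.get(n)
    if n_samples < 10 * len(names):
        raise ConfigurationError(
            f"n_samples ({n_samples}) should be >= 10x the number of parameters "
            f"({len(names)}); the regression design would be poorly conditioned"
        )
    if response is None:
        base_v0 = float(untreated_volume(params, HUMAN_INCEPTION_TO_TREATMENT))
        response = lambda p: _reference_tgi(p, dose, base_v0)  # noqa: E731
    baseline = response(params)

    rng = np.random.default_rng(seed)
    si_rows = []
    for rep in range(n_replicates):
        sampler = qmc.LatinHypercube(d=len(names), seed=int(rng.integers(2**31 - 1)))
        mult = 1.0 - span + 2.0 * span * sampler.random(n_samples)
        y = np.full(n_samples, np.nan)
        for i in range(n_samples):
            try:
                y[i] = response(params.with_multipliers(dict(zip(names, mult[i]))))
            except (SimulationError, ConfigurationError, UndefinedMetricError):
                pass
        ok = np.isfinite(y)
        if ok.sum() <= len(names) + 1:
            raise ConfigurationError(
                "too few successful simulations for the SI regression; "
                "increase n_samples"
            )
        x = (mult[ok] - mult[ok].mean(0)) / mult[ok].std(0)
        yy = (y[ok] - y[ok].mean()) / y[ok].std()
        fit = sm.OLS(yy, sm.add_constant(x)).fit()
        for name, coef in zip(names, fit.params[1:]):
            si_rows.append({"parameter": name, "replicate": rep, "si": float(coef)})
    si = pd.DataFrame(si_rows)

    anova_fit = sm.OLS.from_formula("si ~ C(parameter)", data=si).fit()
    anova = sm.stats.anova_lm(anova_fit, typ=1)
    tukey = pairwise_tukeyhsd(si.si, si.parameter, alpha=0.05)
    means = si.groupby("parameter").si.mean().to_dict()
    ses = si.groupby("parameter").si.sem().to_dict()
    letters = _compact_letters(list(names), means, tukey)
    ranking = pd.DataFrame({
        "parameter": sorted(names, key=lambda p: -abs(means[p])),
    })
    ranking["mean_si"] = ranking.parameter.map(means)
    ranking["se_si"] = ranking.parameter.map(ses)
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    ranking["group"] = ranking.parameter.map(letters)

    return SensitivityReport(
        si_samples=si,
        ranking=ranking,
        baseline_tgi=float(baseline),
        anova_f=float(anova["F"].iloc[0]),
        anova_p=float(anova["PR(>F)"].iloc[0]),
        n_samples=n_samples,
        n_replicates=n_replicates,
        seed=seed,
    )
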