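"""Chou-Talalay median-effect modeling and combination-index screening.

The median-effect equation ``fa/fu = (D/Dm)^m`` (fu = 1 - fa) linearizes to
``log(fa/fu) = m log D - m log Dm``; fitting it to monotherapy dose-effect
data yields the median-effect dose ``Dm`` and slope ``m`` per drug.  For a
combination producing effect ``fa`` at doses ``D_j``, the combination index
for the non-constant-ratio design is

    CI = sum_j D_j / D_x,j(fa),      D_x,j = Dm_j * (fa/(1-fa))^(1/m_j)

with CI < 1 synergism, ~1 additivity, > 1 antagonism.  Effects are TGI
fractions at end of treatment, clipped to the open unit interval as the
median-effect math requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .cohort import Cohort
from .dosing import clinical_regimen
from .errors import ConfigurationError
from .survival import kaplan_meier, median_pfs
from .trial import run_arm

__all__ = [
    "MedianEffectModel",
    "MedianEffectFit",
    "median_effect_fit",
    "required_dose",
    "combination_index",
    "classify_ci",
    "screen_combinations",
    "mine_conditions",
    "CI_CLASSES",
    "FA_CLIP",
]

#: classification thresholds on CI (lower edge inclusive)
CI_CLASSES = (
    (0.0, 0.3, "strong-synergy"),
    (0.3, 0.9, "synergy"),
    (0.9, 1.1, "additive"),
    (1.1, float("inf"), "antagonism"),
)

#: open-interval clip applied to effect fractions before median-effect math
FA_CLIP = (0.001, 0.999)

#: screening dose ranges, mg/kg: 0.01 to the clinical dose (anti-miR-155
#: capped at 2.5 mg/kg, the selected maximum tolerated dose)
DEFAULT_DOSE_RANGES = {
    "anti_mir155_np": (0.01, 2.5),
    "cisplatin": (0.01, 2.04),
    "atezolizumab": (0.01, 17.14),
    "pembrolizumab": (0.01, 2.86),
}


@dataclass
class MedianEffectFit:
    """Median-effect parameterization of one drug's monotherapy response."""

    dm: float           # median-effect dose, mg/kg
    m: float            # slope
    r: float            # correlation of the median-effect plot
    n_points: int
    n_clipped: int = 0

    def fa_at(self, dose: float) -> float:
        ratio = (dose / self.dm) ** self.m
        return ratio / (1.0 + ratio)


class MedianEffectModel:
    """Linear regression of ``log(fa/fu)`` on ``log D``."""

    def __init__(self, doses, effects):
        d = np.asarray(doses, dtype=float)
        fa = np.asarray(effects, dtype=float)
        if d.shape != fa.shape:
            raise ConfigurationError("doses and effects must have equal length")
        ok = np.isfinite(d) & np.isfinite(fa) & (d > 0)
        d, fa = d[ok], fa[ok]
        self.n_clipped = int(np.sum((fa <= FA_CLIP[0]) | (fa >= FA_CLIP[1])))
        fa = np.clip(fa, *FA_CLIP)
        if len(d) < 3:
            raise ConfigurationError("median-effect fit needs >= 3 usable dose points")
        self.doses, self.effects = d, fa

    def fit(self) -> MedianEffectFit:
        x = np.log(self.doses)
        y = np.log(self.effects / (1.0 - self.effects))
        res = stats.linregress(x, y)
        if res.slope <= 0:
            warnings.warn(
                f"non-positive median-effect slope ({res.slope:.3g}); "
                "effects are not increasing with dose"
            )
        m = float(res.slope)
        dm = float(np.exp(-res.intercept / m)) if m != 0 else np.inf
        return MedianEffectFit(dm=dm, m=m, r=float(res.rvalue),
                               n_points=len(self.doses), n_clipped=self.n_clipped)


def median_effect_fit(doses, effects) -> MedianEffectFit:
    return MedianEffectModel(doses, effects).fit()


def required_dose(fit: MedianEffectFit, fa: float) -> float:
    """``D_x = Dm * (fa/(1-fa))^(1/m)``: the monotherapy dose producing fa."""
    if not 0.0 < fa < 1.0:
        raise ConfigurationError("fa must lie strictly in (0, 1)")
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


def combination_index(
    doses: dict[str, float],
    fa: float,
    fits: dict[str, MedianEffectFit],
) -> float:
    """Non-constant-ratio CI for a 2- or 3-drug combination."""
    if not doses:
        raise ConfigurationError("at least one drug dose is required")
    missing = set(doses) - set(fits)
    if missing:
        raise ConfigurationError(f"no median-effect fit for: {sorted(missing)}")
    return float(sum(d / required_dose(fits[drug], fa) for drug, d in doses.items()))


def classify_ci(ci: float) -> str:
    """CI < 0.3 strong synergy; < 0.9 synergy; 0.9-1.1 additive; > 1.1
    antagonism."""
    if not np.isfinite(ci) or ci <= 0:
        raise ConfigurationError("CI must be positive and finite")
    if ci < 0.3:
        return "strong-synergy"
    if ci < 0.9:
        return "synergy"
    if ci <= 1.1:
        return "additive"
    return "antagonism"


# ---------------------------------------------------------------------------
# Cohort-level screening
# ---------------------------------------------------------------------------


def _cohort_fa(cohort, doses, schedule, follow_up_months, control_mean):
    """Cohort-level effect fraction: TGI of the mean tumor-volume trajectory
    at end of treatment, as a fraction clipped to the open interval."""
    reg = clinical_regimen(doses, schedule=schedule, follow_up_months=follow_up_months)
    table, mean = run_arm(cohort, reg, arm="+".join(doses) or "control",
                          doses=doses, collect_mean_volume=True)
    eot = reg.end_of_treatment
    v0 = float(np.interp(0.0, mean.time_day, mean.mean_volume_cm3))
    vt = float(np.interp(eot, mean.time_day, mean.mean_volume_cm3))
    vc = float(np.interp(eot, control_mean.time_day, control_mean.mean_volume_cm3))
    v0c = float(np.interp(0.0, control_mean.time_day, control_mean.mean_volume_cm3))
    tgi = ((vc - v0c) - (vt - v0)) / (vc - v0c)
    fa = float(np.clip(tgi, *FA_CLIP))
    events = table[~table.failed]
    km = kaplan_meier(events.ttp_months, events.event)
    return fa, median_pfs(km), table


def monotherapy_median_effect_fits(
    cohort: Cohort,
    drugs,
    dose_ranges: dict[str, tuple[float, float]] | None = None,
    n_doses: int = 6,
    schedule: str = "Q3W",
    follow_up_months: float = 12.0,
) -> dict[str, MedianEffectFit]:
    """Per-drug median-effect fits from log-spaced monotherapy grids run on
    the same cohort (the screening reference curves)."""
    dose_ranges = {**DEFAULT_DOSE_RANGES, **(dose_ranges or {})}
    control_reg = clinical_regimen({}, schedule=schedule, follow_up_months=follow_up_months)
    _, control_mean = run_arm(cohort, control_reg, arm="control", collect_mean_volume=True)
    fits = {}
    for drug in drugs:
        lo, hi = dose_ranges[drug]
        grid = np.logspace(np.log10(lo), np.log10(hi), n_doses)
        fas = [
            _cohort_fa(cohort, {drug: float(d)}, schedule, follow_up_months, control_mean)[0]
            for d in grid
        ]
        fits[drug] = median_effect_fit(grid, fas)
    return fits


def screen_combinations(
    cohort: Cohort,
    drugs: tuple[str, ...],
    n_samples: int = 50,
    dose_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    schedule: str = "Q3W",
    follow_up_months: float = 12.0,
    fits: dict[str, MedianEffectFit] | None = None,
) -> pd.DataFrame:
    """LHS screening of a 2- or 3-drug combination over dose space.

    For each sampled dose vector the cohort is simulated under the Q3W
    regimen (cisplatin truncated at six cycles), the TGI-based effect
    fraction and CI are computed against the per-drug median-effect fits,
    and the combination's median PFS is recorded.  Failures are isolated
    per sample.
    """
    if len(drugs) < 2:
        raise ConfigurationError("a combination needs >= 2 drugs")
    dose_ranges = {**DEFAULT_DOSE_RANGES, **(dose_ranges or {})}
    control_reg = clinical_regimen({}, schedule=schedule, follow_up_months=follow_up_months)
    _, control_mean = run_arm(cohort, control_reg, arm="control", collect_mean_volume=True)
    if fits is None:
        fits = monotherapy_median_effect_fits(
            cohort, drugs, dose_ranges, schedule=schedule,
            follow_up_months=follow_up_months)

    sampler = qmc.LatinHypercube(d=len(drugs), seed=seed)
    unit = sampler.random(n_samples)
    lows = np.array([dose_ranges[d][0] for d in drugs])
    highs = np.array([dose_ranges[d][1] for d in drugs])
    dose_matrix = np.exp(np.log(lows) + unit * (np.log(highs) - np.log(lows)))

    rows = []
    for i in range(n_samples):
        doses = {d: float(dose_matrix[i, j]) for j, d in enumerate(drugs)}
        total = sum(doses.values())
        row = {f"dose_{d}": v for d, v in doses.items()}
        row.update(sample=i, total_dose=total, failed=False)
        for d, v in doses.items():
            row[f"fraction_{d}"] = v / total
        try:
            fa, mpfs, _ = _cohort_fa(cohort, doses, schedule, follow_up_months, control_mean)
            ci = combination_index(doses, fa, fits)
            row.update(fa=fa, ci=ci, ci_class=classify_ci(ci),
                       median_pfs_months=mpfs if mpfs is not None else np.nan)
        except Exception as exc:
            row.update(failed=True, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


def mine_conditions(
    results: pd.DataFrame,
    target_class: str = "strong-synergy",
    max_terms: int = 3,
    quantiles=(0.1, 0.25, 0.5, 0.75, 0.9),
) -> list[str]:
    """Descriptive threshold-rule mining over a screening table.

    Greedily builds a conjunction of simple predicates (per-drug dose, dose
    fraction, total dose, each compared against sample quantiles) that
    maximizes precision for the target CI class while keeping at least one
    true positive.  A readable report of where (anti)synergy lives in dose
    space, not an inferential model.
    """
    ok = results[~results.get("failed", False)].copy()
    if ok.empty or "ci_class" not in ok:
        raise ConfigurationError("screening table has no successful samples")
    y = (ok.ci_class == target_class).to_numpy()
    if not y.any():
        return [f"no samples in class '{target_class}'"]
    feats = [c for c in ok.columns if c.startswith(("dose_", "fraction_", "total_"))]
    candidates = []
    for f in feats:
        for q in quantiles:
            thr = float(ok[f].quantile(q))
            candidates.append((f, ">", thr, ok[f].to_numpy() > thr))
            candidates.append((f, "<", thr, ok[f].to_numpy() < thr))

    chosen: list[tuple[str, str, float]] = []
    mask = np.ones(len(ok), dtype=bool)
    for _ in range(max_terms):
        best = None
        base_prec = y[mask].mean() if mask.any() else 0.0
        for f, op, thr, cand in candidates:
            m = mask & cand
            if not (y & m).any():
                continue
            prec = y[m].mean()
            if prec > base_prec + 1e-12 and (best is None or prec > best[0]):
                best = (prec, f, op, thr, m)
        if best is None:
            break
        _, f, op, thr, mask = best
        chosen.append((f, op, thr))
    if not chosen:
        return [f"class '{target_class}': no improving threshold rule found"]
    parts = [f"{f} {op} {thr:.3g}" for f, op, thr in chosen]
    prec = y[mask].mean()
    recall = (y & mask).sum() / y.sum()
    return [" AND ".join(parts) + f"   (precision {prec:.0%}, recall {recall:.0%})"]
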