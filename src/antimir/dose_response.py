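"""Dose-response characterization of anti-miR-155: dose grids across
schedules, Hill-equation fits, EC_p inversion and LHS prediction bands.

Two Hill forms are supported.  The basic form (``eq1``)

    E(D) = E_max / (1 + (EC50/D)^n)

describes effects that vanish at zero dose (TGI); the offset form (``eq2``)

    E(D) = E_min + (E_max - E_min) / (1 + (EC50/D)^n)

describes endpoints with a nonzero zero-dose value (RECIST diameter change,
where E_min is the untreated change and E_max the asymptote under saturating
drug).  ``HillModel(...).fit()`` returns a :class:`HillResults` carrying
estimates, standard errors, confidence intervals and the EC_p inversion."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import qmc

from .dosing import clinical_regimen
from .errors import ConfigurationError, SimulationError
from .model import simulate, untreated_volume
from .parameters import ModelParameters
from .response import recist_stream, tumor_growth_inhibition
from .dosing import HUMAN_INCEPTION_TO_TREATMENT

__all__ = [
    "DEFAULT_DOSE_GRID",
    "run_dose_grid",
    "HillModel",
    "HillResults",
    "fit_hill",
    "prediction_interval",
    "SENSITIVE_PARAMETERS",
]

#: 20 doses, log-uniform over 1e-3..10 mg/kg
DEFAULT_DOSE_GRID = np.logspace(-3, 1, 20)

#: GSA-identified sensitive set used for prediction intervals and cohorts
SENSITIVE_PARAMETERS = (
    "growth.intrinsic_growth_rate",
    "mirna.proliferation_gain",
    "nanoparticle.diameter",
    "mirna.production_rate",
    "mirna.degradation_rate",
    "mirna.potency",
    "mirna.antagonist_gain",
    "mirna.antagonist_degradation",
    "mirna.antagonist_potency",
    "nanoparticle.degradation_rate",
)


def run_dose_grid(
    params_human: ModelParameters,
    doses=None,
    schedule: str = "Q3W",
    baseline_volume: float | None = None,
    drug: str = "anti_mir155_np",
) -> pd.DataFrame:
    """Simulate a dose grid for one schedule and return per-dose endpoints.

    Treatment starts from the average patient's 124-week baseline tumor; TGI
    and RECIST diameter change are evaluated at end of treatment against a
    shared control arm.  Per-dose simulation failures are recorded (``error``
    column) without aborting the grid.
    """
    doses = DEFAULT_DOSE_GRID if doses is None else np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ConfigurationError("doses must be > 0 mg/kg")
    if baseline_volume is None:
        baseline_volume = float(untreated_volume(params_human, HUMAN_INCEPTION_TO_TREATMENT))
    eot_months = 190.0 / 30.44
    control = simulate(
        params_human, clinical_regimen({}, schedule=schedule, follow_up_months=eot_months),
        v0=baseline_volume,
    )
    rows = []
    for dose in doses:
        row = {"dose_mgkg": float(dose), "schedule": schedule}
        reg = clinical_regimen({drug: float(dose)}, schedule=schedule,
                               follow_up_months=eot_months)
        try:
            traj = simulate(params_human, reg, v0=baseline_volume)
            eot = reg.end_of_treatment
            row["tgi_percent"] = tumor_growth_inhibition(traj, control, eot)
            stream = recist_stream(traj)
            irow = (stream.time_day - eot).abs().argmin()
            row["diameter_change_percent"] = float(
                stream.change_from_baseline_percent.iloc[irow])
        except SimulationError as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hill fitting
# ---------------------------------------------------------------------------


def _hill_eq1(d, emax, ec50, n):
    return emax / (1.0 + (ec50 / d) ** n)


def _hill_eq2(d, emax, emin, ec50, n):
    return emin + (emax - emin) / (1.0 + (ec50 / d) ** n)


@dataclass
class HillResults:
    """Fitted Hill parameterization with covariance-based uncertainty."""

    form: str
    emax: float
    ec50: float
    n: float
    emin: float | None
    cov: np.ndarray
    doses: np.ndarray
    effects: np.ndarray

    @property
    def param_names(self):
        return ("emax", "ec50", "n") if self.form == "eq1" else ("emax", "emin", "ec50", "n")

    @property
    def estimates(self) -> dict[str, float]:
        vals = (self.emax, self.ec50, self.n) if self.form == "eq1" \
            else (self.emax, self.emin, self.ec50, self.n)
        return dict(zip(self.param_names, vals))

    @property
    def se(self) -> dict[str, float]:
        return dict(zip(self.param_names, np.sqrt(np.diag(self.cov))))

    def conf_int(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        dof = max(len(self.doses) - len(self.param_names), 1)
        tval = stats.t.ppf(0.5 + level / 2.0, dof)
        return {
            k: (v - tval * self.se[k], v + tval * self.se[k])
            for k, v in self.estimates.items()
        }

    def predict(self, dose):
        d = np.asarray(dose, dtype=float)
        out = _hill_eq1(d, self.emax, self.ec50, self.n) if self.form == "eq1" \
            else _hill_eq2(d, self.emax, self.emin, self.ec50, self.n)
        return float(out) if np.isscalar(dose) else out

    def ec_p(self, p: float) -> float:
        """Dose giving p% of the saturable effect span:
        ``D = EC50 * (p / (100 - p))^(1/n)``."""
        if not 0 < p < 100:
            raise ConfigurationError("p must lie in (0, 100)")
        return self.ec50 * (p / (100.0 - p)) ** (1.0 / self.n)

    @property
    def rsquared(self) -> float:
        resid = self.effects - self.predict(self.doses)
        ss = np.sum((self.effects - self.effects.mean()) ** 2)
        return 1.0 - float(np.sum(resid ** 2) / ss) if ss > 0 else np.nan

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [f"Hill fit ({self.form}), {len(self.doses)} dose points, "
                 f"R^2 = {self.rsquared:.4f}"]
        for k, v in self.estimates.items():
            lines.append(f"  {k:<6} {v:10.4g}   95% CI [{ci[k][0]:.4g}, {ci[k][1]:.4g}]")
        return "\n".join(lines)

    def plot(self, ax=None, **kw):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        ax.semilogx(self.doses, self.effects, "o", **kw)
        grid = np.logspace(np.log10(self.doses.min()), np.log10(self.doses.max()), 200)
        ax.semilogx(grid, self.predict(grid), "-")
        ax.set_xlabel("dose (mg/kg)")
        return ax


class HillModel:
    """Nonlinear least-squares Hill model of effect versus dose."""

    def __init__(self, doses, effects, form: str = "eq1"):
        d = np.asarray(doses, dtype=float)
        e = np.asarray(effects, dtype=float)
        if form not in ("eq1", "eq2"):
            raise ConfigurationError("form must be 'eq1' or 'eq2'")
        ok = np.isfinite(d) & np.isfinite(e) & (d > 0)
        d, e = d[ok], e[ok]
        if len(d) < 4:
            raise ConfigurationError("need >= 4 positive dose points")
        if d.max() / d.min() < 100.0:
            warnings.warn("dose span below two decades; Hill fit may be ill-conditioned")
        order = np.argsort(d)
        self.doses, self.effects = d[order], e[order]
        self.form = form

    def _start(self) -> tuple[np.ndarray, tuple]:
        d, e = self.doses, self.effects
        span = (d.min() / 10.0, d.max() * 10.0)
        if self.form == "eq1":
            emax0 = max(e.max(), 1e-6) * 1.05
            # log-log linearization of E/(Emax-E) gives slope n, intercept -n log EC50
            with np.errstate(divide="ignore", invalid="ignore"):
                y = np.log(np.clip(e, 1e-9, None) / np.clip(emax0 - e, 1e-9, None))
            slope, intercept = np.polyfit(np.log(d), y, 1)
            n0 = float(np.clip(slope, 0.1, 5.0))
            ec0 = float(np.clip(np.exp(-intercept / n0), *span))
            p0 = [emax0, ec0, n0]
            bounds = ([0.0, span[0], 0.05], [np.inf, span[1], 10.0])
        else:
            emin0, emax0 = float(e[0]), float(e[-1])
            ec0 = float(np.sqrt(d.min() * d.max()))
            p0 = [emax0, emin0, ec0, 1.0]
            bounds = ([-np.inf, -np.inf, span[0], 0.05], [np.inf, np.inf, span[1], 10.0])
        return np.array(p0), bounds

    def fit(self) -> HillResults:
        func = _hill_eq1 if self.form == "eq1" else _hill_eq2
        p0, bounds = self._start()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                func, self.doses, self.effects, p0=p0, bounds=bounds, maxfev=20000,
            )
        if self.form == "eq1":
            emax, ec50, n = popt
            emin = None
        else:
            emax, emin, ec50, n = popt
        return HillResults(
            form=self.form, emax=float(emax), ec50=float(ec50), n=float(n),
            emin=None if emin is None else float(emin),
            cov=pcov, doses=self.doses, effects=self.effects,
        )


def fit_hill(doses, effects, form: str = "eq1") -> HillResults:
    """Convenience wrapper: ``HillModel(doses, effects, form).fit()``."""
    return HillModel(doses, effects, form).fit()


def ec_p(fit: HillResults, p: float) -> float:
    """Functional alias for :meth:`HillResults.ec_p`."""
    return fit.ec_p(p)


def prediction_interval(
    params_human: ModelParameters,
    doses=None,
    sensitive: tuple[str, ...] = SENSITIVE_PARAMETERS,
    n_sets: int = 1000,
    span: float = 0.10,
    level: float = 90.0,
    seed: int = 155,
    schedule: str = "Q3W",
) -> pd.DataFrame:
    """Empirical per-dose prediction band for TGI under parameter uncertainty.

    ``n_sets`` Latin-Hypercube parameter combinations are drawn within
    ``+-span`` of baseline for the sensitive set; the band reports the
    (100-level)/2 and (100+level)/2 percentiles across sets.
    """
    if n_sets < 100:
        raise ConfigurationError("n_sets < 100 gives unstable interval estimates")
    for name in sensitive:
        params_human.get(name)
    doses = DEFAULT_DOSE_GRID if doses is None else np.asarray(doses, dtype=float)
    sampler = qmc.LatinHypercube(d=len(sensitive), seed=seed)
    mult = 1.0 - span + 2.0 * span * sampler.random(n_sets)
    lo_q, hi_q = (100.0 - level) / 2.0, (100.0 + level) / 2.0

    tgis = np.full((n_sets, len(doses)), np.nan)
    for i in range(n_sets):
        p_i = params_human.with_multipliers(dict(zip(sensitive, mult[i])))
        grid = run_dose_grid(p_i, doses, schedule=schedule)
        if "tgi_percent" in grid:
            tgis[i] = grid.tgi_percent.to_numpy()
    return pd.DataFrame({
        "dose_mgkg": doses,
        "tgi_median": np.nanmedian(tgis, axis=0),
        "tgi_lower": np.nanpercentile(tgis, lo_q, axis=0),
        "tgi_upper": np.nanpercentile(tgis, hi_q, axis=0),
    })
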