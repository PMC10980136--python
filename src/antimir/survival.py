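"""Progression-free survival analysis: Kaplan-Meier estimation, median PFS,
Cox hazard ratios, and Hill characterization of median PFS versus dose.

The product-limit estimator and the Cox proportional-hazards fit are
delegated to ``lifelines``; this module adds the package's conventions
(months scale, not-reached medians, explicit flagging of numerically
degenerate/separated Cox fits instead of reporting implausible point
estimates)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

from .errors import ConfigurationError, UndefinedMetricError

__all__ = [
    "SurvivalCurve",
    "kaplan_meier",
    "median_pfs",
    "HazardRatioResult",
    "hazard_ratio",
    "pfs_dose_hill",
]


@dataclass
class SurvivalCurve:
    """A Kaplan-Meier curve: event-time grid (months), survival
    probabilities, numbers at risk and censoring marks."""

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    censor_times: np.ndarray
    n_subjects: int

    def probability_at(self, t: float) -> float:
        """S(t): right-continuous step function, S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median(self) -> float | None:
        """Smallest time with S(t) <= 0.5, or None when never reached."""
        below = self.survival <= 0.5 + 1e-12
        if not below.any():
            return None
        return float(self.times[np.argmax(below)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_months": self.times,
            "pfs_probability": self.survival,
            "n_at_risk": self.n_at_risk,
        })

    def plot(self, ax=None, **kw):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        ax.step(np.concatenate([[0.0], self.times]),
                np.concatenate([[1.0], self.survival]), where="post", **kw)
        ax.set_xlabel("months from treatment start")
        ax.set_ylabel("PFS probability")
        ax.set_ylim(0, 1.02)
        return ax


def kaplan_meier(durations, event_observed=None) -> SurvivalCurve:
    """Product-limit PFS estimate from per-subject times (months) and event
    flags (True = progression, False = censored; default all events)."""
    t = np.asarray(durations, dtype=float)
    if t.size == 0:
        raise ConfigurationError("at least one subject is required")
    if np.any(t < 0):
        raise ConfigurationError("times must be nonnegative")
    e = np.ones_like(t, dtype=bool) if event_observed is None \
        else np.asarray(event_observed, dtype=bool)
    if e.shape != t.shape:
        raise ConfigurationError("event flags must match times in length")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = times > 0
    at_risk = np.array([
        kmf.event_table.at_risk.loc[ti] if ti in kmf.event_table.index else np.nan
        for ti in times[keep]
    ])
    return SurvivalCurve(
        times=times[keep],
        survival=surv[keep],
        n_at_risk=at_risk,
        censor_times=np.sort(t[~e]),
        n_subjects=len(t),
    )


def median_pfs(curve: SurvivalCurve) -> float | None:
    """Median PFS in months; None when not reached."""
    return curve.median


@dataclass
class HazardRatioResult:
    hr: float | None
    ci_lower: float | None
    ci_upper: float | None
    p_value: float | None
    separated: bool
    n_treatment: int
    n_control: int

    def __str__(self):
        if self.separated:
            return "HR numerically degenerate (complete or near-complete separation)"
        return (f"HR {self.hr:.3g} (95% CI {self.ci_lower:.3g}-{self.ci_upper:.3g}, "
                f"p = {self.p_value:.3g})")


#: |log HR| beyond which a Cox fit is treated as separated
_SEPARATION_LOG_HR = np.log(1e4)


def hazard_ratio(
    treatment_ttp, treatment_event, control_ttp, control_event
) -> HazardRatioResult:
    """Cox proportional-hazards HR (treatment vs control) with Wald CI.

    Groups whose event times barely overlap produce monotone partial
    likelihoods; such fits are reported with ``separated=True`` and no point
    estimate rather than an arbitrarily tiny number.
    """
    t_t = np.asarray(treatment_ttp, dtype=float)
    t_c = np.asarray(control_ttp, dtype=float)
    e_t = np.asarray(treatment_event, dtype=bool)
    e_c = np.asarray(control_event, dtype=bool)
    if t_t.size == 0 or t_c.size == 0:
        raise ConfigurationError("both groups must be non-empty")
    if not e_t.any() or not e_c.any():
        raise UndefinedMetricError("hazard ratio undefined when a group has no events")

    df = pd.DataFrame({
        "time": np.concatenate([t_t, t_c]),
        "event": np.concatenate([e_t, e_c]).astype(int),
        "treated": np.concatenate([np.ones_like(t_t), np.zeros_like(t_c)]),
    })
    if np.allclose(np.sort(t_t), np.sort(t_c)) and t_t.size == t_c.size \
            and (np.sort(e_t) == np.sort(e_c)).all():
        return HazardRatioResult(1.0, None, None, 1.0, False, t_t.size, t_c.size)

    cph = CoxPHFitter(penalizer=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except Exception:
            return HazardRatioResult(None, None, None, None, True, t_t.size, t_c.size)
    beta = float(cph.params_.iloc[0])
    if not np.isfinite(beta) or abs(beta) > _SEPARATION_LOG_HR:
        return HazardRatioResult(None, None, None, None, True, t_t.size, t_c.size)
    ci = cph.confidence_intervals_.to_numpy()[0]
    return HazardRatioResult(
        hr=float(np.exp(beta)),
        ci_lower=float(np.exp(ci[0])),
        ci_upper=float(np.exp(ci[1])),
        p_value=float(cph.summary["p"].iloc[0]),
        separated=False,
        n_treatment=t_t.size,
        n_control=t_c.size,
    )


def pfs_dose_hill(doses, medians):
    """Hill (saturable) fit of median PFS versus dose.

    Not-reached medians (None/NaN) are excluded with a warning; returns the
    fitted :class:`~antimir.dose_response.HillResults` (E_max with CI, EC_p
    inversion shared with the dose-response module).
    """
    from .dose_response import HillModel

    d = np.asarray(doses, dtype=float)
    m = np.array([np.nan if v is None else float(v) for v in medians])
    ok = np.isfinite(m)
    if (~ok).any():
        warnings.warn(f"excluding {int((~ok).sum())} not-reached medians from the Hill fit")
    if ok.sum() < 4:
        raise ConfigurationError("need >= 4 dose points with reached medians")
    return HillModel(d[ok], m[ok], form="eq1").fit()
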