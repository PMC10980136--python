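"""Dose events, regimens and the packaged treatment protocols."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import ConfigurationError

DRUGS = ("anti_mir155_np", "cisplatin", "atezolizumab", "pembrolizumab")

#: days between doses for the named clinical schedules
SCHEDULE_INTERVALS = {"QW": 7.0, "Q2W": 14.0, "Q3W": 21.0}
#: treatment-cycle counts giving a ~six-month course per schedule
SCHEDULE_CYCLES = {"QW": 25, "Q2W": 13, "Q3W": 9}

DAYS_PER_MONTH = 30.44


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: drug id, dose in mg/kg, time in days from
    treatment start."""

    drug: str
    dose: float
    time: float

    def __post_init__(self):
        if self.drug not in DRUGS:
            raise ConfigurationError(f"unknown drug '{self.drug}' (known: {DRUGS})")
        if self.dose < 0:
            raise ConfigurationError("dose must be >= 0 mg/kg")
        if self.time < 0:
            raise ConfigurationError("dose time must be >= 0 days")


@dataclass
class Regimen:
    """An ordered sequence of dose events plus the observation window.

    ``treatment_start`` is expressed in simulation days (days from tumor
    inoculation/inception when the simulation starts there, zero when the
    simulation starts at treatment initiation); event times are days from
    treatment start.  ``follow_up_end`` is in simulation days.
    """

    events: list[DoseEvent] = field(default_factory=list)
    treatment_start: float = 0.0
    follow_up_end: float = 28.0

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: (e.time, e.drug))
        if self.treatment_start < 0:
            raise ConfigurationError("treatment_start must be >= 0")
        if self.events and self.follow_up_end < self.treatment_start + self.events[-1].time:
            raise ConfigurationError("follow_up_end precedes the last dose event")

    @property
    def end_of_treatment(self) -> float:
        """Simulation day of the last administration plus one inter-dose gap
        (or the follow-up end for an empty regimen)."""
        if not self.events:
            return self.follow_up_end
        times = [e.time for e in self.events]
        gap = min((b - a for a, b in zip(times, times[1:]) if b > a), default=7.0)
        return min(self.treatment_start + times[-1] + gap, self.follow_up_end)

    def drugs(self) -> set[str]:
        return {e.drug for e in self.events}

    def absolute_events(self) -> list[tuple[float, str, float]]:
        """(simulation time, drug, dose mg/kg) with simultaneous same-drug doses summed."""
        merged: dict[tuple[float, str], float] = {}
        for e in self.events:
            key = (self.treatment_start + e.time, e.drug)
            merged[key] = merged.get(key, 0.0) + e.dose
        return [(t, d, amt) for (t, d), amt in sorted(merged.items())]

    def shifted(self, new_start: float) -> "Regimen":
        span = self.follow_up_end - self.treatment_start
        return replace(self, treatment_start=new_start, follow_up_end=new_start + span)


def periodic_regimen(
    drug: str,
    dose: float,
    interval: float,
    n_doses: int,
    treatment_start: float = 0.0,
    follow_up_end: float | None = None,
) -> Regimen:
    events = [DoseEvent(drug, dose, i * interval) for i in range(n_doses)]
    if follow_up_end is None:
        follow_up_end = treatment_start + n_doses * interval
    return Regimen(events=events, treatment_start=treatment_start, follow_up_end=follow_up_end)


def schedule_regimen(
    drug: str,
    dose: float,
    schedule: str = "Q3W",
    n_cycles: int | None = None,
    treatment_start: float = 0.0,
    follow_up_end: float | None = None,
) -> Regimen:
    """Build a named-schedule (QW/Q2W/Q3W) regimen; default cycle counts give
    a ~six-month treatment course."""
    if schedule not in SCHEDULE_INTERVALS:
        raise ConfigurationError(f"unknown schedule '{schedule}' (known: QW, Q2W, Q3W)")
    interval = SCHEDULE_INTERVALS[schedule]
    cycles = SCHEDULE_CYCLES[schedule] if n_cycles is None else n_cycles
    return periodic_regimen(drug, dose, interval, cycles, treatment_start, follow_up_end)


def combine(*regimens: Regimen) -> Regimen:
    """Merge regimens that share a treatment start; the follow-up window is
    the longest of the inputs."""
    starts = {r.treatment_start for r in regimens}
    if len(starts) != 1:
        raise ConfigurationError("combined regimens must share treatment_start")
    events = [e for r in regimens for e in r.events]
    return Regimen(
        events=events,
        treatment_start=starts.pop(),
        follow_up_end=max(r.follow_up_end for r in regimens),
    )


# ---------------------------------------------------------------------------
# Packaged protocols
# ---------------------------------------------------------------------------

#: initial engrafted tumor volume for the preclinical protocols, cm^3
PRECLINICAL_V0 = 0.05
#: treatment starts one week after inoculation and runs for three weeks
PRECLINICAL_START = 7.0
PRECLINICAL_END = 28.0

#: preclinical dose levels, mg/kg
PRECLINICAL_DOSES = {
    "anti_mir155_np": 0.2,   # 4,000 ng in a 0.02 kg mouse, twice weekly
    "cisplatin": 8.0,        # once weekly
    "atezolizumab": 10.0,    # twice weekly
    "pembrolizumab": 5.0,    # twice weekly
}

PRECLINICAL_ARMS = (
    "control",
    "anti_mir155",
    "cisplatin",
    "combination",
    "atezolizumab",
    "pembrolizumab",
)


def preclinical_regimen(arm: str) -> Regimen:
    """The packaged mouse xenograft protocols used for calibration anchors."""
    start, end = PRECLINICAL_START, PRECLINICAL_END
    n_weeks = (end - start) / 7.0

    def biweekly(drug):
        return periodic_regimen(
            drug, PRECLINICAL_DOSES[drug], 3.5, int(2 * n_weeks), start, end
        )

    if arm == "control":
        return Regimen(events=[], treatment_start=start, follow_up_end=end)
    if arm == "anti_mir155":
        return biweekly("anti_mir155_np")
    if arm == "cisplatin":
        return periodic_regimen("cisplatin", PRECLINICAL_DOSES["cisplatin"], 7.0,
                                int(n_weeks), start, end)
    if arm == "combination":
        return combine(biweekly("anti_mir155_np"), preclinical_regimen("cisplatin"))
    if arm == "atezolizumab":
        return biweekly("atezolizumab")
    if arm == "pembrolizumab":
        return biweekly("pembrolizumab")
    raise ConfigurationError(f"unknown preclinical arm '{arm}' (known: {PRECLINICAL_ARMS})")


#: human treatment starts 124 weeks post-inception; simulations of the clinical
#: setting start at treatment initiation (t = 0) from the grown baseline tumor.
HUMAN_INCEPTION_TO_TREATMENT = 124 * 7.0
#: follow-up horizon for progression endpoints, months after treatment start
CLINICAL_FOLLOW_UP_MONTHS = 36.0


def clinical_regimen(
    doses: dict[str, float],
    schedule: str = "Q3W",
    follow_up_months: float = CLINICAL_FOLLOW_UP_MONTHS,
    cisplatin_cycles: int = 6,
) -> Regimen:
    """Q3W (or QW/Q2W) clinical course of one or more drugs for ~six months;
    cisplatin is truncated at six cycles per standard practice."""
    follow_up = follow_up_months * DAYS_PER_MONTH
    parts = []
    for drug, dose in doses.items():
        cycles = None
        if drug == "cisplatin":
            cycles = min(cisplatin_cycles, SCHEDULE_CYCLES[schedule])
        parts.append(
            schedule_regimen(drug, dose, schedule, n_cycles=cycles,
                             treatment_start=0.0, follow_up_end=follow_up)
        )
    if not parts:
        return Regimen(events=[], treatment_start=0.0, follow_up_end=follow_up)
    return combine(*parts)
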