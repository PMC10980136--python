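"""Allometric mouse-to-human scaling and clinical dose-unit conversions.

Parameters scale between species as a body-weight power law
``P_h = P_m * (BW_h / BW_m)**A`` with the exponent set by parameter class:
rate constants -0.25, clearance 0.75, volume of distribution 1.0, and doses
-0.33 by convention.  The packaged human-equivalent-dose helper uses -0.25,
which reproduces the reference anti-miR-155 conversion (0.2 mg/kg in a
0.02 kg mouse -> 0.026 mg/kg in a 70 kg human); -0.33 remains available via
the ``exponent`` argument.  Parameters that are physical constants,
dimensionless gains or concentrations are marked ``invariant``; parameters
replaced by human population averages carry an explicit ``human_value``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources

from .errors import ConfigurationError
from .parameters import ModelParameters, SpeciesProfile

__all__ = [
    "ALLOMETRIC_EXPONENTS",
    "ScalingRule",
    "scale_parameter",
    "scale_parameter_set",
    "human_equivalent_dose",
    "clinical_dose_to_mgkg",
    "load_scaling_rules",
    "DEFAULT_HUMAN_PROFILE",
]

ALLOMETRIC_EXPONENTS = {
    "rate_constant": -0.25,
    "clearance": 0.75,
    "volume_of_distribution": 1.0,
    "dose": -0.33,
    "invariant": 0.0,
}

DEFAULT_HUMAN_PROFILE = SpeciesProfile(
    name="human",
    body_weight=70.0,
    plasma_volume=2900.0,
    tumor_interstitial_fraction=0.4,
    assumed_bsa=1.9,
)


@dataclass(frozen=True)
class ScalingRule:
    """How one parameter crosses species: a class (fixing the exponent) or a
    population-average override."""

    parameter_class: str
    human_value: float | None = None
    exponent_override: float | None = None

    def __post_init__(self):
        if self.parameter_class == "population_average":
            if self.human_value is None:
                raise ConfigurationError(
                    "population_average rule requires an explicit human_value"
                )
        elif self.parameter_class not in ALLOMETRIC_EXPONENTS:
            raise ConfigurationError(
                f"unknown parameter class '{self.parameter_class}' "
                f"(known: {sorted(ALLOMETRIC_EXPONENTS)} or 'population_average')"
            )

    @property
    def exponent(self) -> float:
        if self.exponent_override is not None:
            return self.exponent_override
        if self.parameter_class == "population_average":
            raise ConfigurationError("population_average rules have no exponent")
        return ALLOMETRIC_EXPONENTS[self.parameter_class]


def scale_parameter(
    value_mouse: float,
    rule: ScalingRule,
    species_m: SpeciesProfile,
    species_h: SpeciesProfile,
) -> float:
    """Apply ``P_h = P_m * (BW_h/BW_m)**A`` (or the population average)."""
    if species_m.body_weight <= 0 or species_h.body_weight <= 0:
        raise ConfigurationError("body weights must be > 0")
    if rule.parameter_class == "population_average":
        return float(rule.human_value)
    return value_mouse * (species_h.body_weight / species_m.body_weight) ** rule.exponent


def scale_parameter_set(
    params_mouse: ModelParameters,
    rules: dict[str, ScalingRule],
    human_profile: SpeciesProfile | None = None,
) -> ModelParameters:
    """Scale a complete mouse parameter set to humans.

    Every numeric non-species parameter must carry a rule; leftovers raise a
    :class:`ConfigurationError` listing the unassigned names.
    """
    human_profile = human_profile or DEFAULT_HUMAN_PROFILE
    if human_profile.name != "human":
        raise ConfigurationError("human profile must have name 'human'")
    names = [n for n in params_mouse.iter_names() if not n.startswith("species.")]
    missing = [n for n in names if n not in rules]
    if missing:
        raise ConfigurationError(f"no scaling rule for parameters: {missing}")
    out = params_mouse.copy()
    out.species = dataclasses.replace(human_profile)
    for name in names:
        out.set(name, scale_parameter(params_mouse.get(name), rules[name],
                                      params_mouse.species, human_profile))
    return out.validate()


def human_equivalent_dose(
    mouse_dose_mgkg: float,
    species_m: SpeciesProfile | None = None,
    species_h: SpeciesProfile | None = None,
    exponent: float = -0.25,
) -> float:
    """Human-equivalent mg/kg dose for a mouse mg/kg dose.

    The default exponent -0.25 reproduces the packaged reference conversion
    (0.2 -> 0.026 mg/kg); pass ``exponent=-0.33`` for the conventional
    dose-scaling exponent.
    """
    species_m = species_m or SpeciesProfile()
    species_h = species_h or DEFAULT_HUMAN_PROFILE
    rule = ScalingRule("dose", exponent_override=exponent)
    return scale_parameter(mouse_dose_mgkg, rule, species_m, species_h)


def clinical_dose_to_mgkg(
    amount: float,
    unit: str,
    species_h: SpeciesProfile | None = None,
) -> float:
    """Convert a clinical dose specification to mg/kg.

    ``unit`` is ``"mg"`` (flat dose, divided by body weight) or ``"mg/m2"``
    (multiplied by the assumed body surface area, then divided by body
    weight).  Full precision is retained; round only for display.
    """
    species_h = species_h or DEFAULT_HUMAN_PROFILE
    if amount < 0:
        raise ConfigurationError("dose must be >= 0")
    if unit == "mg":
        return amount / species_h.body_weight
    if unit in ("mg/m2", "mg/m^2"):
        if species_h.assumed_bsa is None:
            raise ConfigurationError("mg/m2 dosing requires an assumed BSA on the profile")
        return amount * species_h.assumed_bsa / species_h.body_weight
    raise ConfigurationError(f"unknown dose unit '{unit}' (use 'mg' or 'mg/m2')")


def load_scaling_rules(path=None) -> tuple[dict[str, ScalingRule], SpeciesProfile]:
    """Load the packaged (or a user) scaling-rule table.

    Returns the per-parameter rule map and the human species profile.
    """
    if path is None:
        ref = resources.files("antimir.data").joinpath("scaling_rules.json")
        raw = json.loads(ref.read_text())
    else:
        with open(path) as fh:
            raw = json.load(fh)
    rules = {
        name: ScalingRule(
            parameter_class=spec["class"],
            human_value=spec.get("human_value"),
            exponent_override=spec.get("exponent"),
        )
        for name, spec in raw["rules"].items()
    }
    profile = SpeciesProfile(**raw["human_profile"])
    return rules, profile
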