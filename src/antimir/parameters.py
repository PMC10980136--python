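"""Named model parameters: containers, validation, flat-key access and JSON I/O.

The model parameter vector is organised into physiologically meaningful groups
(species physiology, nanoparticle design, intratumoral transport, the miR-155
axis, the PD-1/PD-L1 checkpoint, cisplatin pharmacology, tumor growth).  Every
simulation, calibration, scaling or sampling operation consumes a
:class:`ModelParameters` instance; parameters are addressed externally by flat
``group.field`` names (e.g. ``"growth.intrinsic_growth_rate"``).

Units follow a single internal convention: time in days, volumes in cm^3
(== mL), tumor lengths in cm, nanoparticle diameters in nm, doses in mg/kg,
drug masses in mg, intracellular anti-miR-155 in mg/mL, molecular species
(miR-155, PD-L1, PD-1) in pM.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from importlib import resources
from typing import Any, Iterator

from .errors import ConfigurationError

__all__ = [
    "SpeciesProfile",
    "NanoparticleParameters",
    "TumorTransportParameters",
    "MirnaAxisParameters",
    "CheckpointParameters",
    "ChemoParameters",
    "GrowthParameters",
    "ModelParameters",
    "load_default_parameters",
]


def _require(condition: bool, name: str, message: str) -> None:
    if not condition:
        raise ConfigurationError(f"parameter '{name}': {message}")


@dataclass
class SpeciesProfile:
    """Host physiology: body weight (kg), plasma volume (mL), tumor
    interstitial volume fraction, and (humans) an assumed body surface area
    in m^2 used for mg/m^2 dose conversions."""

    name: str = "mouse"
    body_weight: float = 0.02
    plasma_volume: float = 1.0
    tumor_interstitial_fraction: float = 0.4
    assumed_bsa: float | None = None

    def validate(self) -> None:
        _require(self.name in ("mouse", "human"), "species.name", "must be 'mouse' or 'human'")
        _require(self.body_weight > 0, "species.body_weight", "must be > 0")
        _require(self.plasma_volume > 0, "species.plasma_volume", "must be > 0")
        _require(
            0 < self.tumor_interstitial_fraction < 1,
            "species.tumor_interstitial_fraction",
            "must lie in (0, 1)",
        )
        if self.assumed_bsa is not None:
            _require(self.assumed_bsa > 0, "species.assumed_bsa", "must be > 0 when given")


@dataclass
class NanoparticleParameters:
    """Anti-miR-155 carrier design and systemic fate.

    ``vascular_permeability_ref`` (cm/day) is the permeability of a vanishingly
    small particle; the effective NP permeability follows a Renkin-type
    hindrance ``P_NP = P_ref * (1 - d/d_pore)^2`` and is zero at or above the
    pore diameter.  The injected dose is expressed as anti-miR-155 payload
    mass, so ``payload_mass_fraction`` defaults to 1.
    """

    diameter: float = 100.0              # nm
    pore_diameter: float = 400.0         # nm
    degradation_rate: float = 0.5        # 1/day (metabolic, delta_NP)
    clearance_rate: float = 1.5          # 1/day (hepatobiliary, k_Cl)
    vascular_permeability_ref: float = 8e-4  # cm/day
    payload_mass_fraction: float = 1.0

    @property
    def vascular_permeability(self) -> float:
        """Effective size-hindered permeability, cm/day."""
        if self.diameter >= self.pore_diameter:
            return 0.0
        return self.vascular_permeability_ref * (1.0 - self.diameter / self.pore_diameter) ** 2

    def validate(self) -> None:
        _require(self.diameter > 0, "nanoparticle.diameter", "must be > 0")
        _require(self.pore_diameter > 0, "nanoparticle.pore_diameter", "must be > 0")
        for nm in ("degradation_rate", "clearance_rate", "vascular_permeability_ref"):
            _require(getattr(self, nm) >= 0, f"nanoparticle.{nm}", "must be >= 0")
        _require(
            0 < self.payload_mass_fraction <= 1,
            "nanoparticle.payload_mass_fraction",
            "must lie in (0, 1]",
        )


@dataclass
class TumorTransportParameters:
    """Intratumoral transport and cellular uptake geometry.

    Interstitial NPs reach cells by hindered diffusion over the intercapillary
    half-distance ``intercapillary_length`` (um); the diffusive delivery rate is
    ``k_diff = D_NP / Len^2`` with a Stokes-Einstein-like size dependence
    ``D_NP = diffusivity_scale / diameter`` (cm^2 nm / day over nm).  Uptake is
    split between cancer cells and TAMs; released payload distributes into an
    effective cytosolic volume fraction of the tumor for each cell type.
    """

    vascular_surface_density: float = 200.0  # cm^2 / cm^3
    intercapillary_length: float = 100.0     # um
    diffusivity_scale: float = 1e-3          # cm^2 * nm / day
    uptake_fraction_cancer: float = 0.8      # TAM share = 1 - this
    cytosol_fraction_cancer: float = 2e-4    # fraction of tumor volume
    cytosol_fraction_tam: float = 5e-5

    def validate(self) -> None:
        _require(self.vascular_surface_density > 0, "transport.vascular_surface_density", "must be > 0")
        _require(self.intercapillary_length > 0, "transport.intercapillary_length", "must be > 0")
        _require(self.diffusivity_scale > 0, "transport.diffusivity_scale", "must be > 0")
        _require(
            0.0 <= self.uptake_fraction_cancer <= 1.0,
            "transport.uptake_fraction_cancer",
            "must lie in [0, 1]",
        )
        _require(self.cytosol_fraction_cancer > 0, "transport.cytosol_fraction_cancer", "must be > 0")
        _require(self.cytosol_fraction_tam > 0, "transport.cytosol_fraction_tam", "must be > 0")


@dataclass
class MirnaAxisParameters:
    """miR-155 production/decay, its proliferative effect, and the antagonist.

    Both cancer cells and TAMs produce miR-155 at ``production_rate`` (pM/day)
    and degrade it at ``degradation_rate`` (1/day); TAMs additionally transfer
    miR-155 to cancer cells via exosomes at ``exosomal_transfer_rate`` (1/day),
    with the cancer-cell intrinsic production reduced correspondingly so that
    both cell types share the same pre-treatment equilibrium.  Intracellular
    anti-miR-155 multiplies the miR-155 degradation rate by
    ``1 + antagonist_gain * AM / (antagonist_potency + AM)``.
    """

    production_rate: float = 3.0         # g0_M, pM/day
    degradation_rate: float = 2.0        # delta_M, 1/day
    potency: float = 1.5                 # k_M, pM (Michaelis constant on proliferation)
    proliferation_gain: float = 2.1      # A_ML, dimensionless > 1
    antagonist_gain: float = 150.0       # A_AM,M, dimensionless > 1
    antagonist_potency: float = 0.01     # EC50_AM, mg/mL
    antagonist_degradation: float = 0.5  # delta_AM, 1/day
    exosomal_transfer_rate: float = 0.2  # k_exo, 1/day

    @property
    def equilibrium(self) -> float:
        """Pre-treatment miR-155 equilibrium (pM), identical in both cell types."""
        return self.production_rate / self.degradation_rate

    def validate(self) -> None:
        for nm in ("production_rate", "degradation_rate", "potency",
                   "antagonist_potency", "antagonist_degradation"):
            _require(getattr(self, nm) > 0, f"mirna.{nm}", "must be > 0")
        _require(self.proliferation_gain > 1, "mirna.proliferation_gain", "must be > 1")
        _require(self.antagonist_gain > 1, "mirna.antagonist_gain", "must be > 1")
        _require(self.exosomal_transfer_rate >= 0, "mirna.exosomal_transfer_rate", "must be >= 0")
        _require(
            self.exosomal_transfer_rate * self.equilibrium < self.production_rate,
            "mirna.exosomal_transfer_rate",
            "exosomal supply may not exceed intrinsic production at equilibrium",
        )


@dataclass
class CheckpointParameters:
    """PD-1/PD-L1 axis, immune kill, and antibody (ICI) pharmacology.

    Free PD-L1 on each tumor cell type is produced under miR-155 repression
    (``pdl1_production * k_ML / (k_ML + M)``) and degraded first-order; the
    repression constant ``pdl1_repression_constant`` defaults to 1.5/9 pM so
    that complete miR-155 knockdown raises steady-state PD-L1 exactly 10-fold.
    PD-1 is a constant-turnover pool with equilibrium 1 pM.  T-cell killing is
    attenuated by PD-1:PD-L1 complex formation, computed each step from the
    competitive binding equilibrium with atezolizumab (anti-PD-L1) and
    pembrolizumab (anti-PD-1).
    """

    pdl1_production: float = 5.0             # g_L, pM/day (per cell type)
    pdl1_degradation: float = 1.0            # delta_L, 1/day
    pdl1_repression_constant: float = 1.5 / 9.0  # k_ML, pM
    pd1_equilibrium: float = 1.0             # pM
    pd1_turnover: float = 1.0                # 1/day
    kd_pd1_pdl1: float = 1.0                 # pM
    kd_atezolizumab: float = 400.0           # pM
    kd_pembrolizumab: float = 29.0           # pM
    immune_kill_max: float = 0.018           # delta_T, 1/day
    inhibition_constant: float = 0.5         # pM of PD-1:PD-L1 complex
    ici_clearance_rate: float = 0.3          # 1/day (plasma)
    ici_permeability: float = 3e-3           # cm/day
    ici_interstitial_degradation: float = 0.1  # 1/day
    ici_molecular_weight: float = 1.47e5     # g/mol

    def validate(self) -> None:
        for nm in ("pdl1_production", "pdl1_degradation", "pdl1_repression_constant",
                   "pd1_equilibrium", "pd1_turnover", "kd_pd1_pdl1", "kd_atezolizumab",
                   "kd_pembrolizumab", "inhibition_constant", "ici_molecular_weight"):
            _require(getattr(self, nm) > 0, f"checkpoint.{nm}", "must be > 0")
        for nm in ("immune_kill_max", "ici_clearance_rate", "ici_permeability",
                   "ici_interstitial_degradation"):
            _require(getattr(self, nm) >= 0, f"checkpoint.{nm}", "must be >= 0")


@dataclass
class ChemoParameters:
    """Cisplatin pharmacology.  miR-155 inflates the cisplatin IC50 by
    ``1 + resistance_gain * M / (k_M + M)`` — the lumped abstraction of the
    miR-155/TP53 resistance feedback."""

    clearance_rate: float = 5.0          # 1/day
    tumor_permeability: float = 0.1      # cm/day
    interstitial_degradation: float = 1.0  # 1/day
    kill_max: float = 0.18               # delta_C, 1/day
    base_ic50: float = 3e-4              # mg/mL interstitial concentration
    resistance_gain: float = 2.5         # R_C, dimensionless >= 0

    def validate(self) -> None:
        for nm in ("clearance_rate", "tumor_permeability", "interstitial_degradation",
                   "kill_max", "resistance_gain"):
            _require(getattr(self, nm) >= 0, f"chemo.{nm}", "must be >= 0")
        _require(self.base_ic50 > 0, "chemo.base_ic50", "must be > 0")


@dataclass
class GrowthParameters:
    """Logistic tumor growth: intrinsic rate (1/day), carrying capacity (cm^3)
    and the volume of the founding cancer cell (cm^3)."""

    intrinsic_growth_rate: float = 0.078   # gamma, 1/day
    carrying_capacity: float = 4.0         # K, cm^3
    initial_cell_volume: float = 1e-9      # cm^3 (~ a single cell)

    def validate(self) -> None:
        _require(self.intrinsic_growth_rate > 0, "growth.intrinsic_growth_rate", "must be > 0")
        _require(self.carrying_capacity > 0, "growth.carrying_capacity", "must be > 0")
        _require(self.initial_cell_volume > 0, "growth.initial_cell_volume", "must be > 0")


_GROUPS = {
    "species": SpeciesProfile,
    "nanoparticle": NanoparticleParameters,
    "transport": TumorTransportParameters,
    "mirna": MirnaAxisParameters,
    "checkpoint": CheckpointParameters,
    "chemo": ChemoParameters,
    "growth": GrowthParameters,
}


@dataclass
class ModelParameters:
    """Composition of all parameter groups; the unit every simulation consumes."""

    species: SpeciesProfile = field(default_factory=SpeciesProfile)
    nanoparticle: NanoparticleParameters = field(default_factory=NanoparticleParameters)
    transport: TumorTransportParameters = field(default_factory=TumorTransportParameters)
    mirna: MirnaAxisParameters = field(default_factory=MirnaAxisParameters)
    checkpoint: CheckpointParameters = field(default_factory=CheckpointParameters)
    chemo: ChemoParameters = field(default_factory=ChemoParameters)
    growth: GrowthParameters = field(default_factory=GrowthParameters)

    def validate(self) -> "ModelParameters":
        for name in _GROUPS:
            getattr(self, name).validate()
        return self

    # -- flat-key access -------------------------------------------------

    def iter_names(self, numeric_only: bool = True) -> Iterator[str]:
        """Yield flat ``group.field`` names."""
        for gname, gtype in _GROUPS.items():
            for f in fields(gtype):
                if numeric_only and f.name in ("name",):
                    continue
                yield f"{gname}.{f.name}"

    def get(self, name: str) -> Any:
        gname, _, fname = name.partition(".")
        if gname not in _GROUPS or not hasattr(getattr(self, gname), fname):
            raise ConfigurationError(f"unknown parameter '{name}'")
        return getattr(getattr(self, gname), fname)

    def set(self, name: str, value: Any) -> None:
        gname, _, fname = name.partition(".")
        if gname not in _GROUPS or not hasattr(getattr(self, gname), fname):
            raise ConfigurationError(f"unknown parameter '{name}'")
        setattr(getattr(self, gname), fname, value)

    def copy(self) -> "ModelParameters":
        return dataclasses.replace(
            self, **{g: dataclasses.replace(getattr(self, g)) for g in _GROUPS}
        )

    def with_updates(self, updates: dict[str, Any]) -> "ModelParameters":
        out = self.copy()
        for k, v in updates.items():
            out.set(k, v)
        return out

    def with_multipliers(self, multipliers: dict[str, float]) -> "ModelParameters":
        """Multiplicatively perturb a set of parameters (sensitivity / cohorts)."""
        out = self.copy()
        for k, m in multipliers.items():
            out.set(k, out.get(k) * m)
        return out

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {g: dataclasses.asdict(getattr(self, g)) for g in _GROUPS}

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        kwargs = {}
        for gname, gtype in _GROUPS.items():
            if gname not in data:
                raise ConfigurationError(f"parameter file missing group '{gname}'")
            known = {f.name for f in fields(gtype)}
            extra = set(data[gname]) - known
            if extra:
                raise ConfigurationError(f"unknown fields in group '{gname}': {sorted(extra)}")
            kwargs[gname] = gtype(**data[gname])
        return cls(**kwargs).validate()

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def load_default_parameters(species: str = "mouse") -> ModelParameters:
    """Load the shipped default parameterization for ``'mouse'`` or ``'human'``.

    Mouse defaults were tuned so the packaged preclinical protocols reproduce
    the anchor tumor-growth-inhibition values; human defaults combine
    allometric scaling with clinically tuned overrides (see docs/methods.md).
    """
    if species not in ("mouse", "human"):
        raise ConfigurationError("species must be 'mouse' or 'human'")
    ref = resources.files("antimir.data").joinpath(f"{species}_default.json")
    return ModelParameters.from_dict(json.loads(ref.read_text()))
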