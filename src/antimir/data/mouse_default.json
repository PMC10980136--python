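{
  "checkpoint": {
    "ici_clearance_rate": 0.3,
    "ici_interstitial_degradation": 0.1,
    "ici_molecular_weight": 147000.0,
    "ici_permeability": 0.003,
    "immune_kill_max": 0.0208521,
    "inhibition_constant": 0.5,
    "kd_atezolizumab": 400.0,
    "kd_pd1_pdl1": 1.0,
    "kd_pembrolizumab": 29.0,
    "pd1_equilibrium": 1.0,
    "pd1_turnover": 1.0,
    "pdl1_degradation": 1.0,
    "pdl1_production": 5.0,
    "pdl1_repression_constant": 0.16666666666666666
  },
  "chemo": {
    "base_ic50": 0.0001,
    "clearance_rate": 5.0,
    "interstitial_degradation": 1.0,
    "kill_max": 0.146805,
    "resistance_gain": 1.0,
    "tumor_permeability": 0.1
  },
  "growth": {
    "carrying_capacity": 4.0,
    "initial_cell_volume": 1e-09,
    "intrinsic_growth_rate": 0.0746114
  },
  "mirna": {
    "antagonist_degradation": 0.5,
    "antagonist_gain": 150.0,
    "antagonist_potency": 0.01,
    "degradation_rate": 2.0,
    "exosomal_transfer_rate": 0.2,
    "potency": 1.5,
    "production_rate": 3.0,
    "proliferation_gain": 2.34555
  },
  "nanoparticle": {
    "clearance_rate": 1.5,
    "degradation_rate": 0.5,
    "diameter": 100.0,
    "payload_mass_fraction": 1.0,
    "pore_diameter": 400.0,
    "vascular_permeability_ref": 0.009
  },
  "species": {
    "assumed_bsa": null,
    "body_weight": 0.02,
    "name": "mouse",
    "plasma_volume": 1.0,
    "tumor_interstitial_fraction": 0.4
  },
  "transport": {
    "cytosol_fraction_cancer": 0.0002,
    "cytosol_fraction_tam": 5e-05,
    "diffusivity_scale": 0.001,
    "intercapillary_length": 100.0,
    "uptake_fraction_cancer": 0.8,
    "vascular_surface_density": 200.0
  }
}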