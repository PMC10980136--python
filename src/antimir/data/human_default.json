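{
  "checkpoint": {
    "ici_clearance_rate": 0.03900355956206215,
    "ici_interstitial_degradation": 0.013001186520687383,
    "ici_molecular_weight": 147000.0,
    "ici_permeability": 0.003,
    "immune_kill_max": 0.047,
    "inhibition_constant": 0.5,
    "kd_atezolizumab": 400.0,
    "kd_pd1_pdl1": 1.0,
    "kd_pembrolizumab": 29.0,
    "pd1_equilibrium": 1.0,
    "pd1_turnover": 0.13001186520687383,
    "pdl1_degradation": 0.13001186520687383,
    "pdl1_production": 0.6500593260343691,
    "pdl1_repression_constant": 0.16666666666666666
  },
  "chemo": {
    "base_ic50": 0.0001,
    "clearance_rate": 0.6500593260343691,
    "interstitial_degradation": 0.13001186520687383,
    "kill_max": 0.01988423825917028,
    "resistance_gain": 1.0,
    "tumor_permeability": 0.1
  },
  "growth": {
    "carrying_capacity": 26.8788945067861,
    "initial_cell_volume": 1e-09,
    "intrinsic_growth_rate": 0.020957935664806495
  },
  "mirna": {
    "antagonist_degradation": 0.5011535918089695,
    "antagonist_gain": 150.0,
    "antagonist_potency": 1.9072287774806194,
    "degradation_rate": 0.26002373041374766,
    "exosomal_transfer_rate": 0.026002373041374767,
    "potency": 1.5,
    "production_rate": 0.3900355956206215,
    "proliferation_gain": 3.9
  },
  "nanoparticle": {
    "clearance_rate": 0.19501779781031076,
    "degradation_rate": 0.06500593260343691,
    "diameter": 100.0,
    "payload_mass_fraction": 1.0,
    "pore_diameter": 400.0,
    "vascular_permeability_ref": 0.009
  },
  "species": {
    "assumed_bsa": 1.9,
    "body_weight": 70.0,
    "name": "human",
    "plasma_volume": 2900.0,
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
}
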