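{
 "human_profile": {
  "assumed_bsa": 1.9,
  "body_weight": 70.0,
  "name": "human",
  "plasma_volume": 2900.0,
  "tumor_interstitial_fraction": 0.4
 },
 "rules": {
  "checkpoint.ici_clearance_rate": {
   "class": "rate_constant"
  },
  "checkpoint.ici_interstitial_degradation": {
   "class": "rate_constant"
  },
  "checkpoint.ici_molecular_weight": {
   "class": "invariant"
  },
  "checkpoint.ici_permeability": {
   "class": "invariant"
  },
  "checkpoint.immune_kill_max": {
   "class": "population_average",
   "human_value": 0.047
  },
  "checkpoint.inhibition_constant": {
   "class": "invariant"
  },
  "checkpoint.kd_atezolizumab": {
   "class": "invariant"
  },
  "checkpoint.kd_pd1_pdl1": {
   "class": "invariant"
  },
  "checkpoint.kd_pembrolizumab": {
   "class": "invariant"
  },
  "checkpoint.pd1_equilibrium": {
   "class": "invariant"
  },
  "checkpoint.pd1_turnover": {
   "class": "rate_constant"
  },
  "checkpoint.pdl1_degradation": {
   "class": "rate_constant"
  },
  "checkpoint.pdl1_production": {
   "class": "rate_constant"
  },
  "checkpoint.pdl1_repression_constant": {
   "class": "invariant"
  },
  "chemo.base_ic50": {
   "class": "invariant"
  },
  "chemo.clearance_rate": {
   "class": "rate_constant"
  },
  "chemo.interstitial_degradation": {
   "class": "rate_constant"
  },
  "chemo.kill_max": {
   "class": "population_average",
   "human_value": 0.01988423825917028
  },
  "chemo.resistance_gain": {
   "class": "invariant"
  },
  "chemo.tumor_permeability": {
   "class": "invariant"
  },
  "growth.carrying_capacity": {
   "class": "population_average",
   "human_value": 26.8788945067861
  },
  "growth.initial_cell_volume": {
   "class": "invariant"
  },
  "growth.intrinsic_growth_rate": {
   "class": "population_average",
   "human_value": 0.020957935664806495
  },
  "mirna.antagonist_degradation": {
   "class": "population_average",
   "human_value": 0.5011535918089695
  },
  "mirna.antagonist_gain": {
   "class": "invariant"
  },
  "mirna.antagonist_potency": {
   "class": "population_average",
   "human_value": 1.9072287774806194
  },
  "mirna.degradation_rate": {
   "class": "rate_constant"
  },
  "mirna.exosomal_transfer_rate": {
   "class": "rate_constant"
  },
  "mirna.potency": {
   "class": "invariant"
  },
  "mirna.production_rate": {
   "class": "rate_constant"
  },
  "mirna.proliferation_gain": {
   "class": "population_average",
   "human_value": 3.9
  },
  "nanoparticle.clearance_rate": {
   "class": "rate_constant"
  },
  "nanoparticle.degradation_rate": {
   "class": "rate_constant"
  },
  "nanoparticle.diameter": {
   "class": "invariant"
  },
  "nanoparticle.payload_mass_fraction": {
   "class": "invariant"
  },
  "nanoparticle.pore_diameter": {
   "class": "invariant"
  },
  "nanoparticle.vascular_permeability_ref": {
   "class": "invariant"
  },
  "transport.cytosol_fraction_cancer": {
   "class": "invariant"
  },
  "transport.cytosol_fraction_tam": {
   "class": "invariant"
  },
  "transport.diffusivity_scale": {
   "class": "invariant"
  },
  "transport.intercapillary_length": {
   "class": "invariant"
  },
  "transport.uptake_fraction_cancer": {
   "class": "invariant"
  },
  "transport.vascular_surface_density": {
   "class": "invariant"
  }
 }
}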