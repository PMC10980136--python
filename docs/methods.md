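# Methods

## Model structure

The model couples a plasma compartment (site of administration and systemic
clearance) to a tumor compartment (interstitium + cancer cells, TAMs and
CD8+ T cells treated as fixed effective fractions) with 16 states: NP-borne
anti-miR-155 mass in plasma and interstitium; intracellular anti-miR-155
(mg/mL) in cancer cells and TAMs; miR-155 (pM) in both cell types; free
PD-L1 (pM) on both cell types; free PD-1 (pM); cisplatin, atezolizumab and
pembrolizumab masses in plasma and interstitium; tumor volume (cm³). All
fluxes are mass-action and mass-conserving; units are days, cm³ (= mL), mg,
mg/kg, pM, and nm for particle diameters.

Key constitutive choices:

* **NP permeability** is a Renkin-type hindrance of a reference
  permeability, `P_NP = P_ref (1 − Φ_NP/Φ_pore)²`, zero at or above the pore
  diameter — one extra parameter encodes "smaller particles permeate
  better".
* **Interstitial delivery to cells** is lumped into a diffusive rate
  `k_diff = D_NP/Len²` with `D_NP ∝ 1/Φ_NP` (Stokes–Einstein form);
  endocytosis and payload release are not resolved separately. Released
  payload distributes into small effective cytosolic volume fractions of the
  tumor (defaults 2×10⁻⁴ for cancer cells, 5×10⁻⁵ for TAMs), chosen so
  intracellular concentrations sit on the mg/mL scale probed by the
  antagonist potency.
* **miR-155** is produced at `g0_M` and degraded at `δ_M`, with the
  antagonist multiplying degradation by `1 + A_AM,M·AM/(EC50_AM+AM)`.
  TAM-to-cancer exosomal transfer (`k_exo·M_TAM`) is compensated in the
  cancer-cell production term so both cell types share the 1.5 pM
  pre-treatment equilibrium. `A_AM,M = 150` puts the fully suppressed level
  at 1.5/151 ≈ 0.01 pM.
* **PD-L1** production is repressed by miR-155 through
  `k_ML/(k_ML + M)` with `k_ML = 1.5/9 pM`, anchoring a 10-fold steady-state
  rise under complete knockdown. PD-1 is a constant-turnover pool with a
  1 pM equilibrium. The immune-kill attenuation
  `ψ = K_inh/(K_inh + [PD1:PDL1])` uses the PD-1:PD-L1 complex from the
  two-species competitive binding equilibrium with both antibodies (closed
  quadratic solution per step; antibodies are assumed non-depleted since
  their interstitial concentrations exceed the pM-scale receptor pools by
  orders of magnitude).
* **Tumor volume** follows logistic growth boosted by miR-155
  (`Φ(M) = 1 + (A_M,L−1)·M/(k_M+M)`) minus saturable cisplatin kill (with
  the miR-155-inflated IC50 as the resistance abstraction) and checkpoint-
  gated immune kill `δ_T·ψ`.

Dosing is an instantaneous plasma-mass increment (`mg/kg × body weight`)
with the integrator (LSODA, rtol 1e-7) restarted at every event;
simultaneous same-drug events sum, and a dose at t = 0 is applied before the
first step. Sub-tolerance negative excursions are clipped to zero;
excursions beyond −1e−6 abort with a numerical-integrity error. Halving the
tolerances moves end-of-treatment volume by far less than 0.1%.

## Parameter provenance

The shipped **mouse defaults** (`src/antimir/data/mouse_default.json`) mix
standard physiology (0.02 kg body weight, 1 mL plasma, interstitial fraction
0.4, 100 nm particles against 400 nm pores) with values tuned by bounded
least squares against six anchors: control growth (0.05 → ~0.9 cm³ over
four weeks) and end-of-treatment TGI of 62/49/86/16/18% for the five
packaged treatment arms (anti-miR-155 0.2 mg/kg twice weekly from day 7;
cisplatin 8 mg/kg weekly; their combination; atezolizumab 10 mg/kg and
pembrolizumab 5 mg/kg twice weekly; all evaluated at day 28). The tuned set
is {γ, A_M,L, δ_T, δ_C, R_C, IC50}; the achieved TGIs are 61.7/48.8/86.5/
17.0/17.0%. The two antibody arms saturate checkpoint blockade at these
doses and are therefore nearly indistinguishable (~17%), which both anchors
tolerate.

**Human parameters** are produced by
`scale_parameter_set(mouse_defaults, scaling_rules)`. Rate-like parameters
scale by `(BW_h/BW_m)^−0.25`, physical permeabilities, concentrations,
affinities and dimensionless gains are invariant, and five parameters are
population-average overrides (γ, K, A_M,L via the shipped rule table plus
δ_T and δ_C): pure allometry makes the standard-of-care arms clinically
inert, so these were tuned once against clinical anchors — a 1.5 cm baseline
tumor 124 weeks after a single founding cell, untreated time-to-progression
near 1.4 months, cisplatin monotherapy TTP ≈ 2.8 months, anti-miR-155 at
2.5 mg/kg Q3W ≈ 6.5–6.9 months, and ~32%/flexible TGI at the 0.026 mg/kg
human-equivalent dose (Q3W vs QW ordering preserved). The intracellular
antagonist degradation rate (0.5/day) and potency are also population
averages: a −0.25-scaled degradation rate cannot produce the near-complete
inter-dose depletion that the Q3W clinical profile shows, and the duty cycle
of suppression is what creates the shallow (n ≈ 1) dose-response over four
dose decades.

The **dose-scaling exponent**: the package's human-equivalent-dose helper
uses A = −0.25, which maps 0.2 mg/kg (mouse) to the reference 0.026 mg/kg;
the conventional −0.33 dose exponent is available via the `exponent`
argument. Clinical unit conversions assume a 70 kg, 1.9 m² reference
patient (75 mg/m² ≡ 2.04 mg/kg; 1200 mg ≡ 17.14 mg/kg; 200 mg ≡ 2.86 mg/kg).

## Response endpoints

TGI(t) = 100·[(V_ctrl − V0) − (V_trt − V0)]/(V_ctrl − V0) at end of
treatment, undefined unless the control arm has grown. RECIST 1.1 is applied
to the spherical-equivalent diameter of the single modeled lesion:
progression requires ≥20% growth over the nadir (smallest diameter since
treatment start, baseline included) **and** an absolute 0.5 cm increase;
partial response is ≥30% shrinkage from baseline; complete response uses a
1 mm detectability floor (never reached in practice). Assessment is daily on
the simulation grid — continuous in-silico monitoring — with a configurable
grid for trial-realistic cadences. TTP converts at 30.44 days/month;
patients without progression are censored at the 36-month follow-up
horizon.

## Calibration, sensitivity, trials, synergy

* **Calibration** pools squared volume residuals across all arms with
  per-arm mean normalization (log-residuals optional), optimized by bounded
  trust-region least squares with an explicit finite-difference step (1e-4)
  above the integrator noise floor, optional seeded multi-start (default 8,
  seed 20240314), bound-pinning flags, and Pearson-r goodness of fit.
  Because the original digitized in-vivo tables are not redistributable, the
  packaged calibration inputs are the synthetic-data module's paper-like
  five-treatment/two-control bundles (twice-weekly caliper times, lognormal
  replicate noise); this is a stated substitution, not a hidden one.
* **Sensitivity**: LSA sweeps one parameter over ±50% multipliers; GSA draws
  replicated LHS designs (defaults 500 samples × 20 replicates, seed 155)
  over 28 parameters, regresses standardized TGI on standardized
  multipliers, and ranks parameters by |SI| into Tukey-HSD letter groups
  (greedy compact-letter heuristic, α = 0.05). Both hold the baseline tumor
  volume fixed at the unperturbed patient's 124-week value so perturbations
  act on treatment dynamics, not on re-growing the baseline — without this,
  growth-rate perturbations explode the baseline through 2.4 years of
  compounding and TGI becomes meaningless.
* **Virtual cohort**: independent lognormal multipliers
  (σ_log = ln(1.3)/1.96, ~95% of proposals within ±30%) on the ten
  GSA-sensitive biological parameters; untreated growth to week 124 uses the
  closed-form logistic solution of the drug-free system (verified against
  the full ODE); acceptance iff baseline diameter ∈ [1.0, 2.68] cm. The
  published volume window (0.5–10 cm³) and diameter window are mutually
  inconsistent at the lower edge (0.5 cm³ → 0.985 cm), so the diameter
  window governs. Default acceptance rate ≈ 19%.
* **Survival**: lifelines' product-limit estimator and Cox model stand
  behind the module; medians report as not-reached rather than infinite, and
  Cox fits with |log HR| > log(10⁴) or failed convergence are flagged as
  separated instead of reporting implausible point estimates (very high dose
  arms genuinely separate from control).
* **Synergy**: median-effect fits are linear regressions of log(fa/fu) on
  log dose over per-drug monotherapy grids run on the same cohort; the
  cohort-level effect fraction is the TGI of the mean tumor-volume
  trajectory, clipped to [0.001, 0.999] as the Chou-Talalay math requires.
  Screening samples 50 LHS dose vectors per combination between 0.01 mg/kg
  and the clinical dose (anti-miR-155 capped at 2.5 mg/kg), runs Q3W courses
  with cisplatin truncated at six cycles, and reports CI, class
  (0.3/0.9/1.1 thresholds) and median PFS. Condition mining is a greedy
  decision-stump conjunction over dose/fraction/total-dose thresholds,
  reported as descriptive precision/recall rules.

## Problem sizes

Defaults are the study conditions (1,000-patient cohorts, 20-dose grids,
500-sample GSA, 1,000-set prediction bands). The test suite exercises the
same code paths at smaller sizes it documents inline — e.g. a 200-patient
dose-ladder trial, 8-dose schedule grids, a 1,000-patient cohort-bounds
check — chosen as the smallest sizes at which the assertions are stable.

## What the synthetic data does and does not show

The generator emulates the modeled mean with multiplicative replicate noise;
recovery tests therefore demonstrate estimator correctness
(self-consistency), not fidelity to real xenografts, which carry
model-mismatch, measurement floors, correlated within-animal errors and
dropout that the generator omits. Likewise the virtual cohort varies ten
biological parameters but no covariates (age, PD-L1 expression, histology),
so between-arm comparisons are internally valid while absolute clinical
numbers inherit the calibration anchors.

## Known limitations

Single spherical lesion (no multi-lesion RECIST sums, no new-lesion rule);
no spatial transport or hypoxia; immune and TAM populations are static
effective fractions rather than recruited populations; TP53 mechanics are
abstracted into one resistance gain; antibody PK shares one clearance/
permeability pair for both ICIs, making their preclinical arms nearly
identical; carrying capacities (4 cm³ mouse, ~27 cm³ human) are tuning
choices, not measurements. The model's saturated-dose TGI (~89%) exceeds
what a bounded-effect Hill plateau would suggest because, unlike TTP, TGI
compounds exponentially over the six-month course; TTP/PFS endpoints are the
primary clinical readouts.
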