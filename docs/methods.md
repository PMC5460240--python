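# Methods

## Scope and model

`translearn` implements a translational population-pharmacokinetics
workflow: a mechanistic whole-body model for a parent–metabolite pair is
embedded in a hierarchical Bayesian mixed-effects model, fitted to sparse
plasma concentration–time data by MCMC, and the acquired knowledge —
population distributions of physiological and drug-specific parameters —
is transferred as prior information into subsequent analyses, ending in a
de-novo population prediction of a candidate drug in a new (diseased)
cohort. Because the clinical data the original studies rested on are not
public, the package ships a first-class synthetic-study generator with
known ground truth; every claim the test suite makes is a claim about
recovery of that truth.

## Whole-body model

The body is reduced to seven compartments per compound: gut lumen
(amount-only), gut wall, liver, kidney, arterial and venous plasma, and a
lumped rest-of-body tissue. This is a deliberate reduction of the much
finer organ lists of commercial PBPK platforms: it is the smallest
topology that still houses every process the workflow needs (oral
absorption, intestinal and hepatic metabolism, biliary-side efflux,
hepatic uptake, renal excretion, distribution) while keeping a full
hierarchical MCMC affordable on one CPU.

* **Circulation.** Plasma flows arterial → tissues → venous → arterial;
  the gut-wall outflow drains into the liver (portal vein). Reference
  plasma flows and organ volumes (73 kg adult) are fixed constants;
  volumes scale linearly with body weight, flows with the 3/4 power.
* **Distribution.** Tissue uptake is flow-limited with
  `Kp(organ) = 1 + f_lipid(organ)·10^logP·fu`. The rule is a stand-in for
  proprietary distribution models: any monotone-in-lipophilicity rule
  would serve; this one is fixed and recorded in `translearn/constants.py`
  so results are reproducible.
* **Endothelial barrier.** For very highly protein-bound drugs the
  capillary endothelium is a true barrier. An organ scale `s ∈ (0,1]`
  lets only the fraction `s` of the perfusing plasma equilibrate with
  tissue (outflow `(1−s)·C_in + s·C_tissue/Kp`), which conserves mass and
  reduces to the flow limit at `s = 1`. The torsemide models carry
  `s = 0.001` everywhere except the fenestrated liver (`0.1`), as printed.
  The barrier is **not** applied to the gut wall: the mucosa is modelled
  luminal of the endothelium because it is the absorption pathway — with a
  scaled gut wall, an absorbed dose of a strongly barrier-limited drug
  would be trapped in the enterocyte compartment and never reach plasma.
* **Absorption.** First-order gut lumen → gut wall with
  `ka = intestinal permeability × 20 cm⁻¹`. The effective-area constant
  was calibrated once so the mean-value midazolam model peaks between 0.5
  and 1.5 h after a 1 mg dose, and is never revisited. A single constant
  cannot also reproduce torsemide's clinical absorption speed from its
  much lower printed permeability; the torsemide profile is therefore
  absorption-limited. The synthetic study is self-consistent (generator
  and inference share the model), so this affects realism of the
  torsemide curve shape, not the validity of any recovery result.
  Dissolution capping by solubility is off by default.
* **Active processes.** Michaelis–Menten in the unbound plasma-equivalent
  concentration of the source compartment, with organ-local
  `Vmax = kcat × expression(protein, organ)`. Absolute enzyme abundance is
  absorbed into kcat (as in the source parameter tables); the relative
  expression amounts per organ are package constants chosen once so the
  mean-value models show pharmacologically plausible clearances
  (e.g. midazolam hepatic extraction ≈ 0.3–0.5), and they scale linearly
  with body weight. PGP/ABCB1 is modelled as gut-wall→lumen and
  liver→lumen efflux (canonical topology; the source states expression
  sites, not direction). OATP1B1 is venous-plasma→liver uptake — the
  direction/organ were unstated; this is an assumption. Metabolism with an
  unmodelled product (glucuronide, M5) drains into a terminal-metabolism
  ledger.
* **Renal clearance.** The tabulated `l/min/kg` values are interpreted as
  plasma clearance per kg body weight acting on total arterial plasma
  concentration and bypassing the endothelial barrier (glomerular
  filtration); the platform-internal semantics of the printed unit are
  not reproducible.
* **Units and numerics.** Amounts in µmol, concentrations µmol/l, time in
  hours at the API (minutes internally); mg→µmol conversion happens once
  at dosing, %→fraction once at parameter load. LSODA with rtol 1e-8,
  atol 1e-12; the kernel is numba-jitted with a plain-Python reference
  retained. The molar mass-balance ledger (all compartments + urine +
  terminal metabolism = dose) closes to machine precision; the package
  contract is 1e-6 relative.

## Hierarchical inference

Individual parameter vectors are conditionally independent draws from
population laws — lognormal for positive parameters (all defaults),
normal otherwise — whose location and spread are estimated. Observations
enter through a multiplicative lognormal residual model
(`log y ~ N(log f(θ), σ²)`, single σ estimated); the error model was an
open choice and multiplicative is the population-PK standard for
concentrations spanning decades. Sampling is Metropolis-within-Gibbs:
random-walk updates per individual (one forward simulation per proposal),
an exact conjugate normal update of each population mean (random-walk when
its prior is uniform), and log-scale random walks with half-normal priors
(scale 0.5) for the population SDs and σ, both evaluated on cached
residual summaries so they cost no simulations. Proposal scales adapt
toward 20–40 % acceptance only during a declared adaptation window (first
quarter of the chain), preserving detailed balance afterwards.

Convergence follows the single-long-chain strategy: the chain is cut into
four segments that play the role of parallel chains in the
potential-scale-reduction statistic, and burn-in is the first point on a
candidate grid where all finite R̂ of the remainder drop below the
threshold (default 1.1). A posterior subsample of *n* (default 500) draws
is taken one-per-block at stride `floor(remaining/n)` to suppress
autocorrelation.

The default estimated-parameter set per learning step is deliberately
small — the liver-volume factor (physiological) plus the catalytic
constant of every metabolism process of parent and metabolite
(drug-specific) — because the sparse 8-point design cannot identify much
more, and the exact estimated list of the original analyses was never
published. Default priors: lognormal centred on the mean-value parameters,
sd 0.5 (log scale) for catalytic constants, 0.25 for the liver factor.

## Translational workflow

Acquired knowledge is carried parametrically: the maximum-posterior
population estimates (mean, sd) become the new distributions, which is
exactly what the virtual-population step consumes. Step 3 (reference drug
in the diseased cohort) starts its physiological priors from the package
defaults by default (`step3_physiology_source: initial`); wiring it from
the step-1 posterior is a config switch, since the original description
leaves this open. Learning is quantified per parameter by
KL(acquired ‖ initial): closed form within a family, quadrature across
families, `NaN` where a parameter was not in a step's model. The step-4
prediction composes candidate-drug knowledge (step 2) with target-cohort
physiology (step 3) and simulates a virtual population; a provenance audit
refuses states whose history contains candidate-drug observations from
the target cohort.

**Benchmark convention.** The "initial" simulation that normalizes the
RMSE comparison represents the pre-study state of knowledge: initial
parameter distributions *and* healthy-cohort anthropometric assumptions.
The diseased cohort's anthropometry is treated as part of what the study
teaches, so the prediction is credited for it. Normalized RMSE divides the
candidate median curve's pooled weighted-residual RMSE over all observed
datasets by the benchmark curve's; the benchmark scores exactly 1 by
construction. Residual weighting is relative (observation-scaled),
config-switchable, since the original weighting was not defined.

## Virtual populations

A virtual individual is an anthropometric draw — uniform in age, height
and weight with BMI-consistency rejection; obese-dominant cohorts draw BMI
from a two-component mixture split at BMI 30 (72 % above by default) —
plus a parameter vector drawn from the knowledge distributions. Percentile
bands are empirical pointwise 2.5/97.5 percentiles over (default) 500
individuals; the mean curve is the arithmetic mean across individuals
(the mean-parameter simulation is available separately), and the median
curve is the one evaluated by normalized RMSE.

## Synthetic-study generator

The generator defines the study conditions: two cohorts with the
published anthropometric ranges (healthy 18–56 y, 48.5–113 kg,
1.54–1.94 m, BMI 18.8–32.3; diseased 20–77 y, 52–206 kg, 1.56–1.92 m, BMI
19.7–67.1, 72 % obese); 30 % geometric CV on kinetic parameters and 15 %
on the liver-volume factor (typical PK interindividual variability; the
original values are unpublished); a diseased-cohort pathophysiology of
CYP3A4 activity ×0.7 and CYP2C9 activity ×1.5 (the reported directions);
multiplicative lognormal residual noise σ = 0.15; 5 % CYP2C9 *3/*3
poor-metabolizer outliers in the healthy cohort (activity factor 0.2 —
the factors are assumptions, only the phenotype is established). Learning
steps exclude flagged poor metabolizers by default, mirroring study
practice of setting genotype-explained outliers aside. Histology metadata
(steatosis, lobular inflammation, ballooning) follow an ordinal model
monotone in body weight; an expression surrogate per enzyme is the log of
the individual's true catalytic constant plus noise, giving correlation
analyses a known positive truth.

What the generator does **not** emulate: model misspecification (the
inference fits the same structural model that generated the data), real
assay error structure, dropout/sampling irregularities, covariate effects
beyond body size, and the four other cocktail drugs. Passing recovery
tests therefore demonstrate the statistical machinery, not structural
identifiability against a mismatched reality.

## Problem sizes and numerical choices

Desk-scale defaults are used throughout the shipped configurations and
checks: learning steps of up to 20 individuals (the phase-I/II-typical
size), chains of 1.5–20 k iterations depending on purpose, virtual
populations of 100–500, credible-interval coverage over 20 replicate
syntheses of 4 individuals each, and a 5-seed panel for the end-to-end
ordering check (prediction beats the initial benchmark; the retrospective
re-fit is at least as good). Full-scale settings (150 k iterations,
50 k burn-in, subsample 500) are plain config values. Ties in Cmax take
the earliest time; zero observations under relative weighting fall back to
additive weight for that point; a constant chain reports R̂ as NaN with a
warning; solver round-off negatives in reported concentrations are clipped
at zero.

## Known limitations

* The compartment reduction, partition rule, expression constants and
  renal-clearance interpretation mean simulated curves are *plausible*,
  not validated against clinical data; nothing here reproduces the
  numerical output of the commercial platform the original models were
  built in.
* The single absorptive-area constant cannot fit both drugs' absorption
  kinetics (see above).
* Identifiability of the liver-volume factor is weak under the sparse
  design; its posterior partly absorbs clearance variability.
* KL is computed between population-level parameter distributions, not
  joint posteriors; correlations between parameters are invisible to the
  heat map.
* Short desk-scale chains may not pass the R̂ gate; learning steps then
  refuse to emit knowledge unless forced, and the shipped demo
  configuration forces with the diagnostics retained.
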