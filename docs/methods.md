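# Methods

This package re-implements, as a tested pipeline, a longitudinal
shear-wave-elastography (SWE) analysis for early prediction of breast-cancer
response to neoadjuvant chemotherapy (NACT): feature derivation from
three-visit SWE/MRI measurements, residual-cancer-burden (RCB) response
labeling, St. Gallen subtyping, responder/non-responder group comparisons,
and leave-one-out cross-validated (LOOCV) ROC prediction models.  Because
the underlying patient data are not deposited, the pipeline is exercised and
validated on a synthetic cohort whose configuration encodes the published
per-group, per-visit summary statistics.

## Feature derivation

Each visit contributes three 3-mm tumor regions of interest (ROIs) at the
stiffest part of the lesion and one normal-tissue ROI; the scanner reports
mean/min/max shear-wave speed (SWS, m/s) per ROI.  Tumor SWS statistics are
the arithmetic means of the three ROIs, statistic by statistic (the mean of
the per-ROI minima is the "averaged minimum SWS" V_min).

* **SWS → elasticity.** The scanner's conversion formula is not published;
  we adopt the standard linear-elastic relation E = 3·ρ·c² with
  ρ = 1000 kg/m³, i.e. E[kPa] = 3·c² for c in m/s.  The density constant is
  an argument of `sws_to_elasticity` so an alternate calibration can be
  configured.  E_mean and E_max are the conversions of the aggregated mean
  and maximum SWS.
* **Tumor-to-normal ratios.** Whether the original ratios were formed on the
  elasticity or the speed scale is not stated; we default to elasticity
  (`ratio_scale="elasticity"`), under which the ratio equals the squared
  speed ratio, and expose `ratio_scale="speed"` as an option.
* **Mass characteristic frequency.** f_mass = 1000·V_min/d (Hz), with d the
  greatest B-mode mass dimension (mm) — physically the inverse of the
  maximum shear-wave transit time across the mass.  Full precision is kept
  internally; displayed values are rounded to integer Hz (the published
  worked example, V_min = 2.7 m/s and d = 28 mm, prints as 96 Hz from
  96.43).
* **Change scores** are always earlier minus later (visit 1 − visit 2,
  visit 1 − visit 3) and require both visits; a rising f_mass therefore
  yields a negative change score.
* **MRI volume** is the product of the AP × trans × SI dimensions.  A
  separate utility implements percentage-enhancement volumetry,
  PE = (S1−S0)/S0 × 100%, counting voxels with PE ≥ the threshold
  (default 70%, boundary inclusive).
* Missing inputs propagate as NaN, never as zeros.

## Pathology scoring

RCB = 1.4·(f_inv·d_prim)^0.17 + [4·(1−0.75^LN)·d_met]^0.17, exactly as
printed in the source protocol (a simplified single-dimension form of the
MD Anderson definition; the printed form is the contract here).  Categories:
0 (RCB = 0), I (0 < RCB ≤ 1.36), II (1.36 < RCB ≤ 3.28), III (RCB > 3.28);
upper bounds inclusive.  Responders are categories 0/I; II/III and patients
who never reached surgery are non-responders.  Categories are serialized as
the strings "0"/"I"/"II"/"III" to avoid 0-vs-"0" ambiguity in CSV.

ER/PR are positive at ≥ 1% immunoreactive cells.  HER2 is positive at IHC
3+ or IHC 2+ with FISH amplification; IHC 2+ without FISH is explicitly
unresolved.  St. Gallen subtype rules use Ki-67 < 14% to split Luminal A
from Luminal B (HER2−); ER+/HER2+ is Luminal B (HER2+) regardless of Ki-67.
ER−/PR+ combinations are not covered by the printed five-subtype rule list
and are assigned `unclassified` rather than guessed, as is any combination
needing an unresolved marker or a missing Ki-67.

## Synthetic cohort

The generator emits *raw* tables (per-ROI speeds, B-mode mass size, MRI
dimensions, IHC panels, RCB inputs), so every downstream stage runs exactly
as it would on real exports.

**Marginals.** Only mean ± SD per group and visit are published, so each
continuous variable uses a two-parameter positive family whose realized
moments equal the targets. Mass size, E_mean, E_max and Ki-67 use
zero-truncated (Ki-67: [0, 100]) Gaussians whose *parent* parameters are
solved numerically so the truncated distribution itself has the target mean
and SD.  The elasticity ratios and the MRI volume have target coefficients
of variation near or above 1 (V_MRI up to ≈ 2.4), which no zero-truncated
Gaussian can realize (its CV is bounded by ≈ 1); these use moment-matched
lognormals, which is also the natural shape for positive, strongly
right-skewed ratio/volume data.

**Dependence.** A Gaussian copula couples everything: each patient carries
a latent standard-normal factor; each (variable-block, visit) score is
√ρ·z_patient + √(1−ρ)·ε, giving within-patient across-visit correlation
ρ (default 0.5 — the study reports no longitudinal covariance, so ρ is an
acknowledged assumption surfaced in the config).  E_max shares its copula
score with E_mean within a visit (and E_max_ratio with E_mean_ratio), so
ordering violations are rare; a clip E_max ≥ E_mean guards the remainder.
Quantile-transforming copula scores leaves every marginal exact regardless
of the coupling.

**Speeds from elasticities.** Targets are inverted through c = √(E/3);
V_min is u·c_mean with u ~ U(0.7, 1.0); normal-tissue speeds derive from
the drawn ratios.  The three tumor ROIs are the aggregate plus centered
offsets, so averaging them reproduces the aggregate to machine precision —
and hence `visit_features_table` reproduces the generator's recorded ground
truth exactly, and f_mass is always exactly 1000·V_min/d of the latents,
never drawn independently.  Consequently f_mass is an *emergent* quantity:
its group means are not calibrated targets, and because f_mass ∝ 1/d its
cohort mean is sensitive to the smallest masses (visit-3 responder means
run higher than the published ones).  The qualitative pattern — f_mass
rising sharply for responders by visit 3, flat for non-responders — is
reproduced.

**Composition.** Subtype counts per group are fixed to the published table;
markers are constructed from the subtype slots.  The published marginals
are not exactly jointly satisfiable (the subtype-data-missing rows cannot
all carry fully resolved markers), so one responder is modeled as ER−/PR−
with HER2 2+/FISH-not-done (unclassified; HER2 resolved counts are off by
one against the published table), and two non-responders as ER−/PR+
(unclassified under the rule set) plus one ER+/HER2− with missing Ki-67.
Ki-67 for Luminal A / Luminal B (HER2−) patients is drawn from the group
marginal conditioned to < 14 / ≥ 14 so labels and values are mutually
consistent; group-level Ki-67 moments are therefore approximate.

**Pathology.** Responder RCB inputs are solved to hit a target score (35%
of responders at RCB = 0, a realistic pathological-complete-response rate;
the rest uniform in category I); non-responders split 60/40 between
categories II and III, with two patients flagged `no_surgery`
(non-responders by definition).  The published study does not report the
pCR fraction or the II/III split; both are config knobs.

**Missingness** is injected completely at random, per (group, visit),
leaving exactly the published numbers of patients with SWE and with MRI
data (the dropout mechanism behind the published counts is unknown; only
the counts are emulated).  Ki-67 missingness follows the published
measured/missing counts with the subtype constraints above.

## Group comparisons

Kruskal–Wallis (continuous) and Pearson chi-squared (categorical) are
implemented from the textbook formulas — rank-based H with tie correction
against χ²(k−1), and Σ(O−E)²/E without continuity correction — and
validated against scipy in the test suite.  Two-group comparisons still use
Kruskal–Wallis (equivalent to the rank-sum test up to the χ² approximation)
because that is the named procedure.  All-tied input returns H = 0 (limit
convention) rather than NaN.  Analysis is complete-case per variable; the
reported n is always the count of values actually used.  Raw p-values are
reported with significance at p < 0.05; no multiplicity adjustment is
applied (matching the source analysis).

## Prediction models

Six presets: noninvasive visit 1 {E_mean_ratio1, s1}, visit 2 {E_mean2,
s2}, visit 3 {E_max_ratio3, f_mass3} on all complete-case patients; mixed
models add Ki-67 and restrict to ER-positive tumors.  The classifier inside
LOOCV is unpenalized maximum-likelihood logistic regression — the minimal
standard choice for 2–3 features; the source analysis names only LOOCV —
standardized internally for numerics (predictions are affine-equivariant).
(Quasi-)separation in a training fold, detected as a standardized slope
beyond 30, falls back to a ridge-stabilized fit (C = 10³) with a warning.

Out-of-fold probabilities feed a threshold-sweep ROC; AUC is the
trapezoidal area, which equals the tie-aware Mann–Whitney concordance (a
property-tested identity).  The 95% CI is a stratified-bootstrap percentile
interval (B = 2000, seeded; widened if needed to contain the point
estimate, which percentile intervals on small discrete samples can
otherwise exclude).  The optimal cutoff is the ROC point closest to (0, 1)
in Euclidean distance, ties broken by higher sensitivity then higher
threshold; it is reported on the *probability* scale (feature-scale cutoffs
are not recoverable for multivariable models).  Paired AUCs are compared
with DeLong's test on the patients the two models share; the CI method and
comparison test are unstated in the source and are documented choices here.

## Problem sizes and numerical choices

Default analyses run at the study scale (62 patients).  Calibration checks
use 2000 patients per group, where each moment-matched marginal is verified
within 3 standard errors of its target — using the delta-method SE from the
truncated normal's exact kurtosis for SD checks (normal-theory σ/√(2n) is
badly wrong for skewed families), and exact normal theory on the log scale
for the lognormal variables.  Significance-pattern checks simulate 200
study-sized cohorts and compare rejection frequencies of the visit-1 and
visit-2 mean-elasticity group tests.  Floating-point self-consistency uses
rtol 1e-9; oracle equivalences use 1e-12 (AUC) and 1e-8 (LOOCV
probabilities).  All randomness flows from a single integer seed
(`numpy.random.default_rng`); identical (config, seed) yields byte-identical
artifact bundles, and the run manifest records the seed and SHA-256
checksums of every output.

## What passing tests do and do not show

The synthetic cohort reproduces published *marginal* summaries, counts and
missingness patterns — not the joint distribution of real tumors.  It
assumes Gaussian-copula dependence with a single ρ, MCAR dropout,
subtype-independent SWE distributions, and emergent (uncalibrated) f_mass
levels.  Published dataset-dependent numbers (the exact group-table values
and the AUCs of the six models) are not reproducible without the patient
data; the pipeline reproduces the *procedure*, validated against
independent oracles (exhaustive concordance, brute-force LOOCV refits,
scipy test statistics, R pROC for DeLong on a frozen fixture) and against
the generator's closed-form implied separation.  Performance estimates on
synthetic cohorts (e.g. the model report in the README) characterize the
generator's configuration, not the clinical cohort.
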