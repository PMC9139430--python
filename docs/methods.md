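# Methods

## Overview

`pulmodens` quantifies where in the irradiated lung CT density changes after
thoracic radiotherapy track pulmonary function, using three co-registered CT
volumes per patient (baseline `tpre`, and `t3m`/`t6m` at three and six months
post-RT), the planning dose grid, a lung mask and paired PFT measurements
(DLCO, FEV1). The analysis chain is:

1. **Subvolumes.** The lung is cut into isodose-defined subvolumes. Total
   volumes Vx% contain all lung voxels receiving at least x% of the
   prescription; differential volumes V(a−b)% contain voxels in the half-open
   interval [b, a)% (a = Dmax means no upper cut). The standard ladder runs
   105% … 5% in steps of 10.
2. **Density.** Per subvolume, time point and patient, the mean HU is
   normalized by the whole-lung mean HU of the same scan, giving the relative
   density number n_ρ = H̄U_subvolume / H̄U_lung. Aerated lung is strongly
   negative, so n_ρ is positive and below 1 for tissue more transparent than
   dense; densification *lowers* n_ρ.
3. **Per-patient correlation.** For each subvolume and PFT parameter, the
   Pearson correlation r over the three (n_ρ(t), PFT(t)) pairs, then the
   Fisher transform z = atanh(r). With three points |r| = 1 occurs with
   positive probability; |r| is clamped to 1 − 1e−7 (configurable) so z stays
   finite. Zero-variance series are *degenerate* and excluded (r is
   undefined; imputing 0 would bias the cohort mean); patients missing a
   time point are *insufficient* and likewise excluded from this stage.
4. **Cohort test.** A one-sample, right-tailed t-test of the cohort's z
   values against zero — the null is "no or negative correlation", since a
   density increase is expected to accompany functional loss. Bonferroni
   correction over the family of subvolumes tested (family size defaults to
   the number of cells in the run; an override of 10 is available). The
   triangle over (high, low) pairs with high ∈ {Dmax, 95, 85, 75, 65} and
   low ∈ {95 … 5} has 40 cells, each labelled with a three-tier significance
   code (high < 0.01, moderate < 0.05, ns) computed on the raw p-value; the
   corrected p-value is reported alongside.
5. **Temporal change.** Relative change (value(t) − value(tpre))/value(tpre)
   per patient for PFTs and n_ρ, with a two-sided paired t-test (sidedness
   configurable; two-sided is the conservative default).
6. **Volume-size prediction.** Across patients, the Pearson correlation
   between a subvolume's relative size (% of total lung) and the relative
   PFT change at a follow-up time point. A negative r means patients with
   more lung in that dose window lose more function.

## Dose conversions

EQD2 = D·(d + α/β)/(2 + α/β) with α/β = 10 Gy by default (tumor tissue);
at the reference fractionation d = 2 Gy it equals the physical dose for any
α/β. Isodose levels convert to Gy as level/100 × prescription. All rounding
(0.1 Gy) happens at report formatting, never inside computations: 65% of
73.8 Gy is carried as 47.97 and printed as 48.0.

## Frames and input contracts

All of a patient's volumes must share one voxel grid (shape, spacing and
origin equal within 1e−3 mm, tolerating header round-off). The package never
registers or resamples — upstream tooling owns that — and refuses mixed
frames instead. Subvolume masks are computed once from the planning dose and
reused for every time point. Whether the PTV is carved out of the lung mask
is a flag (default off: whole-lung normalization; the alternative mirrors
the clinical practice of excluding the target from organ-at-risk lung).
Missing PFT values or CT time points are allowed at ingest; each analysis
stage decides eligibility and reports exclusions explicitly.

## The phantom cohort generator

No clinical images ship with the package; every stage is validated against
synthetic cohorts with known ground truth. A phantom patient lives on a 48³
grid of 3 mm voxels: two ellipsoidal lungs (~12 500 voxels, ~335 mL — a
scaled-down thorax chosen to keep a 40-patient, multi-replicate simulation
cheap), a spherical tumor (radius 12 mm, lognormal-jittered per patient)
inside the right lung, and a dose field equal to the prescription (66 Gy in
3 Gy fractions) inside the tumor with exponential falloff (length scale
25 mm, per-patient lognormal spread σ = 0.3 emulating plan-conformity
differences).

**Planted signal.** Post-RT injury adds ΔHU = 300 · s_i · σ((dose% − 55)/10)
inside the lung at t3m, where s_i is a per-patient lognormal susceptibility
(σ = 0.4) and σ(·) the logistic function; at t6m 0.8 of the 3-month injury
remains. HU saturates at soft-tissue density (full consolidation). Lung
function declines proportionally to the *injury burden* — the
volume-weighted mean sigmoid response over the lung — via
PFT(t) = baseline · (1 − γ · burden(t)) · (1 + ε), with coupling γ = 0.3,
3% multiplicative measurement noise, and lognormal baselines around the
DLCO/FEV1 medians 5.3 mmol/min/kPa and 2.2 L. γ = 0 is the exact null
scenario used for calibration tests.

**Confounders.** Real follow-up CTs are not clean realizations of a dose
response, and a generator without the corresponding nuisance structure
validates too little: with three time points anchored at baseline, *every*
dose band with a systematic post-RT density increase correlates near-perfectly
with a declining PFT, and the "most informative subvolume" becomes a
coin-flip. The generator therefore includes the nuisance processes that, in
clinical data, make the high-dose bands uninformative:

* spatially correlated scan noise (Gaussian texture, correlation length
  2.5 voxels), so thin shells average few independent patches;
* erratic tumor mass dynamics between scans — lognormal radius factor
  (median 0.85, σ = 0.5, growth capped at ×1.15 since sub-acute progression
  is the separately flagged relapse case) plus a 1.5-voxel apparent position
  jitter per scan (residual registration error);
* erratic remodeling of the near-target injury (per-scan lognormal factor,
  weighted by a sigmoid in dose centred at 80%);
* a peritumoral atelectasis rim (thickness U(2, 10) mm, −150 HU) that at
  each follow-up either persists or resolves completely and irreversibly
  (the obstructed airway reopens or it does not).

The last mechanism matters most: atelectasis resolution moves near-target
density *down* while fibrosis moves it up, so bands within ~10 mm of the
tumor surface (the ≥75% isodoses at the default falloff) change with
patient-specific, function-independent sign and timing. Mid-dose bands —
the windows spanning the 55% sigmoid midpoint — stay clean, which is why the
strongest cohort correlation localizes there. We define this *mid-dose
block* as the triangle cells with high ∈ {75, 65} and low ∈ {55, 45, 35, 25}.
Across independent replicate batches (90+ cohorts) the most significant
triangle cell falls in this block in roughly 80% of replicates, the
fraction of patients with positive Fisher z for DLCO is ~0.9, and the
size-vs-DLCO-change correlation for V65−45% is negative (−0.4 ± 0.1).

Per-patient plan spread (the falloff σ) is what gives subvolume sizes
cross-patient variance and couples them to burden: a shallower falloff puts
more lung into the mid-dose window *and* increases the burden, so larger
relative V65−45% sizes predict larger DLCO declines. Without it (pure
tumor-radius variation) the phantom produces the *opposite* sign, because a
larger tumor pushes the mid-dose shell out of the lung while increasing
injury.

All randomness flows from a single seed through per-patient `SeedSequence`
substreams; cohorts are bit-reproducible and `run-all` output tables are
byte-identical across reruns with the same seed and configuration.

**What the phantom does not emulate:** realistic lung anatomy and lobar
structure, breathing motion and inspiration-level differences, scanner and
contrast-agent effects beyond stationary texture, pneumonitis as a distinct
acute phase, or relapse-driven image changes (relapse is a flag only, used
to exercise the sensitivity re-run). Passing tests therefore show that the
statistical machinery recovers the planted dose-response structure under
realistic nuisance processes — not that the clinical effect sizes of any
particular cohort would be reproduced.

## Numerical choices and degenerate inputs

* Half-open [low, high) dose intervals: makes consecutive differential
  volumes an exact partition of the lung; acceptance of a voxel sitting
  exactly on a threshold is therefore well-defined (it belongs to the band
  whose lower edge it matches).
* Differential-band means are computed from per-band count/sum accumulators
  (one pass per scan); this equals the mask-by-mask mean exactly, by the
  weighted decomposition mean(V(a−b)) = (N_b μ_b − N_a μ_a)/(N_b − N_a).
* Normalization refuses lungs with |mean HU| < 50 (a lung that dense
  indicates an input error; the ratio would be unstable).
* Zero-variance cohort z samples: p = 1 when the mean is 0 (no evidence), by
  convention, logged.
* Empty subvolumes raise with the patient/range/time point identity rather
  than propagating NaNs.
* Bonferroni: min(1, m·p); family size m defaults to the hypotheses actually
  run, with a configurable override (m = 10 for the prediction family).

## Reference problem sizes

The test-suite and the acceptance script use 40-patient cohorts on 48³
grids; null calibration uses 500 replicates of the statistics layer on one
set of precomputed densities (the γ = 0 scenario makes density and PFT
draws independent, so only PFTs need resampling); localization uses 50
independent full cohorts. These sizes give Monte-Carlo standard errors of
~0.01 on the type-I error and ~6 percentage points on the localization
rate.

## Known limitations

* The two-ellipsoid lung and spherical tumor make subvolume geometry far
  more regular than clinical anatomy; relative-size distributions are
  narrower than in real cohorts.
* The burden→PFT link is linear and instantaneous; real DLCO dynamics lag
  and saturate.
* With extreme falloff draws, very narrow low-dose bands (e.g. V25−15%) can
  be empty on the phantom geometry; the analysis raises rather than
  imputing, and the standard triangle/prediction families avoid such bands.
* The α/β default (10 Gy) is the tumor value; organ-at-risk analyses should
  pass their own.
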