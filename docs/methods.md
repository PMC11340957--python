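# Methods

## Signal model and biomarker definitions

The phantom and the extraction code share one signal model, chosen because
it is the model the sFF formula presumes.

**Two-point Dixon (magnitude images).** A voxel with water density W and
fat density F produces `SI_in = W + F` and `SI_out = |W − F|`. The signal
fat fraction computed downstream,

    sFF = (SI_in − SI_out) / (2 · SI_in),

equals `F/(W+F)` whenever W ≥ F. Because the magnitude pair is symmetric
in (W, F), a fat-dominant voxel is indistinguishable from its
water-dominant mirror and the recovered fraction is `min(W,F)/(W+F)`.
This aliasing is asserted in the tests rather than hidden: `compute_sff`
never clips its output, and values outside [0, 0.5] are flagged, not
altered. Whether the out-of-phase term should enter signed or absolute
when noise pushes `SI_out > SI_in` is genuinely ambiguous at the
ROI-mean level; we keep the arithmetic as written and emit a warning.

**Enhancement.** The fat-sat series uses a multiplicative fraction on the
non-contrast baseline: `SI_phase = S0 · (1 + E_phase)` for the arterial,
portal-venous and delayed phases. No pharmacokinetic time-curve is
modelled — the protocol samples three fixed time points (bolus-triggered
arterial, ~60 s, ~120 s), so the three E values are free parameters per
structure. The contrast enhancement fraction
`CEFR = (SI_ce − SI_nc)/SI_nc` recovers E exactly in the noiseless case.
A non-positive baseline raises an error: non-enhancing exams are a
rejection category, not a NaN.

**Bilateral pooling.** The default (`bilateral="pool"`) averages the
left/right PSM ROI mean signals first and applies the formula once; the
per-muscle-then-average alternative is exposed but not default. The two
orders coincide when the muscles are symmetric and differ in general
because the formulas are ratios.

**SMI.** Mean of the two PSM areas divided by height squared (cm²·m⁻²).
ROI area is voxel count × voxel area; the phantom rasterizes a voxel into
a structure iff the voxel *center* lies inside the ellipse, which makes
the analytic-area tests exact statements about the rasterization rule
(observed: ~0.6% area error for a 20 × 10 mm ellipse at 1 mm spacing,
falling at least linearly with spacing).

**MELD.** Classic pre-sodium UNOS variant: labs clamped to ≥ 1.0,
creatinine capped at 4.0 (forced to 4.0 on dialysis),
`10·(0.957 ln Cr + 0.378 ln Tbili + 1.12 ln INR + 0.643)` rounded
half-up, bounded to [6, 40]. The sodium-corrected variant is not
computable from the collected variables (no sodium column), which is why
the classic equation is the right one here.

**Lin's CCC** uses population (1/n) moments:
`2·cov(x,y) / (var x + var y + (mean x − mean y)²)`. It is bounded by
|Pearson r| with equality iff the two series share mean and variance — a
property test, not an assumption.

## Phantom noise

Default noise is additive Gaussian (σ configurable, 0 by default so
recovery tests are exact); Rician noise — the magnitude of a complex
Gaussian perturbation — is available for realism at low SNR. Gaussian
noise can produce negative voxels; readers preserve them (no silent
clipping) so that downstream statistics see the data as stored. For ROI
means over n voxels the CEFR standard error is approximately
σ·√2 / (S0·√n) ≈ 5·10⁻⁴ at σ = 2, S0 = 200, n ≈ 800, which motivates the
±0.01 tolerance used in the noisy-recovery tests.

## Cohort simulator

The simulator exists to exercise the statistics pipeline end-to-end, with
known truth, at the reference cohort's conditions (n = 224 by default).

- **Copula.** Continuous variables (age, BMI, albumin, creatinine,
  bilirubin, INR, sFF, SMI, three CEFRs) are drawn from a Gaussian copula.
  Pairwise targets are the published signed biomarker–laboratory
  correlations plus the two reported biomarker–biomarker pairs;
  unspecified pairs default to zero. The latent matrix is repaired to the
  nearest positive-semidefinite matrix by eigenvalue clipping; if the
  repair moves any entry by more than 0.1 the targets are declared
  inconsistent and the simulator raises.
- **Moment-matched latent correlations.** Because Pearson correlation is
  not preserved through non-linear marginal transforms, latent
  correlations are adjusted with the closed-form normal/log-normal
  moment-matching identities so the *observed-scale* correlations hit the
  targets (a log-normal as skewed as bilirubin would otherwise attenuate
  its correlations by ~25%).
- **Marginals.** Normal for age, BMI, albumin, SMI and the CEFRs;
  log-normal for creatinine, bilirubin, INR (printed SD above half the
  printed mean implies right skew, and labs are positive) and for sFF
  (same rule, and fractions should stay positive).
- **MELD is never drawn.** It is recomputed from the simulated labs, so
  the stored column is internally consistent by construction. The
  emergent population MELD mean under these marginals is ≈ 11.3 ± 3.7
  versus the reference 10.9 ± 5.3 — the printed lab marginals do not pin
  down the joint tail behaviour that MELD inherits, and we do not bend
  the marginals to force agreement.
- **Binaries.** One shared latent severity score — the MELD-coefficient-
  weighted sum of the latent laboratory z-scores — is mixed with
  per-binary noise according to a loading in [0, 1) and thresholded at
  the sample quantile matching each prevalence, so counts are exact and
  severity-linked group differences (e.g. lower CEFR-PV with paracentesis
  history) emerge jointly. Default loadings (ascites 0.6, paracentesis
  0.6, varices 0.5, variceal bleed 0.4, SBP 0.4, TIPS 0.3, sex/diabetes/
  thyroid 0) are stated assumptions that reproduce the reported
  directions, not published facts. Ordinal grades (ascites volume,
  variceal size) are assigned among positives by severity rank with the
  published composition.
- **Height** is not among the published descriptives; we draw
  sex-conditional normals (M 1.76 ± 0.07 m, F 1.62 ± 0.07 m, clipped to
  [1.30, 2.10]) as a realistic adult distribution.

What the simulator does *not* emulate: missing-data patterns, lab–lab
correlations (zero by default), measurement error in the ROI placement,
and the comparison-table cell values themselves — those are emergent.
Passing tests therefore demonstrate that the pipeline recovers configured
structure, not that real data would show the same effect sizes.

## Statistics engine

- Two-group cells: Shapiro–Wilk per group at α = 0.05; both normal →
  Welch's t; otherwise Mann–Whitney U. Which published rows used which
  test is unknown, so every cell records `test_used`, the p-value of the
  *other* test, and whether the significance call at 0.05 flips — a
  built-in sensitivity analysis. Means ± SD are always reported, even for
  nonparametric rows.
- Mann–Whitney p-values: exact enumeration of the permutation
  distribution when C(n₁+n₂, n₁) ≤ 10⁵ (valid with ties, unlike the
  classical exact tables), tie-corrected normal approximation otherwise.
  Constant groups fall through to the rank test with a warning.
- Pearson cells: Fisher-z CI `tanh(atanh r ± z/√(n−3))`, p from the
  t-transform on n − 2 df, complete cases only, |r| ≈ 1 clamped with a
  warning. The one fully specified published interval (r = 0.36,
  n = 224 → 0.24–0.47 at 2 dp) is reproduced exactly.
- Categorical: Pearson chi-squared (no Yates correction) when all
  expected counts ≥ 5; otherwise Fisher exact on 2×2; a sparse 2×k table
  has its smallest-total column merged into the next smallest until
  expectations are adequate or the table is 2×2 (the number of collapses
  is reported).
- ROC: rank (Mann–Whitney) AUC with tie midranks; the identity
  AUC = U/(n₁n₂) is tested. Orientation is explicit: lower CEFR predicts
  the high-MELD group, so scores are negated and the orientation logged.
- Two-sided tests throughout; α = 0.05; no multiplicity correction in the
  primary cells (matching the analysis being reproduced) — a
  Benjamini–Hochberg column is attached as clearly supplementary.
- Missing data: complete-case per analysis, with n reported in every
  cell.

## Pipeline and reproduction harness

`load_cohort` resolves CSV headers through a normalised alias table (user
extensible), guards units (height median > 3 ⇒ centimetres, converted
with a warning), derives the imaging binaries from the ordinal grades
(any ascites including trace counts as present; any varices including
small counts as present — inferred from how the published grade
categories collapse into the binary comparisons), recomputes MELD from
labs and reports discrepancies against any stored MELD column. The
MELD > 17 dichotomy is the default threshold and is configurable.

`run_analysis` is deterministic given its input (byte-identical JSON);
display rounding (biomarkers and r to 2 dp) is applied only at the CSV
layer, JSON keeps full precision. `reproduce` diffs every recomputed cell
against the bundled reference values using half a unit in the last
printed decimal as the agreement criterion and reports — never hides —
disagreements. On synthetic cohorts the count cells agree exactly (the
simulator hits prevalences by construction) while continuous cells carry
sampling error; the full cell-by-cell check is meaningful only with the
real per-patient datasheet, which is patient-level data and not
redistributed.

## Problem sizes used in the test and acceptance runs

Phantom grids 96×96–320×320 at 0.5–2 mm; correlation recovery at
n = 10⁵; CI coverage with 2 000 replicates at n = 224; null-calibration
over 25–40 simulated 224-patient cohorts (≥ 2 000 p-values); severity
coupling demonstrated at n = 2 000 and sign patterns at n = 20 000. These
sizes give Monte-Carlo error comfortably inside the asserted tolerances
(e.g. coverage SE ≈ 0.5% at 2 000 reps against a ±1% band).

## Known limitations

- Single-slice 2-D analysis; masks are inputs (no segmentation).
- Two-point Dixon only: no T2* correction, no multi-echo PDFF
  calibration; sFF is a signal fraction, not a proton-density fat
  fraction.
- The aorta ROI is measured and stored but feeds no derived quantity —
  no aortic normalisation of CEFR is defined, and none is invented.
- The enhancement model has no kinetics; inter-phase timing variation is
  outside the model.
- Cohort binaries share a single severity axis; real comorbidity
  structure is richer.
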