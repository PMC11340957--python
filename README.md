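# psmbio

Paraspinous-muscle (PSM) MRI biomarkers for liver-cirrhosis severity:
extraction of three imaging biomarkers from multi-phase abdominal MR images
plus the cohort-level statistical comparison against clinical measures of
cirrhosis severity, with synthetic generators (an image-level phantom and a
copula-based patient-cohort simulator) so every stage is testable without
clinical data.

## Who this is for

Radiology / hepatology researchers quantifying sarcopenia and myosteatosis
on contrast-enhanced liver MRI, and anyone who wants a tested, reproducible
implementation of the muscle contrast-enhancement-fraction analysis — from
ROI signal means all the way to the comparison and correlation tables.

## The biomarkers

Measured in the bilateral paraspinous muscles at the level of the superior
mesenteric artery origin, from regions of interest on six co-registered
series (in-phase, out-of-phase, non-contrast T1 fat-sat, arterial,
portal-venous, delayed):

- **signal fat fraction** (myosteatosis surrogate), from the two-point
  Dixon pair:

  sFF = (SI_in − SI_out) / (2 · SI_in)

- **contrast enhancement fraction** per post-contrast phase (ART / PV /
  DEL):

  CEFR = (SI_ce − SI_nc) / SI_nc

- **skeletal muscle index** (sarcopenia surrogate): mean bilateral PSM
  cross-sectional area divided by height squared, in cm²·m⁻².

Clinical context comes from the classic (pre-sodium) UNOS MELD score
(10·(0.957 ln Cr + 0.378 ln Tbili + 1.12 ln INR + 0.643), clamped and
rounded, bounded to [6, 40]) and binary severity markers: ascites and
varices on imaging, paracentesis history, variceal-bleed history, SBP,
TIPS. The statistics engine follows the usual clinical-imaging recipe:
Shapiro–Wilk-screened Welch t / Mann–Whitney U group comparisons, Pearson
correlations with Fisher-z 95% CIs, chi-squared / Fisher exact tests, and
ROC analysis of CEFR against the MELD > 17 group (lower enhancement
predicts high MELD). Lin's concordance correlation coefficient is included
for inter-observer agreement checks.

## Worked example

Render a noisy two-muscle phantom with known composition (fat fraction
0.10, enhancement 0.10/0.22/0.25, baseline 200, Gaussian noise σ = 2) and
recover the biomarkers:

```python
from psmbio import (PhantomSpec, StructureSpec, render_phantom,
                    roi_stats, measure_biomarkers)

spec = PhantomSpec(
    shape=(96, 96), spacing_mm=(1.0, 1.0),
    structures=[
        StructureSpec(label="psm_left", center_mm=(60, 25), semi_axes_mm=(14, 9),
                      water_density=90, fat_density=10, s0=200,
                      enhancement=(0.10, 0.22, 0.25)),
        StructureSpec(label="psm_right", center_mm=(60, 70), semi_axes_mm=(14, 9),
                      water_density=90, fat_density=10, s0=200,
                      enhancement=(0.10, 0.22, 0.25)),
        StructureSpec(label="aorta", center_mm=(20, 48), semi_axes_mm=(6, 6),
                      water_density=100, fat_density=0, s0=300,
                      enhancement=(1.5, 0.8, 0.5)),
    ],
    noise_sd=2.0, seed=1,
)
images, masks, truth = render_phantom(spec)
panel = roi_stats(images, masks)
bm = measure_biomarkers(panel, height_m=1.75)
print(f"sFF      = {bm.sff:.4f}")
print(f"CEFR-PV  = {bm.cefr_pv:.4f}")
print(f"SMI      = {bm.smi:.2f} cm^2/m^2")
```

prints

```
sFF      = 0.1001
CEFR-PV  = 0.2202
SMI      = 1.31 cm^2/m^2
```

— the fat fraction and enhancement fractions land on the configured truths
to within the ROI-mean noise (≈5·10⁻⁴ here), and the SMI is the rasterized
ellipse area (4.00 cm² per muscle) over 1.75².

The same works from the shell: `psmbio phantom`, `psmbio measure`,
`psmbio cohort-sim`, `psmbio analyze`, `psmbio reproduce` (see `--help`).
`cohort-sim` writes a 224-patient synthetic datasheet with the reference
cohort's marginals, prevalences and biomarker–laboratory correlation
structure; `analyze` recomputes the descriptives table, the 5 × 6
comparison grid, the correlation grid and the ROC curves from any
S1-schema CSV; `reproduce` additionally diffs every cell against the
bundled published reference values and reports disagreements.

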