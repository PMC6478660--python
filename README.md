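# ezpet

Epileptogenic-zone (EZ) localization from interictal ¹⁸F-FDG PET by
single-subject statistical parametric mapping, with *dynamic* threshold
segmentation.

## The problem and the method

In medically refractory epilepsy, the EZ often appears as a subtle
hypometabolic region on interictal FDG-PET. `ezpet` compares one patient
study against a normative control cohort, voxel by voxel, and turns the
resulting statistical map into an anatomical call — a hemisphere (L/R) and
a sublobar location (mesial temporal MT, lateral temporal LT, combined
MLT, frontal F, parietal P, occipital O, insular I) — for presurgical
evaluation.

The processing chain:

1. **Spatial normalization** — 12-parameter affine registration to a PET
   template (multi-resolution sum-of-squared-differences), plus optional
   application of a precomputed nonlinear deformation field.
2. **Intensity normalization** — the global scale factor is the *mode* of
   the voxel-wise patient/reference quotient distribution, located by a
   parabola fitted around the maximum of the quotient histogram. Unlike a
   total-counts ratio, the mode is insensitive to focal defects.
   (SPM-style proportional scaling is available as an emulation mode.)
3. **Smoothing** — Gaussian, FWHM 8 × 8 × 8 mm.
4. **t-map** — per voxel over a gray-matter mask,

   ```
   t = (mean_controls − patient) / sqrt(s²_controls · (1 + 1/n)),   df = n − 1
   ```

   a pooled-variance two-sample Student-t with the patient as a singleton
   group; positive t = hypometabolism.
5. **Dynamic segmentation** — the t-map is re-thresholded across a whole
   grid of significance levels p ∈ [0.05 … 0.0001] and minimum cluster
   extents k ∈ [50 … 200] voxels in one pass (the programmatic equivalent
   of dragging two threshold scrollbars). Connected supra-threshold
   clusters outside the cortex or straddling the interhemispheric region
   are excluded; the biggest cluster (peak-t tie-break) yields the EZ call.

The package also reproduces the study-level evaluation statistics —
positive/localizing summaries, Cohen's κ with verbal concordance bands,
the exact binomial McNemar test, χ² and one-way ANOVA — from a packaged
30-patient study table, and ships a synthetic phantom generator so that
every imaging stage is testable at desk scale with known ground truth.

## Worked example

Generate a phantom dataset (20 controls + one patient with a 20%
hypometabolic lesion in the left mesial temporal blob), analyze it, and
evaluate the packaged study table:

```bash
ezpet simulate --seed 0 --out phantom/
ezpet analyze --patient phantom/patient.nii --controls phantom/ \
              --template phantom/template.nii --atlas phantom/atlas.nii \
              --atlas-table phantom/atlas_table.tsv --out run/
# -> EZ call: L/MT (24 sweep rows) -> run/
ezpet evaluate --erratum-fixture --out eval/
```

The `analyze` report (`run/report.json`) names the EZ call `L/MT` — the
seeded lesion — and `run/sweep.tsv` holds one row per (p, k) setting.
`evaluate` prints the per-method summary:

```
     method  positive  positive_pct  negative  negative_pct  localizing  localizing_pct
     visual        28          93.3         2           6.7          21            70.0
       spm1         1           3.3        29          96.7           0             0.0
       spm2        18          60.0        12          40.0          11            36.7
petanalysis        29          96.7         1           3.3          20            66.7
        mri        16          53.3        14          46.7          16            53.3
```

Reading: visual assessment detected a hypometabolic area in 28/30 studies
and correctly localized the surgically confirmed EZ in 21/30; the fixed
corrected threshold (spm1, p<0.05/k=50) was positive in a single study;
the fixed uncorrected threshold (spm2, p<0.001/k=100) localized 11/30;
the dynamic parametric analysis localized 20/30. `eval/evaluation.json`
adds the paired exact McNemar comparisons — visual vs spm2 p = 0.0309,
dynamic analysis vs spm2 p = 0.0117 — and per-method κ values with their
verbal bands.

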