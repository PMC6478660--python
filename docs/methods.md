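# Methods

## The statistical model

A patient study is tested against a normative cohort of n preprocessed
control studies with a per-voxel pooled-variance two-sample Student-t in
which the patient forms a singleton group:

t(v) = (m(v) − y(v)) / sqrt(s²(v) · (1 + 1/n)),

where m and s² are the cohort's per-voxel mean and unbiased variance and
y is the patient value. The singleton group contributes no variance
degrees of freedom, so df = n − 1. The sign convention makes positive t
mean hypometabolism (the clinically relevant direction in epilepsy); the
test is one-sided by default, switchable to two-sided. Voxels with zero
cohort variance receive t = 0 rather than ±∞: such voxels are background
artifacts and must not seed clusters; their count is recorded on the map.

Family-wise-corrected thresholding uses Bonferroni over the in-mask voxel
count. This is a deliberate design choice: it is exactly testable, and it
reproduces the qualitative behaviour that matters here — a corrected
threshold is drastically more conservative than any uncorrected setting.
Random-field-theory corrections and cluster-level corrected inference are
out of scope.

## Preprocessing

**Spatial normalization.** A 12-parameter affine (3 translations mm, 3
rotations rad, 3 scales, 3 shears; composition T·Rx·Ry·Rz·S·H about the
template center) is fitted by minimizing the sum of squared differences
over a 3-level dyadic multi-resolution schedule with Powell's method,
initialized from center-of-mass alignment. There is no random
initialization, so registration is deterministic. Same-modality PET pairs
make SSD an adequate metric; mutual information is unnecessary. Nonlinear
normalization is *consumed*, not produced: a precomputed dense
deformation field (world-mm displacements per target voxel) can be
applied by pull-back interpolation, but field estimation is delegated to
external registration tools.

**Intensity normalization.** The quotient-parabola method: voxel-wise
patient/reference quotients over the analysis mask are histogrammed
between their 1st and 99th percentiles into 100 equal-width bins; a
parabola is least-squares-fitted to the bin counts over the modal bin ± 3
bins, and the factor is the vertex abscissa clamped to the fitted window.
Defaults of 100 bins and half-width 3 give a stable mode estimate at
10⁴–10⁶ masked voxels. Degenerate cases (single-bin histogram,
upward-opening fit, non-positive vertex) fall back to the modal bin
center and are flagged in the diagnostics. The reference for controls is
the template; for the patient it is the mean of the already-normalized
control cohort (flag-selectable back to the template) — which reference
the quotient is taken against is an open choice, and the cohort mean is
the least noisy subject-independent option. Proportional scaling
(divide by masked mean over a grand mean of 50) is provided for the
SPM-emulation mode.

**Smoothing.** Separable Gaussian, σ per axis = FWHM/(2√(2 ln 2)) divided
by the voxel spacing; default FWHM 8 mm isotropic. Boundaries are
zero-padded, so intensity leaks at the grid edge; all phantom structures
sit well inside the field of view, and interior kernel mass is conserved
to 1e-6.

## Segmentation and EZ calling

Supra-threshold voxels (t ≥ the one-sided Student quantile at p,
optionally Bonferroni-corrected, intersected with the analysis mask) are
grouped into connected components; default connectivity 26
(flag-switchable to 6/18 — no single convention is universal, and 26 is
the most inclusive standard choice). Components are excluded
when smaller than k voxels ("extent"), when more than half their voxels
lie on non-cortical labels ("extracortical"), or when more than half lie
within 6 mm of the midsagittal plane ("interhemispheric"; margin
configurable — both the margin and the 50% vote are explicit because no
published value exists). Survivors are ranked by size descending, peak t
descending, then lexicographic peak-voxel index — "biggest and most
significant" is a composite criterion, and size-first with significance
tie-break is the only total order in which the biggest cluster always
leads; the ranking is a flag, not a constant. The rank-1 cluster's
majority cortical label fixes the side; the majority sublobar class of
its cortical voxels fixes the location; when mesial- and lateral-temporal
labels each cover ≥ 30% of the cortical voxels the combined class MLT is
reported (threshold configurable — some reference EZs are combined
mesial+lateral and a pure majority vote could never produce that class).

The dynamic sweep computes the t-map once and re-thresholds it per (p, k)
grid point; default grids p ∈ {0.05, 0.01, 0.005, 0.001, 0.0005, 0.0001}
and k ∈ {50, 100, 150, 200}, spanning the ranges used interactively.
Sweep rows are identical by construction to independent single-threshold
runs.

## The match rule and evaluation statistics

A method call "correctly localizes" when side and sublobar location both
agree with the post-surgically confirmed EZ; a reference MLT is matched
by MT, LT or MLT calls, while MT against LT is a mismatch. MRI counts as
positive only when lesional (unspecific findings group with negative).
McNemar is the exact binomial variant, p = min(1, 2·P(X ≤ min(b,c))) with
X ~ Bin(b+c, ½) on the discordant pairs — the variant consistent with the
published pairwise p-values, which doubles as a validation of the match
rule. Cohen's κ is computed from the marginal products with the
asymptotic 95% CI; the verbal bands are slight (0, 0.20], fair
(0.21, 0.40], moderate (0.41, 0.60], substantial (0.61, 0.80], excellent
(> 0.81), and values falling in the cut-point gaps (e.g. 0.205 or 0.81)
band low and are flagged. Published κ values are classified through the
bands but not recomputed: the category space behind them (whether
Negative is a category, whether MLT is merged) is not documented, so any
recomputation would be a guess.

## Packaged study fixtures

The packaged table records, for 30 operated patients with Engel I–II
outcomes, the reference EZ and the calls of five methods. Two variants
ship as data: the table as published, and an erratum variant in which
patient 9's dynamic-analysis call is Negative. The as-published row is
internally inconsistent — it implies 21/30 localizing studies while every
published summary (20/30, the 66.7% figure, and the McNemar p = 0.0117
against the fixed uncorrected threshold) requires 20, and the published
discussion names patients 9, 11 and 13 as the incorrectly localizing
ones. The one-cell correction is therefore shipped as a second fixture
file rather than silently patched; the MRI lesion-token mapping
(MTS → MT, named lesions keep their printed side/lobe) is likewise data,
not code.

## The phantom

The phantom emulates a normative PET database on a 64³ grid at
2.6 × 2.6 × 2.4 mm (the clinical reconstruction voxel size): an
ellipsoidal brain (semi-axes 70 × 80 × 65 mm) with ten spherical cortical
blobs (radius 16 mm; left/right × MT, LT, F, P, O; mirror-symmetric about
x = 0, world x positive = Right) at intensity 100 over a non-cortical
core at 60. A control is the template times a log-normal global scale
(σ_g = 0.15, emulating inter-subject global metabolic variation) plus
iid voxel noise (σ_v = 5, i.e. 5% of cortical intensity), truncated at
zero. A patient additionally has a spherical lesion (per-axis radius 4.5
voxels, ≈ 380 voxels) anchored at a blob center, its intensity multiplied
by (1 − c) with default contrast c = 0.2, and optionally a small random
affine misalignment. These defaults make the recovery experiment
non-trivial at n = 20 controls while keeping a 20%-contrast lesion
reliably detectable at p = 0.001/k = 100.

What the phantom does *not* model: inter-subject anatomical variability,
scanner point-spread, attenuation or scatter. Two consequences for
interpreting the tests. First, type-I calibration is exact only for the
σ_g = 0 variant (iid normal voxels), which is what the calibration
experiment uses — with a log-normal global scale the marginal null is a
scale mixture and nominally miscalibrated until normalization. Second,
real control cohorts carry anatomical variance that inflates s²(v) and
suppresses corrected-threshold detections; the phantom's noise floor is
low enough that a 20% lesion survives even the Bonferroni-corrected
threshold, so "the corrected regime is too restrictive" is verified here
as an ordering (corrected never yields more clusters than uncorrected),
not as emptiness.

## Validation experiments and problem sizes

All experiments run on 1 CPU at desk scale; problem sizes were chosen so
each completes in seconds to about a minute. The t-map is checked against
a brute-force two-sample t-test (scipy) on 100 random 6³ instances to
1e-8. Null calibration draws 200 independent patient+cohort replicates
(64³, gray-matter mask ≈ 10,600 voxels) and requires the supra-threshold
fraction to sit within 3 binomial standard errors of p for
p ∈ {0.05, 0.01, 0.001}. Connected components are checked against a
breadth-first-search oracle on 50 random 16³ volumes at all three
connectivities. End-to-end recovery uses one shared 20-control cohort and
50 lesioned patients: at c = 0.2 the correct (side, sublobar) call rate
must be ≥ 90% (observed 100%), and at c = 0 the positive-call rate ≤ 10%
(observed 0%). The normalization stress test triples a patient's global
scale and requires the parabola factor to scale accordingly within one
histogram bin and the EZ call to be unchanged in ≥ 95% of 20 seeds.

## Known limitations

* The affine registration is plain SSD/Powell — adequate for
  same-modality, mostly-overlapping volumes, but no substitute for a
  full deformable normalization on real heads; nonlinear warps must be
  supplied externally.
* Bonferroni is more conservative than random-field FWE at equal p on
  smooth maps; corrected-mode results are comparable in kind, not in
  exact threshold value.
* The EZ call is a majority vote over atlas labels; pathologies spanning
  more than two sublobar classes reduce to the dominant one (plus the
  MLT rule).
* Kappa CIs use the simple asymptotic standard error, which is known to
  be approximate for small n and sparse categories.
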