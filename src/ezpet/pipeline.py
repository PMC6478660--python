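"""End-to-end single-subject analysis workflows.

Two modes mirror the two processing chains being compared:

* ``petanalysis`` — affine spatial normalization (optional, for already
  aligned data it is skipped), quotient-parabola intensity normalization
  (controls against the template, the patient against the control-cohort
  mean by default), 8 mm Gaussian smoothing, a gray-matter analysis mask,
  and a dynamic (p, k) sweep of uncorrected thresholds;
* ``spm-emulation`` — proportional-scaling intensity normalization to a
  grand mean of 50, the 0.3-of-maximum background mask, and the two fixed
  literature thresholds (corrected p<0.05/k=50, via Bonferroni here, and
  uncorrected p<0.001/k=100).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import LabelAtlas
from .clusters import DEFAULT_K_GRID, DEFAULT_P_GRID, Segmentation, ez_call, segment, sweep
from .image import Volume
from .preprocess import (
    affine_register,
    intensity_normalize_parabola,
    intensity_normalize_proportional,
    resample,
    smooth_gaussian,
)
from .statmap import (
    ControlCohort,
    ThresholdSpec,
    TStatMap,
    background_mask,
    build_cohort,
    gray_matter_mask,
    tmap,
)
from .studytable import EZCall

__all__ = ["AnalysisResult", "run_petanalysis", "run_spm_emulation", "SPM_CORRECTED", "SPM_UNCORRECTED"]

SPM_CORRECTED = ThresholdSpec(p=0.05, k=50, correction="bonferroni")
SPM_UNCORRECTED = ThresholdSpec(p=0.001, k=100, correction="none")


@dataclass
class AnalysisResult:
    """Everything one analysis run produces."""

    mode: str
    tstat: TStatMap
    sweep_table: pd.DataFrame
    primary_spec: ThresholdSpec
    segmentation: Segmentation
    call: EZCall
    diagnostics: dict = field(default_factory=dict)


def run_petanalysis(
    patient: Volume,
    controls: list[Volume],
    template: Volume,
    atlas: LabelAtlas,
    fwhm: float = 8.0,
    p_grid=DEFAULT_P_GRID,
    k_grid=DEFAULT_K_GRID,
    primary_spec: ThresholdSpec = SPM_UNCORRECTED,
    patient_reference: str = "cohort-mean",
    register: bool = False,
    connectivity: int = 26,
    midline_margin: float = 6.0,
    bins: int = 100,
    fit_half_width: int = 3,
) -> AnalysisResult:
    """The dynamic parametric-analysis chain on one patient study.

    ``patient_reference`` selects the denominator of the quotient
    histogram for the patient: the mean of the already-normalized control
    cohort (default) or the template.
    """
    diagnostics: dict = {"mode": "petanalysis"}
    mask = gray_matter_mask(atlas)

    if register:
        transform = affine_register(patient, template)
        patient = resample(patient, transform, template)
        diagnostics["registration"] = transform.params.tolist()

    norm_controls = []
    for ctl in controls:
        res = intensity_normalize_parabola(ctl, template, mask, bins, fit_half_width)
        norm_controls.append(res.apply(ctl))
    if patient_reference == "cohort-mean":
        ref = template.with_data(np.mean([v.data for v in norm_controls], axis=0))
    elif patient_reference == "template":
        ref = template
    else:
        raise ValueError(f"unknown patient reference {patient_reference!r}")
    pat_norm = intensity_normalize_parabola(patient, ref, mask, bins, fit_half_width)
    diagnostics["patient_norm_factor"] = pat_norm.factor
    patient_n = pat_norm.apply(patient)

    smoothed_controls = [smooth_gaussian(v, fwhm) for v in norm_controls]
    patient_s = smooth_gaussian(patient_n, fwhm)

    cohort = build_cohort(smoothed_controls)
    tm = tmap(patient_s, cohort, mask)
    table = sweep(tm, atlas, p_grid, k_grid, connectivity=connectivity, midline_margin=midline_margin)
    seg = segment(tm, primary_spec, atlas, connectivity, midline_margin)
    return AnalysisResult(
        mode="petanalysis",
        tstat=tm,
        sweep_table=table,
        primary_spec=primary_spec,
        segmentation=seg,
        call=ez_call(seg, atlas),
        diagnostics=diagnostics,
    )


def run_spm_emulation(
    patient: Volume,
    controls: list[Volume],
    template: Volume,
    atlas: LabelAtlas,
    fwhm: float = 8.0,
    spec: ThresholdSpec = SPM_CORRECTED,
    grand_mean: float = 50.0,
    mask_fraction: float = 0.3,
    register: bool = False,
    connectivity: int = 26,
    midline_margin: float = 6.0,
) -> AnalysisResult:
    """Fixed-threshold emulation of the generic SPM-style chain.

    Family-wise error correction is Bonferroni over in-mask voxels (the
    original random-field correction behaves comparably: both are far more
    restrictive than the uncorrected threshold).
    """
    diagnostics: dict = {"mode": "spm-emulation"}
    if register:
        transform = affine_register(patient, template)
        patient = resample(patient, transform, template)
        diagnostics["registration"] = transform.params.tolist()

    def proportional(vol: Volume) -> Volume:
        own_mask = background_mask(vol, mask_fraction)
        return intensity_normalize_proportional(vol, own_mask, grand_mean).apply(vol)

    norm_controls = [proportional(v) for v in controls]
    patient_n = proportional(patient)

    smoothed_controls = [smooth_gaussian(v, fwhm) for v in norm_controls]
    patient_s = smooth_gaussian(patient_n, fwhm)
    cohort = build_cohort(smoothed_controls)
    mask = background_mask(cohort.mean, mask_fraction)
    tm = tmap(patient_s, cohort, mask)
    seg = segment(tm, spec, atlas, connectivity, midline_margin)
    table = sweep(
        tm, atlas, [spec.p], [spec.k], correction=spec.correction,
        connectivity=connectivity, midline_margin=midline_margin,
    )
    return AnalysisResult(
        mode="spm-emulation",
        tstat=tm,
        sweep_table=table,
        primary_spec=spec,
        segmentation=seg,
        call=ez_call(seg, atlas),
        diagnostics=diagnostics,
    )
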