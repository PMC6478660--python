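"""Phantom validation experiments.

Since no patient imaging is distributable, the pipeline's imaging claims
are validated on the phantom with known ground truth: type-I calibration
of the null t-map, end-to-end lesion recovery, and the intensity
normalization stress test.  These functions are consumed both by the test
suite and by the reproduction script.
"""

from __future__ import annotations

import warnings

import numpy as np

from .clusters import ez_call, segment
from .phantom import PhantomSpec, make_control, make_patient, make_template_and_atlas
from .preprocess import intensity_normalize_parabola, smooth_gaussian
from .statmap import ThresholdSpec, build_cohort, gray_matter_mask, t_threshold, tmap

__all__ = ["null_calibration", "lesion_recovery", "normalization_stress"]

RECOVERY_SPEC = ThresholdSpec(p=0.001, k=100, correction="none")


def null_calibration(
    n_draws: int = 200,
    n_controls: int = 20,
    levels=(0.05, 0.01, 0.001),
    seed: int = 0,
) -> dict[float, dict[str, float]]:
    """Exceedance rates of null t-maps against nominal one-sided levels.

    Patients and controls are drawn from the identical generative model
    (no global-scale variability, so voxel values are iid normal and the
    statistic's null distribution is exactly Student-t); a fresh cohort is
    drawn per patient so exceedances aggregate binomially.
    """
    spec = PhantomSpec(sigma_g=0.0, seed=seed)
    template, atlas = make_template_and_atlas(spec)
    mask = gray_matter_mask(atlas)
    m = int(np.count_nonzero(mask.data))
    counts = {p: 0 for p in levels}
    total = 0
    for d in range(n_draws):
        base = 50_000 + d * (n_controls + 1)
        controls = [make_control(spec, base + i, template) for i in range(n_controls)]
        cohort = build_cohort(controls)
        patient = make_control(spec, base + n_controls, template)
        tm = tmap(patient, cohort, mask)
        tvals = tm.t.data[mask.data.astype(bool)]
        total += m
        for p in levels:
            counts[p] += int((tvals >= t_threshold(p, tm.df)).sum())
    return {
        p: {"rate": counts[p] / total, "n": total, "se": float(np.sqrt(p * (1 - p) / total))}
        for p in levels
    }


def _prepare_cohort(spec: PhantomSpec, template, atlas, fwhm: float):
    mask = gray_matter_mask(atlas)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        norm = []
        for i in range(spec.n_controls):
            ctl = make_control(spec, i, template)
            norm.append(intensity_normalize_parabola(ctl, template, mask).apply(ctl))
    ref = template.with_data(np.mean([v.data for v in norm], axis=0))
    cohort = build_cohort([smooth_gaussian(v, fwhm) for v in norm])
    return mask, ref, cohort


def lesion_recovery(
    n_seeds: int = 50,
    contrast: float = 0.2,
    seed: int = 0,
    fwhm: float = 8.0,
    threshold: ThresholdSpec = RECOVERY_SPEC,
) -> dict[str, float]:
    """End-to-end EZ recovery rate on lesioned phantom patients.

    One control cohort (as in the clinical setting, shared across
    patients); ``n_seeds`` patients with a lesion of the given contrast.
    Returns the fraction of correct (side, sublobar) calls and the
    fraction of positive (non-Negative) calls — at contrast 0 the latter
    is the false-positive rate.
    """
    spec = PhantomSpec(lesion_contrast=contrast, seed=seed)
    template, atlas = make_template_and_atlas(spec)
    mask, ref, cohort = _prepare_cohort(spec, template, atlas, fwhm)
    n_correct = n_positive = 0
    for i in range(n_seeds):
        patient, truth, _ = make_patient(spec, 100_000 + i, template, atlas)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            norm = intensity_normalize_parabola(patient, ref, mask)
        tm = tmap(smooth_gaussian(norm.apply(patient), fwhm), cohort, mask)
        call = ez_call(segment(tm, threshold, atlas), atlas)
        if not call.is_negative:
            n_positive += 1
            if call == truth:
                n_correct += 1
    return {
        "correct_rate": n_correct / n_seeds,
        "positive_rate": n_positive / n_seeds,
        "n_seeds": n_seeds,
        "contrast": contrast,
    }


def normalization_stress(
    n_seeds: int = 20,
    scale_factor: float = 3.0,
    seed: int = 0,
    fwhm: float = 8.0,
    threshold: ThresholdSpec = RECOVERY_SPEC,
) -> dict[str, float]:
    """Tripling a patient's global scale must be absorbed by normalization.

    Returns the fraction of seeds whose parabola factor scales by
    ``scale_factor`` within one histogram bin width, and the fraction
    whose final EZ call is unchanged.
    """
    spec = PhantomSpec(seed=seed)
    template, atlas = make_template_and_atlas(spec)
    mask, ref, cohort = _prepare_cohort(spec, template, atlas, fwhm)
    factor_ok = call_same = 0
    for i in range(n_seeds):
        patient, _, _ = make_patient(spec, 200_000 + i, template, atlas)
        scaled = patient.with_data(patient.data * scale_factor)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res_a = intensity_normalize_parabola(patient, ref, mask)
            res_b = intensity_normalize_parabola(scaled, ref, mask)
        if abs(res_b.factor - scale_factor * res_a.factor) <= scale_factor * res_b.diagnostics["bin_width"]:
            factor_ok += 1
        call_a = ez_call(
            segment(tmap(smooth_gaussian(res_a.apply(patient), fwhm), cohort, mask), threshold, atlas),
            atlas,
        )
        call_b = ez_call(
            segment(tmap(smooth_gaussian(res_b.apply(scaled), fwhm), cohort, mask), threshold, atlas),
            atlas,
        )
        if call_a == call_b:
            call_same += 1
    return {"factor_ok_rate": factor_ok / n_seeds, "call_same_rate": call_same / n_seeds, "n_seeds": n_seeds}
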