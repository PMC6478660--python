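"""Single-subject versus normative-cohort voxel-wise t statistics.

The normative model is a control cohort summarized per voxel by its mean
and unbiased variance.  A patient study is compared voxel-by-voxel with
the pooled-variance two-sample t statistic in which the patient forms a
singleton group:

    t = (mean_controls - patient) / sqrt(var_controls * (1 + 1/n)),

with n - 1 degrees of freedom (the singleton contributes no variance
degrees of freedom).  The sign convention makes positive t mean
hypometabolism — the patient below the controls — which is the clinically
relevant direction in epilepsy; the test is one-sided by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .atlas import LabelAtlas
from .image import Volume

__all__ = [
    "ControlCohort",
    "TStatMap",
    "ThresholdSpec",
    "build_cohort",
    "tmap",
    "t_threshold",
    "background_mask",
    "gray_matter_mask",
]


@dataclass
class ControlCohort:
    """Per-voxel normative statistics from n >= 2 control studies."""

    n: int
    mean: Volume
    variance: Volume
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("control cohort needs at least 2 subjects")
        if not self.mean.same_grid(self.variance):
            raise ValueError("cohort mean and variance grids differ")
        if (self.variance.data < 0).any():
            raise ValueError("negative variance")


@dataclass
class TStatMap:
    """Per-voxel t statistic with its degrees of freedom and analysis mask.

    ``t`` is finite on the mask and exactly 0 off it.  ``direction`` records
    the sign convention (positive t = hypometabolism).
    """

    t: Volume
    df: int
    mask: Volume
    direction: str = "hypometabolism"
    n_zero_variance: int = 0

    @property
    def n_mask_voxels(self) -> int:
        return int(np.count_nonzero(self.mask.data))


@dataclass(frozen=True)
class ThresholdSpec:
    """A (p, correction, k) segmentation setting."""

    p: float
    k: int
    correction: str = "none"  # "none" | "bonferroni"

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError(f"p must be in (0, 1), got {self.p}")
        if self.k < 1:
            raise ValueError(f"cluster extent k must be >= 1, got {self.k}")
        if self.correction not in ("none", "bonferroni"):
            raise ValueError(f"unknown correction {self.correction!r}")


def build_cohort(volumes: list[Volume], provenance: list[str] | None = None) -> ControlCohort:
    """Per-voxel mean and unbiased variance of the control volumes."""
    if len(volumes) < 2:
        raise ValueError("need at least 2 control volumes")
    ref = volumes[0]
    for i, v in enumerate(volumes[1:], start=1):
        if not v.same_grid(ref):
            name = provenance[i] if provenance else f"volume {i}"
            raise ValueError(f"control {name} is not on the common grid")
    stack = np.stack([np.asarray(v.data, dtype=float) for v in volumes])
    mean = stack.mean(axis=0)
    var = stack.var(axis=0, ddof=1)
    return ControlCohort(
        n=len(volumes),
        mean=ref.with_data(mean),
        variance=ref.with_data(np.maximum(var, 0.0)),
        provenance=list(provenance) if provenance else [],
    )


def tmap(patient: Volume, cohort: ControlCohort, mask: Volume, two_sided: bool = False) -> TStatMap:
    """The single-subject t-map over the analysis mask.

    Masked voxels with zero cohort variance get t = 0 (they are background
    artifacts that must not seed clusters); their count is recorded on the
    returned map.  ``two_sided=False`` keeps the hypometabolism direction
    only in downstream thresholding; the statistic itself is signed either
    way.
    """
    if not patient.same_grid(cohort.mean):
        raise ValueError("patient volume is not on the cohort grid")
    if not mask.same_grid(cohort.mean):
        raise ValueError("mask is not on the cohort grid")
    m = np.asarray(mask.data, dtype=bool)
    if not m.any():
        raise ValueError("empty analysis mask")
    n = cohort.n
    var = np.asarray(cohort.variance.data, dtype=float)
    diff = np.asarray(cohort.mean.data, dtype=float) - np.asarray(patient.data, dtype=float)
    denom = np.sqrt(var * (1.0 + 1.0 / n))
    t = np.zeros_like(diff)
    ok = m & (denom > 0)
    t[ok] = diff[ok] / denom[ok]
    n_zero = int(np.count_nonzero(m & ~(denom > 0)))
    return TStatMap(
        t=patient.with_data(t),
        df=n - 1,
        mask=patient.with_data(m),
        direction="hypometabolism" if not two_sided else "two-sided",
        n_zero_variance=n_zero,
    )


def t_threshold(p: float, df: int, correction: str = "none", m: int = 1) -> float:
    """Student-t threshold for one-sided upper-tail level ``p``.

    With ``correction='bonferroni'`` the level is divided by the number of
    in-mask voxels ``m`` (family-wise error control across the map).
    """
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if df < 1:
        raise ValueError("df must be >= 1")
    if correction == "none":
        level = p
    elif correction == "bonferroni":
        if m < 1:
            raise ValueError("m must be >= 1 for Bonferroni correction")
        level = p / m
    else:
        raise ValueError(f"unknown correction {correction!r}")
    t = float(stats.t.isf(level, df))
    if not np.isfinite(t):
        raise ValueError(f"corrected level {level:g} underflows the t quantile; use a larger p")
    return t


def background_mask(image: Volume, fraction: float = 0.3) -> Volume:
    """Voxels above ``fraction`` of the image maximum (SPM-style 0.3 mask)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    data = np.asarray(image.data, dtype=float)
    peak = data.max()
    if peak <= 0:
        raise ValueError("cannot build a background mask from an all-zero image")
    return image.with_data(data > fraction * peak)


def gray_matter_mask(atlas: LabelAtlas) -> Volume:
    """Union of atlas regions flagged cortical (seizures arise in gray matter)."""
    cortical = atlas.cortical_ids
    mask = np.isin(atlas.labels.data, cortical)
    if not mask.any():
        raise ValueError("gray-matter mask is empty")
    return atlas.labels.with_data(mask)
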