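"""Cluster segmentation of t-maps and epileptogenic-zone calling.

A cluster is a connected set of supra-threshold voxels of at least k
voxels.  Candidate clusters outside the cerebral cortex or straddling the
interhemispheric region are excluded; the survivors are ranked size-first
with peak-t tie-break, and the rank-1 cluster's anatomical majority vote
yields the (side, sublobar) EZ call.  :func:`sweep` re-thresholds one
t-map across a whole (p, k) grid — the programmatic equivalent of
dragging the two threshold scrollbars of an interactive session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import LabelAtlas
from .image import Volume
from .statmap import ThresholdSpec, TStatMap, t_threshold
from .studytable import EZCall

__all__ = [
    "Cluster",
    "Segmentation",
    "threshold_map",
    "connected_components",
    "extract_clusters",
    "filter_and_exclude",
    "rank_clusters",
    "ez_call",
    "segment",
    "sweep",
    "DEFAULT_P_GRID",
    "DEFAULT_K_GRID",
]

# default dynamic-thresholding grids: p from 0.05 down to 0.0001 and
# minimum cluster extents from 50 to 200 voxels
DEFAULT_P_GRID = (0.05, 0.01, 0.005, 0.001, 0.0005, 0.0001)
DEFAULT_K_GRID = (50, 100, 150, 200)

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class Cluster:
    """One connected supra-threshold component."""

    voxels: np.ndarray  # (size, 3) int indices
    size: int
    peak_t: float
    peak_voxel: tuple[int, int, int]
    centroid_mm: np.ndarray
    label_histogram: dict[int, int]


@dataclass
class Segmentation:
    """Ranked clusters for one threshold setting, with exclusions."""

    spec: ThresholdSpec
    clusters: list[Cluster] = field(default_factory=list)
    excluded: list[tuple[Cluster, str]] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.clusters


def threshold_map(tm: TStatMap, spec: ThresholdSpec, m: int | None = None) -> Volume:
    """Binary map of voxels with t >= the (p, correction) threshold, in-mask."""
    if m is None:
        m = tm.n_mask_voxels
    thr = t_threshold(spec.p, tm.df, spec.correction, m)
    binary = (np.asarray(tm.t.data) >= thr) & np.asarray(tm.mask.data, dtype=bool)
    return tm.t.with_data(binary)


def connected_components(binary: Volume | np.ndarray, connectivity: int = 26) -> list[np.ndarray]:
    """Maximal connected foreground components as (size, 3) index arrays."""
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")
    data = np.asarray(binary.data if isinstance(binary, Volume) else binary, dtype=bool)
    labeled, n = ndimage.label(data, structure=_STRUCTURES[connectivity])
    comps = []
    for objslice, lab in zip(ndimage.find_objects(labeled), range(1, n + 1)):
        local = np.argwhere(labeled[objslice] == lab)
        offset = np.array([s.start for s in objslice])
        comps.append(local + offset)
    return comps


def extract_clusters(tm: TStatMap, components: list[np.ndarray], atlas: LabelAtlas) -> list[Cluster]:
    """Attach statistics and atlas-label histograms to raw components."""
    t = np.asarray(tm.t.data)
    labels = np.asarray(atlas.labels.data)
    out = []
    for vox in components:
        idx = tuple(vox.T)
        tv = t[idx]
        # first occurrence under C order = lexicographically smallest peak voxel
        order = np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0]))
        vox_sorted = vox[order]
        tv_sorted = tv[order]
        ipk = int(np.argmax(tv_sorted))
        lab, counts = np.unique(labels[idx], return_counts=True)
        out.append(
            Cluster(
                voxels=vox_sorted,
                size=int(len(vox)),
                peak_t=float(tv_sorted[ipk]),
                peak_voxel=tuple(int(v) for v in vox_sorted[ipk]),
                centroid_mm=tm.t.world_coords(vox.mean(axis=0))[0],
                label_histogram={int(l): int(c) for l, c in zip(lab, counts)},
            )
        )
    return out


def filter_and_exclude(
    clusters: list[Cluster],
    k: int,
    atlas: LabelAtlas,
    midline_margin: float = 6.0,
    grid: Volume | None = None,
) -> tuple[list[Cluster], list[tuple[Cluster, str]]]:
    """Apply the extent, extracortical and interhemispheric exclusions.

    A cluster is dropped when its size is below ``k`` ("extent"), when more
    than half its voxels lie on non-cortical atlas labels
    ("extracortical"), or when more than half lie within ``midline_margin``
    mm of the x = 0 midsagittal plane ("interhemispheric").
    """
    if grid is None:
        grid = atlas.labels
    kept: list[Cluster] = []
    excluded: list[tuple[Cluster, str]] = []
    for cl in clusters:
        if cl.size < k:
            excluded.append((cl, "extent"))
            continue
        noncortical = sum(c for l, c in cl.label_histogram.items() if not atlas.is_cortical(l))
        if noncortical > 0.5 * cl.size:
            excluded.append((cl, "extracortical"))
            continue
        x_world = grid.world_coords(cl.voxels)[:, 0]
        if np.count_nonzero(np.abs(x_world) <= midline_margin) > 0.5 * cl.size:
            excluded.append((cl, "interhemispheric"))
            continue
        kept.append(cl)
    return kept, excluded


def rank_clusters(kept: list[Cluster], spec: ThresholdSpec, excluded=None) -> Segmentation:
    """Rank size-descending, peak-t tie-break, then peak-voxel index.

    "Biggest and most significant" is a composite criterion; size leads
    here, with statistical significance breaking ties, which is the only
    total order in which the biggest cluster always wins.
    """
    ranked = sorted(kept, key=lambda c: (-c.size, -c.peak_t, c.peak_voxel))
    return Segmentation(spec=spec, clusters=ranked, excluded=list(excluded or []))


def ez_call(seg: Segmentation, atlas: LabelAtlas, mlt_threshold: float = 0.3) -> EZCall:
    """The (side, sublobar) call of the rank-1 cluster, or Negative.

    Side is the side of the cluster's majority cortical label; sublobar is
    the majority sublobar class of its cortical voxels.  When mesial- and
    lateral-temporal labels each cover at least ``mlt_threshold`` of the
    cortical voxels the combined class MLT is reported.
    """
    if seg.is_empty:
        return EZCall.negative()
    top = seg.clusters[0]
    cort = {l: c for l, c in top.label_histogram.items() if atlas.is_cortical(l)}
    if not cort:
        raise ValueError("rank-1 cluster covers no cortical labels; it should have been excluded")
    n_cort = sum(cort.values())
    majority_label = min(cort, key=lambda l: (-cort[l], l))
    side = atlas.side(majority_label)
    sub_counts: dict[str, int] = {}
    for l, c in cort.items():
        sub_counts[atlas.sublobar(l)] = sub_counts.get(atlas.sublobar(l), 0) + c
    sublobar = min(sub_counts, key=lambda s: (-sub_counts[s], s))
    mt_share = sub_counts.get("MT", 0) / n_cort
    lt_share = sub_counts.get("LT", 0) / n_cort
    if mt_share >= mlt_threshold and lt_share >= mlt_threshold:
        sublobar = "MLT"
    return EZCall(side, sublobar)


def segment(
    tm: TStatMap,
    spec: ThresholdSpec,
    atlas: LabelAtlas,
    connectivity: int = 26,
    midline_margin: float = 6.0,
) -> Segmentation:
    """Threshold, extract, exclude and rank for one (p, k) setting."""
    binary = threshold_map(tm, spec)
    comps = connected_components(binary, connectivity)
    clusters = extract_clusters(tm, comps, atlas)
    kept, excl = filter_and_exclude(clusters, spec.k, atlas, midline_margin, grid=tm.t)
    return rank_clusters(kept, spec, excl)


def sweep(
    tm: TStatMap,
    atlas: LabelAtlas,
    p_grid=DEFAULT_P_GRID,
    k_grid=DEFAULT_K_GRID,
    correction: str = "none",
    connectivity: int = 26,
    midline_margin: float = 6.0,
    mlt_threshold: float = 0.3,
) -> pd.DataFrame:
    """Re-threshold one t-map across the full (p, k) grid.

    The t-map is computed once by the caller and only re-thresholded here;
    each row is identical to an independent :func:`segment` run at that
    (p, k).  Columns: p, k, correction, n_clusters, n_excluded, side,
    sublobar.
    """
    p_grid = list(p_grid)
    k_grid = list(k_grid)
    if not p_grid or not k_grid:
        raise ValueError("threshold grids must be nonempty")
    rows = []
    for p in p_grid:
        binary = threshold_map(tm, ThresholdSpec(p=p, k=1, correction=correction))
        comps = connected_components(binary, connectivity)
        clusters = extract_clusters(tm, comps, atlas)
        for k in k_grid:
            spec = ThresholdSpec(p=p, k=k, correction=correction)
            kept, excl = filter_and_exclude(clusters, k, atlas, midline_margin, grid=tm.t)
            seg = rank_clusters(kept, spec, excl)
            call = ez_call(seg, atlas, mlt_threshold)
            rows.append(
                {
                    "p": p,
                    "k": k,
                    "correction": correction,
                    "n_clusters": len(seg.clusters),
                    "n_excluded": len(seg.excluded),
                    "side": call.side,
                    "sublobar": call.sublobar,
                }
            )
    return pd.DataFrame(rows)
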