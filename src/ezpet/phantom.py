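"""Synthetic brain phantoms with known ground truth.

The phantom stands in for a normative PET database: an ellipsoidal "brain"
with ten spherical cortical blobs (left/right x mesial temporal, lateral
temporal, frontal, parietal, occipital) at intensity 100 over a
non-cortical core at 60.  Controls are the template under a per-subject
log-normal global scale plus voxel-level Gaussian noise; a patient
additionally carries a spherical hypometabolic lesion (intensity
multiplied by 1 - c) anchored inside one cortical blob, and optionally a
small random affine misalignment.  Every downstream stage — registration,
normalization, t-mapping, segmentation, EZ calling — is testable against
the seeded ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import LabelAtlas
from .image import Volume, write_volume
from .preprocess import AffineTransform, resample
from .studytable import EZCall

__all__ = ["PhantomSpec", "make_template_and_atlas", "make_control", "make_patient", "simulate_dataset"]

# blob centers in world mm for the Right hemisphere (x mirrored for Left);
# chosen pairwise > 2 radii apart and inside the brain ellipsoid
_REGION_CENTERS = {
    "MT": (24.0, 10.0, -30.0),
    "LT": (50.0, 0.0, -6.0),
    "F": (28.0, 52.0, 16.0),
    "P": (30.0, -36.0, 30.0),
    "O": (20.0, -58.0, -8.0),
}
CORE_LABEL = 11


@dataclass(frozen=True)
class PhantomSpec:
    """Generative settings for one phantom study population."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.6, 2.6, 2.4)
    brain_semiaxes: tuple[float, float, float] = (70.0, 80.0, 65.0)
    blob_radius: float = 16.0  # mm
    cortical_intensity: float = 100.0
    core_intensity: float = 60.0
    sigma_g: float = 0.15  # sd of log global scale
    sigma_v: float = 5.0  # voxel noise sd, same units as intensity
    lesion_region: str = "L-MT"
    lesion_radius_vox: float = 4.5  # per-axis radius in voxels
    lesion_contrast: float = 0.2  # lesion intensity multiplied by (1 - c)
    n_controls: int = 20
    rot_max_deg: float = 0.0  # optional affine perturbation of the patient
    shift_max_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.lesion_contrast < 1:
            raise ValueError("lesion contrast must be in [0, 1)")
        side, _, region = self.lesion_region.partition("-")
        if side not in ("L", "R") or region not in _REGION_CENTERS:
            raise ValueError(f"unknown lesion region {self.lesion_region!r}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("shape", "spacing", "brain_semiaxes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def replace(self, **kw) -> "PhantomSpec":
        return replace(self, **kw)


def _grid_affine(spec: PhantomSpec) -> np.ndarray:
    aff = np.diag(list(spec.spacing) + [1.0])
    aff[:3, 3] = -(np.array(spec.shape) - 1) / 2.0 * np.array(spec.spacing)
    return aff


def _world_grid(spec: PhantomSpec) -> list[np.ndarray]:
    aff = _grid_affine(spec)
    axes = [aff[i, i] * np.arange(spec.shape[i]) + aff[i, 3] for i in range(3)]
    return list(np.meshgrid(*axes, indexing="ij"))


def _region_centers(spec: PhantomSpec) -> dict[str, np.ndarray]:
    centers = {}
    for region, (x, y, z) in _REGION_CENTERS.items():
        centers[f"R-{region}"] = np.array([x, y, z])
        centers[f"L-{region}"] = np.array([-x, y, z])
    return centers


def make_template_and_atlas(spec: PhantomSpec) -> tuple[Volume, LabelAtlas]:
    """Deterministic phantom template and its label atlas.

    Labels 1..10 are the cortical blobs (mirror-symmetric about x = 0);
    label 11 is the non-cortical core.
    """
    aff = _grid_affine(spec)
    X, Y, Z = _world_grid(spec)
    a, b, c = spec.brain_semiaxes
    brain = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0

    labels = np.zeros(spec.shape, dtype=np.int16)
    rows = []
    centers = _region_centers(spec)
    order = [f"{side}-{region}" for region in _REGION_CENTERS for side in ("L", "R")]
    for lab, name in enumerate(order, start=1):
        cx, cy, cz = centers[name]
        blob = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= spec.blob_radius**2
        if (labels[blob] != 0).any():
            raise ValueError(f"phantom region {name} overlaps another region")
        labels[blob] = lab
        side, _, region = name.partition("-")
        rows.append({"id": lab, "name": name, "side": side, "sublobar": region, "cortical": True})
    core = brain & (labels == 0)
    labels[core] = CORE_LABEL
    rows.append({"id": CORE_LABEL, "name": "core", "side": "midline", "sublobar": "other", "cortical": False})

    template = np.zeros(spec.shape)
    template[labels == CORE_LABEL] = spec.core_intensity
    template[(labels > 0) & (labels < CORE_LABEL)] = spec.cortical_intensity
    atlas = LabelAtlas(Volume(labels, aff), pd.DataFrame(rows))
    return Volume(template, aff), atlas


def _rng(spec: PhantomSpec, seed: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, seed])


def make_control(spec: PhantomSpec, seed: int, template: Volume | None = None) -> Volume:
    """One control study: template x LogNormal(0, sigma_g^2) + N(0, sigma_v^2)."""
    if template is None:
        template, _ = make_template_and_atlas(spec)
    rng = _rng(spec, seed)
    g = rng.lognormal(0.0, spec.sigma_g) if spec.sigma_g > 0 else 1.0
    noise = rng.normal(0.0, spec.sigma_v, spec.shape) if spec.sigma_v > 0 else 0.0
    data = np.clip(template.data * g + noise, 0.0, None)
    return template.with_data(data)


def lesion_mask(spec: PhantomSpec, grid: Volume) -> np.ndarray:
    """Boolean mask of the lesion sphere (per-axis radius in voxels)."""
    center_mm = _region_centers(spec)[spec.lesion_region]
    inv = np.linalg.inv(grid.affine)
    center_vox = (inv[:3, :3] @ center_mm + inv[:3, 3])
    idx = np.indices(spec.shape, dtype=float)
    d2 = sum(((idx[i] - center_vox[i]) / spec.lesion_radius_vox) ** 2 for i in range(3))
    return d2 <= 1.0


def make_patient(
    spec: PhantomSpec, seed: int, template: Volume | None = None, atlas: LabelAtlas | None = None
) -> tuple[Volume, EZCall, dict]:
    """A lesioned, optionally misaligned patient study plus its ground truth.

    Returns ``(volume, true_call, info)`` where ``info`` records the global
    scale, the lesion voxel count, and — when an affine perturbation was
    requested — the applied pull-back transform (registering the patient to
    the template recovers its inverse).
    """
    if template is None or atlas is None:
        template, atlas = make_template_and_atlas(spec)
    side, _, region = spec.lesion_region.partition("-")

    les = lesion_mask(spec, template)
    region_id = int(atlas.table.loc[atlas.table["name"] == spec.lesion_region, "id"].iloc[0])
    inside = np.asarray(atlas.labels.data)[les] == region_id
    clipped = 1.0 - inside.mean() if les.any() else 1.0
    if clipped > 0:
        import warnings

        warnings.warn(f"lesion sphere extends outside its region (clipped fraction {clipped:.2f})", stacklevel=2)

    lesioned = template.data.copy()
    lesioned[les] *= 1.0 - spec.lesion_contrast

    rng = _rng(spec, seed)
    g = rng.lognormal(0.0, spec.sigma_g) if spec.sigma_g > 0 else 1.0
    noise = rng.normal(0.0, spec.sigma_v, spec.shape) if spec.sigma_v > 0 else 0.0
    data = np.clip(lesioned * g + noise, 0.0, None)
    vol = template.with_data(data)

    transform = None
    if spec.rot_max_deg > 0 or spec.shift_max_mm > 0:
        rot = rng.uniform(-1, 1, 3) * np.deg2rad(spec.rot_max_deg)
        shift = rng.uniform(-1, 1, 3) * spec.shift_max_mm
        transform = AffineTransform(translation=shift, rotation=rot)
        vol = resample(vol, transform, template)

    info = {
        "global_scale": float(g),
        "lesion_voxels": int(np.count_nonzero(les)),
        "lesion_clipped_fraction": float(clipped),
        "transform": transform,
    }
    return vol, EZCall(side, region), info


def simulate_dataset(spec: PhantomSpec, outdir, patient_seed: int = 1000) -> dict:
    """Write a complete phantom dataset (template, atlas, controls, patient).

    Control seeds are 0..n_controls-1; the patient uses ``patient_seed``.
    Returns the ground-truth record that is also written as JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    template, atlas = make_template_and_atlas(spec)
    write_volume(template, outdir / "template.nii")
    write_volume(atlas.labels, outdir / "atlas.nii")
    atlas.table.to_csv(outdir / "atlas_table.tsv", sep="\t", index=False)
    for i in range(spec.n_controls):
        write_volume(make_control(spec, i, template), outdir / f"control_{i:02d}.nii")
    patient, truth, info = make_patient(spec, patient_seed, template, atlas)
    write_volume(patient, outdir / "patient.nii")
    record = {
        "lesion_region": spec.lesion_region,
        "true_side": truth.side,
        "true_sublobar": truth.sublobar,
        "lesion_contrast": spec.lesion_contrast,
        "global_scale": info["global_scale"],
        "lesion_voxels": info["lesion_voxels"],
        "patient_seed": patient_seed,
        "spec": asdict(spec),
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(record, fh, indent=2)
    return record
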