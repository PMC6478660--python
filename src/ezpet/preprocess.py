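"""Spatial and intensity preprocessing of PET volumes.

The preprocessing chain mirrors routine single-subject parametric mapping:

1. spatial normalization to a template grid — a 12-parameter affine
   (deterministic multi-resolution sum-of-squared-differences fit), with an
   optional precomputed nonlinear deformation field applied afterwards;
2. intensity normalization to remove global metabolic differences between
   subjects — either the quotient-histogram parabola method (the mode of
   the voxel-wise patient/reference ratio, located by a local parabola fit,
   which is robust to focal defects that bias a total-counts ratio) or
   SPM-style proportional scaling to a grand mean;
3. Gaussian smoothing (FWHM in mm, converted to voxel sigmas per axis).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, optimize

from .image import Volume

__all__ = [
    "AffineTransform",
    "NormalizationResult",
    "RegistrationError",
    "affine_register",
    "resample",
    "apply_deformation",
    "read_deformation_field",
    "write_deformation_field",
    "intensity_normalize_parabola",
    "intensity_normalize_proportional",
    "smooth_gaussian",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class RegistrationError(RuntimeError):
    pass


@dataclass
class AffineTransform:
    """A 12-parameter affine in world (mm) coordinates.

    Composition order: points map as ``x -> c + t + R S H (x - c)`` with
    rotation ``R = Rx Ry Rz``, scale ``S = diag(s)``, upper-triangular shear
    ``H`` and a fixed rotation/scale center ``c`` (metadata, not a free
    parameter; registration sets it to the template center so rotations do
    not trade off against translations).  The matrix maps fixed-image world
    points to moving-image world points, i.e. it is applied as a pull-back
    when resampling.
    """

    translation: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))
    scale: np.ndarray = dc_field(default_factory=lambda: np.ones(3))
    shear: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        for name in ("translation", "rotation", "scale", "shear", "center"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        if (self.scale <= 0).any():
            raise ValueError("scales must be strictly positive")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()

    @classmethod
    def from_params(cls, params: np.ndarray, center=(0.0, 0.0, 0.0)) -> "AffineTransform":
        p = np.asarray(params, dtype=float).reshape(12)
        return cls(p[0:3], p[3:6], p[6:9], p[9:12], np.asarray(center, dtype=float))

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.translation, self.rotation, self.scale, self.shear])

    def matrix(self) -> np.ndarray:
        """The 4x4 world->world matrix."""
        rx, ry, rz = self.rotation
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        S = np.diag(self.scale)
        hxy, hxz, hyz = self.shear
        H = np.array([[1, hxy, hxz], [0, 1, hyz], [0, 0, 1]])
        A = Rx @ Ry @ Rz @ S @ H
        M = np.eye(4)
        M[:3, :3] = A
        M[:3, 3] = self.center + self.translation - A @ self.center
        return M

    def to_json(self, path) -> None:
        names = ["tx", "ty", "tz", "rx", "ry", "rz", "sx", "sy", "sz", "hxy", "hxz", "hyz"]
        payload = dict(zip(names, self.params.tolist()))
        payload["center"] = self.center.tolist()
        payload["composition"] = "T*Rx*Ry*Rz*S*H about center"
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AffineTransform":
        with open(path) as fh:
            d = json.load(fh)
        p = [d[k] for k in ("tx", "ty", "tz", "rx", "ry", "rz", "sx", "sy", "sz", "hxy", "hxz", "hyz")]
        return cls.from_params(np.array(p), d.get("center", (0.0, 0.0, 0.0)))


@dataclass
class NormalizationResult:
    """Outcome of a global intensity normalization.

    The normalized image is the input divided voxel-wise by ``factor``.
    """

    factor: float
    method: str  # "parabola-quotient" or "proportional-scaling"
    diagnostics: dict

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise ValueError(f"normalization factor must be positive, got {self.factor}")

    def apply(self, vol: Volume) -> Volume:
        return vol.with_data(vol.data / self.factor)


# ---------------------------------------------------------------------------
# resampling


def resample(image: Volume, transform: AffineTransform, target: Volume | None = None) -> Volume:
    """Resample ``image`` onto ``target``'s grid through ``transform``.

    Trilinear interpolation; voxels mapping outside the moving image's
    field of view are set to 0.  The identity transform on the image's own
    grid returns the data bitwise unchanged.
    """
    if target is None:
        target = image
    M = transform.matrix()
    if abs(np.linalg.det(M[:3, :3])) < 1e-12:
        raise ValueError("singular affine transform")
    # target voxel -> moving voxel
    V = np.linalg.inv(image.affine) @ M @ target.affine
    if np.allclose(V, np.eye(4), atol=1e-12) and image.shape == target.shape:
        return Volume(image.data.copy(), target.affine.copy())
    out = ndimage.affine_transform(
        np.asarray(image.data, dtype=float),
        V[:3, :3],
        offset=V[:3, 3],
        output_shape=target.shape,
        order=1,
        mode="constant",
        cval=0.0,
    )
    return Volume(out, target.affine.copy())


def apply_deformation(image: Volume, field: np.ndarray) -> Volume:
    """Apply a precomputed dense deformation field (pull-back).

    ``field`` has shape ``image.shape + (3,)`` and holds, per target voxel,
    a world-mm displacement added to the voxel's world position before
    sampling the input.  An all-zero field is the identity.
    """
    field = np.asarray(field, dtype=float)
    if field.shape != image.shape + (3,):
        raise ValueError(f"deformation field shape {field.shape} does not match grid {image.shape} + (3,)")
    if not field.any():
        return image.copy()
    inv3 = np.linalg.inv(image.affine[:3, :3])
    idx = np.indices(image.shape, dtype=float)
    disp_vox = np.einsum("ij,...j->...i", inv3, field)
    coords = np.stack([idx[a] + disp_vox[..., a] for a in range(3)])
    out = ndimage.map_coordinates(
        np.asarray(image.data, dtype=float), coords, order=1, mode="constant", cval=0.0
    )
    return Volume(out, image.affine.copy())


def read_deformation_field(path) -> np.ndarray:
    """Read a 3-channel NIfTI deformation field as an (x, y, z, 3) array."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 5 and data.shape[3] == 1:  # NIfTI vector-field layout
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"expected a 3-channel deformation field, got shape {data.shape}")
    return data.astype(float)


def write_deformation_field(field: np.ndarray, affine: np.ndarray, path) -> None:
    """Write an (x, y, z, 3) displacement array as a 3-channel NIfTI."""
    import nibabel as nib

    field = np.asarray(field, dtype=float)
    if field.ndim != 4 or field.shape[-1] != 3:
        raise ValueError(f"expected an (x, y, z, 3) field, got shape {field.shape}")
    nib.save(nib.Nifti1Image(field, np.asarray(affine, dtype=float)), str(path))


# ---------------------------------------------------------------------------
# registration


def _downsample(vol: Volume, factor: int) -> Volume:
    if factor == 1:
        return vol
    sm = ndimage.gaussian_filter(np.asarray(vol.data, dtype=float), sigma=factor / 2.0, mode="nearest")
    data = sm[::factor, ::factor, ::factor]
    aff = vol.affine @ np.diag([factor, factor, factor, 1.0])
    return Volume(data, aff)


def _com_world(vol: Volume) -> np.ndarray:
    data = np.asarray(vol.data, dtype=float)
    data = np.clip(data, 0, None)
    total = data.sum()
    if total <= 0:
        return vol.world_coords(np.array([(s - 1) / 2.0 for s in vol.shape]))[0]
    com = np.asarray(ndimage.center_of_mass(data))
    return vol.world_coords(com)[0]


def affine_register(
    moving: Volume,
    template: Volume,
    levels: int = 3,
    max_iterations: int = 30,
) -> AffineTransform:
    """Fit a 12-parameter affine mapping template space onto ``moving``.

    Minimizes the sum of squared differences between the template and the
    resampled moving image over a coarse-to-fine multi-resolution schedule
    (``levels`` dyadic levels).  Deterministic: initialization is
    center-of-mass alignment, the optimizer is Powell's method, and no
    randomness enters the cost.
    """
    center = template.world_coords(np.array([(s - 1) / 2.0 for s in template.shape]))[0]
    init = np.zeros(12)
    init[6:9] = 1.0
    init[0:3] = _com_world(moving) - _com_world(template)

    # internal scaling so Powell steps are comparable across parameter kinds
    scales = np.array([1.0, 1.0, 1.0, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01])
    n_eval = [0]

    def make_cost(tpl: Volume, mov: Volume, active: np.ndarray, base: np.ndarray):
        tdata = np.asarray(tpl.data, dtype=float)

        def cost(q: np.ndarray) -> float:
            p = base.copy()
            p[active] = base[active] + q * scales[active]
            n_eval[0] += 1
            if (p[6:9] <= 0.05).any():
                return np.inf
            tr = AffineTransform.from_params(p, center)
            res = resample(mov, tr, tpl)
            c = float(np.mean((tdata - res.data) ** 2))
            if not np.isfinite(c):
                raise RegistrationError(f"non-finite registration cost at evaluation {n_eval[0]}")
            return c

        return cost

    rigid = np.zeros(12, dtype=bool)
    rigid[0:6] = True
    full = np.ones(12, dtype=bool)

    params = init
    factors = [2 ** (levels - 1 - i) for i in range(levels)]
    # evaluation budget shrinks as resolution (and per-eval cost) grows
    budgets = [100 * max_iterations, 15 * max_iterations, 4 * max_iterations]
    for li, f in enumerate(factors):
        tpl = _downsample(template, f)
        mov = _downsample(moving, f)
        stages = [rigid, full] if li == 0 else [full]
        budget = budgets[min(li, len(budgets) - 1)]
        for active in stages:
            cost = make_cost(tpl, mov, active, params)
            res = optimize.minimize(
                cost,
                np.zeros(int(active.sum())),
                method="Powell",
                options={"maxfev": budget, "xtol": 0.02, "ftol": 1e-7},
            )
            params = params.copy()
            params[active] = params[active] + res.x * scales[active]
    return AffineTransform.from_params(params, center)


# ---------------------------------------------------------------------------
# intensity normalization


def intensity_normalize_parabola(
    patient: Volume,
    reference: Volume,
    mask: Volume,
    bins: int = 100,
    fit_half_width: int = 3,
) -> NormalizationResult:
    """Global scale factor from the mode of the voxel-wise quotient.

    The patient/reference quotients over the mask are histogrammed between
    their 1st and 99th percentiles; a parabola is least-squares fitted to
    the bin counts around the modal bin and the factor is the parabola's
    vertex abscissa (clamped to the fitted window).  Unlike a total-counts
    ratio, the mode is insensitive to a minority of focally abnormal
    voxels, which is the point of the method.
    """
    m = np.asarray(mask.data, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    ref = np.asarray(reference.data, dtype=float)[m]
    pat = np.asarray(patient.data, dtype=float)[m]
    if (ref <= 0).any():
        raise ValueError("reference must be strictly positive on masked voxels")
    q = pat / ref

    flags: list[str] = []
    lo, hi = np.percentile(q, [1.0, 99.0])
    if not hi > lo:
        flags.append("degenerate-histogram")
        factor = float(lo)
        diag = {"mode": factor, "bin_width": 0.0, "window": (factor, factor), "flags": flags}
        return NormalizationResult(factor, "parabola-quotient", diag)

    counts, edges = np.histogram(q, bins=bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    imode = int(np.argmax(counts))
    mode_center = float(centers[imode])
    w0 = max(0, imode - fit_half_width)
    w1 = min(bins, imode + fit_half_width + 1)

    if counts[imode] == counts.sum():
        flags.append("degenerate-histogram")
        factor = mode_center
    else:
        a, b, _c = np.polyfit(centers[w0:w1], counts[w0:w1], 2)
        if a >= 0:
            flags.append("upward-parabola")
            factor = mode_center
        else:
            vertex = -b / (2.0 * a)
            factor = float(np.clip(vertex, centers[w0], centers[w1 - 1]))

    if factor <= 0:
        flags.append("nonpositive-vertex")
        factor = mode_center
    if flags:
        warnings.warn(f"parabola normalization flags: {flags}", stacklevel=2)
    diag = {
        "mode": mode_center,
        "bin_width": float(edges[1] - edges[0]),
        "window": (float(centers[w0]), float(centers[w1 - 1])),
        "histogram_range": (float(lo), float(hi)),
        "flags": flags,
    }
    return NormalizationResult(float(factor), "parabola-quotient", diag)


def intensity_normalize_proportional(
    patient: Volume, mask: Volume, grand_mean: float = 50.0
) -> NormalizationResult:
    """Proportional scaling: divide so the masked mean equals ``grand_mean``."""
    m = np.asarray(mask.data, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    mean = float(np.asarray(patient.data, dtype=float)[m].mean())
    if mean == 0:
        raise ValueError("zero masked mean; cannot scale proportionally")
    return NormalizationResult(mean / grand_mean, "proportional-scaling", {"masked_mean": mean})


# ---------------------------------------------------------------------------
# smoothing


def smooth_gaussian(image: Volume, fwhm) -> Volume:
    """Separable Gaussian smoothing with per-axis FWHM in mm.

    sigma per axis = fwhm / (2 sqrt(2 ln 2)) / spacing, in voxels.  Zero
    FWHM returns the input unchanged.  Boundaries are zero-padded, so
    intensity leaks out of the grid near the edges; interior mass is
    conserved.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm, dtype=float), (3,))
    if (fwhm < 0).any():
        raise ValueError("FWHM must be non-negative")
    if (fwhm == 0).all():
        return image.copy()
    sigma_vox = fwhm / FWHM_TO_SIGMA / image.spacing
    out = ndimage.gaussian_filter(
        np.asarray(image.data, dtype=float), sigma=sigma_vox, mode="constant", cval=0.0
    )
    return image.with_data(out)
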