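"""Synthetic head phantoms: CT pairs, dose grids, masks, known transformations.

The generator emulates the geometry the registration method assumes for a
head-and-neck study at the working resolution: an ellipsoidal head with a
high-density skull shell, heterogeneous soft tissue, a spherical primary
tumor, and a couch slab outside the patient.  Soft tissue carries two
intensity components on top of its 40 HU base: band-limited heterogeneity
(Gaussian-smoothed noise, ~8 mm correlation length) standing in for real
multi-scale tissue structure, and white acquisition noise.  All HU values
are kept in [−1000, 3000] and every generator is a pure function of its
seed.

Ground-truth transformations (translations, 2nd-order polynomial warps,
concentric tumor shrinkage with a smooth inward pull of the surrounding
tissue) come with their exact analytic displacement fields or masks, so
registration accuracy can be scored without manual contours.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .grid import (
    AIR_HU,
    BinaryMask,
    DisplacementField,
    VolumeImage,
    resample_to_grid,
    warp,
)
from .preprocess import VoxelBox

__all__ = [
    "PhantomSpec",
    "HeadPhantom",
    "ShrinkageStudy",
    "make_head_phantom",
    "make_dose",
    "polynomial_transform",
    "simulate_shrinkage",
    "translate_phantom",
    "make_shrinkage_study",
]


@dataclass
class PhantomSpec:
    """Geometry and intensity model of the synthetic head.

    Defaults give a 96×96×40-voxel volume at 2×2×3 mm — the working
    resolution of the pipeline — with the head well inside the field of
    view so that ±10 mm translations stay in-frame.
    """

    shape: tuple[int, int, int] = (40, 96, 96)  # (z, y, x)
    spacing: tuple[float, float, float] = (3.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    head_center_mm: tuple[float, float, float] = (60.0, 82.0, 96.0)
    head_semiaxes_mm: tuple[float, float, float] = (50.0, 66.0, 62.0)
    skull_inner_fraction: float = 0.88
    skull_hu: float = 1200.0
    bone_texture_hu: float = 80.0
    soft_hu: float = 40.0
    texture_hu: float = 15.0
    texture_corr_mm: float = 8.0
    noise_hu: float = 10.0
    tumor_center_mm: tuple[float, float, float] = (60.0, 70.0, 88.0)
    tumor_radius_mm: float = 15.0
    tumor_hu: float = 60.0
    couch_rows: tuple[int, int] = (85, 94)  # y-index slab
    couch_hu: float = 300.0
    seed: int = 0


@dataclass
class HeadPhantom:
    image: VolumeImage
    tumor: BinaryMask
    body: BinaryMask
    couch_box: VoxelBox
    spec: PhantomSpec


def _world_grids(spec: PhantomSpec):
    axes = [
        spec.origin[a] + spec.spacing[a] * np.arange(spec.shape[a]) for a in range(3)
    ]
    return np.meshgrid(*axes, indexing="ij")


def make_head_phantom(spec: PhantomSpec | None = None) -> HeadPhantom:
    """Planning-like CT with tumor mask, body mask and couch region."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    Z, Y, X = _world_grids(spec)
    cz, cy, cx = spec.head_center_mm
    az, ay, ax = spec.head_semiaxes_mm
    rho = np.sqrt(((Z - cz) / az) ** 2 + ((Y - cy) / ay) ** 2 + ((X - cx) / ax) ** 2)
    body = rho <= 1.0
    skull = (rho <= 1.0) & (rho >= spec.skull_inner_fraction)
    soft = rho < spec.skull_inner_fraction

    tz, ty, tx = spec.tumor_center_mm
    r_t = np.sqrt((Z - tz) ** 2 + (Y - ty) ** 2 + (X - tx) ** 2)
    tumor = soft & (r_t <= spec.tumor_radius_mm)

    values = np.full(spec.shape, AIR_HU)
    values[soft] = spec.soft_hu
    values[skull] = spec.skull_hu
    values[tumor] = spec.tumor_hu

    if spec.texture_hu > 0 or spec.bone_texture_hu > 0:
        sig = [spec.texture_corr_mm / s for s in spec.spacing]
        tex = ndimage.gaussian_filter(rng.standard_normal(spec.shape), sig, mode="wrap")
        tex /= tex.std()
        sel = soft & ~tumor
        values[sel] += spec.texture_hu * tex[sel]
        # trabecular density variation; without it the uniform shell would
        # leave tangential motion unobservable (aperture problem)
        values[skull] += spec.bone_texture_hu * tex[skull]
    if spec.noise_hu > 0:
        noise = rng.normal(0.0, spec.noise_hu, spec.shape)
        values[body] += noise[body]

    # couch slab outside the patient
    y0, y1 = spec.couch_rows
    couch_box: VoxelBox = ((0, spec.shape[0]), (y0, y1), (0, spec.shape[2]))
    values[:, y0:y1, :] = spec.couch_hu

    np.clip(values, -1000.0, 3000.0, out=values)
    image = VolumeImage(values, spec.spacing, spec.origin)
    return HeadPhantom(
        image=image,
        tumor=BinaryMask.from_image(image, tumor),
        body=BinaryMask.from_image(image, body),
        couch_box=couch_box,
        spec=spec,
    )


def make_dose(
    tumor: BinaryMask,
    prescription_gy: float = 70.0,
    margin_mm: float = 8.0,
    falloff_mm: float = 8.0,
    grid_spacing_mm: float = 4.0,
    grid_offset_mm: tuple[float, float, float] = (1.3, 1.3, 1.3),
) -> VolumeImage:
    """Planned-dose grid: prescription inside tumor+margin, Gaussian falloff.

    The dose lives on its own ``grid_spacing_mm`` isotropic grid, offset
    from the CT grid, as exported dose maps are.
    """
    if prescription_gy < 0:
        raise ParameterError("prescription must be non-negative")
    ref = VolumeImage(np.zeros(tumor.shape), tumor.spacing, tumor.origin)
    dist = ndimage.distance_transform_edt(~tumor.values, sampling=tumor.spacing)
    beyond = np.maximum(dist - margin_mm, 0.0)
    dose_ct = prescription_gy * np.exp(-((beyond / falloff_mm) ** 2))
    dose_img = ref.copy(values=dose_ct)

    extent = np.array(tumor.shape) * tumor.spacing
    n = np.ceil(extent / grid_spacing_mm).astype(int)
    target = VolumeImage(
        np.zeros(tuple(n)),
        (grid_spacing_mm,) * 3,
        np.asarray(tumor.origin) + np.asarray(grid_offset_mm),
    )
    out = resample_to_grid(dose_img, target, method="trilinear", fill=0.0)
    out.values = np.clip(out.values, 0.0, None)
    return out


_N_MONOMIALS = 10


def _poly_basis(spec_like: VolumeImage) -> np.ndarray:
    """2nd-order monomial basis on normalized world coordinates, shape (10, nz, ny, nx)."""
    axes = [
        spec_like.origin[a] + spec_like.spacing[a] * np.arange(spec_like.shape[a])
        for a in range(3)
    ]
    center = [0.5 * (ax_[0] + ax_[-1]) for ax_ in axes]
    half = [max(0.5 * (ax_[-1] - ax_[0]), 1.0) for ax_ in axes]
    Z, Y, X = np.meshgrid(*[(axes[a] - center[a]) / half[a] for a in range(3)], indexing="ij")
    one = np.ones_like(Z)
    return np.stack([one, Z, Y, X, Z * Z, Y * Y, X * X, Z * Y, Z * X, Y * X])


def polynomial_transform(
    image: VolumeImage,
    coeffs: np.ndarray | None = None,
    target_mean_mm: float = 5.5,
    body: BinaryMask | None = None,
    seed: int = 0,
) -> tuple[VolumeImage, DisplacementField]:
    """Warp ``image`` by a full 2nd-order polynomial displacement field.

    Each displacement component is a degree-2 polynomial in normalized
    world coordinates.  If ``coeffs`` (shape (3, 10)) is not given, random
    seeded coefficients are drawn and rescaled so the mean displacement
    magnitude over ``body`` (whole grid if None) equals ``target_mean_mm``.
    Returns the warped image and the exact analytic field.
    """
    basis = _poly_basis(image)
    if coeffs is None:
        rng = np.random.default_rng(seed)
        coeffs = rng.standard_normal((3, _N_MONOMIALS))
        vec = np.tensordot(coeffs, basis, axes=(1, 0))
        sel = body.values if body is not None else np.ones(image.shape, bool)
        mean_mag = float(np.mean(np.sqrt(np.sum(vec**2, axis=0))[sel]))
        if mean_mag > 0 and target_mean_mm > 0:
            coeffs = coeffs * (target_mean_mm / mean_mag)
    else:
        coeffs = np.asarray(coeffs, float).reshape(3, _N_MONOMIALS)
    vec = np.tensordot(coeffs, basis, axes=(1, 0))
    truth = DisplacementField(vec, image.spacing.copy(), image.origin.copy())
    return warp(image, truth, method="trilinear"), truth


def simulate_shrinkage(
    planning: VolumeImage,
    tumor: BinaryMask,
    volume_factor: float = 0.67,
    residual_hu: float = 15.0,
    inward_amp_mm: float = 2.0,
    pull_range_mm: float = 10.0,
    soft_hu: float = 40.0,
    noise_hu: float = 10.0,
    seed: int = 0,
) -> tuple[VolumeImage, BinaryMask]:
    """Posttreatment image: concentric tumor shrinkage plus inward tissue pull.

    The tumor is replaced by a concentric tumor whose radius is scaled by
    ``volume_factor**(1/3)`` at ``residual_hu`` — default 15 HU, the
    markedly hypodense (necrotic/fluid-like) appearance of a residual
    mass after a lethal dose, which is what breaks voxel correspondence
    for plain intensity-based registration; vacated voxels take
    soft-tissue HU.  Tissue around the tumor is pulled
    smoothly inward (radial displacement ``inward_amp_mm`` at the tumor
    surface, Gaussian decay over ``pull_range_mm``).  Fresh noise is drawn
    only for the repainted voxels; elsewhere the (warped) planning
    realisation is kept, so the tumor region is the only site where
    voxel correspondence is broken.
    """
    if not (0.0 < volume_factor <= 1.0):
        raise ParameterError("volume_factor must be in (0, 1]")
    if not tumor.values.any():
        raise ParameterError("tumor mask is empty")
    rng = np.random.default_rng(seed)
    f = volume_factor ** (1.0 / 3.0)
    spacing = np.asarray(planning.spacing, float)
    idx = np.argwhere(tumor.values)
    centroid = planning.origin + (idx.mean(axis=0)) * spacing  # world mm

    Z, Y, X = _world_grids_like(planning)
    dz, dy, dx = Z - centroid[0], Y - centroid[1], X - centroid[2]
    r = np.sqrt(dz * dz + dy * dy + dx * dx)

    # shrunken mask: x is inside iff its radially magnified preimage was tumor
    scale = np.where(r > 0, 1.0 / f, 1.0)
    pre = np.stack(
        [
            (centroid[a] + d * scale - planning.origin[a]) / spacing[a]
            for a, d in enumerate((dz, dy, dx))
        ]
    )
    shrunk_vals = ndimage.map_coordinates(
        tumor.values.astype(float), pre, order=0, mode="constant", cval=0.0
    )
    shrunk = shrunk_vals > 0.5

    post_vals = planning.values
    if inward_amp_mm > 0:
        r_eff = (3.0 * tumor.voxel_count() * np.prod(spacing) / (4.0 * np.pi)) ** (1.0 / 3.0)
        amp = inward_amp_mm * np.exp(-(((np.maximum(r, r_eff) - r_eff) / pull_range_mm) ** 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(r > 0, 1.0 / r, 0.0)
        vec = np.stack([amp * dz * unit, amp * dy * unit, amp * dx * unit])
        pull = DisplacementField(vec, planning.spacing.copy(), planning.origin.copy())
        post_vals = warp(planning, pull, method="trilinear").values

    post = planning.copy(values=post_vals)
    vacated = tumor.values & ~shrunk
    post.values[shrunk] = residual_hu + rng.normal(0.0, noise_hu, int(shrunk.sum()))
    post.values[vacated] = soft_hu + rng.normal(0.0, noise_hu, int(vacated.sum()))
    np.clip(post.values, -1000.0, 3000.0, out=post.values)
    return post, BinaryMask.from_image(post, shrunk)


def _world_grids_like(image: VolumeImage):
    axes = [image.origin[a] + image.spacing[a] * np.arange(image.shape[a]) for a in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def translate_phantom(image: VolumeImage, t_mm) -> VolumeImage:
    """Move the content by ``+t_mm`` (world): output(x) = image(x − t)."""
    t = np.asarray(t_mm, float)
    return warp(image, DisplacementField.constant(image, -t), method="trilinear")


@dataclass
class ShrinkageStudy:
    """Planning/posttreatment pair with dose, masks and geometry — the
    standard fixture for the with/without-IMP comparison."""

    planning: VolumeImage
    posttreatment: VolumeImage
    dose: VolumeImage
    tumor: BinaryMask            # planning-CT tumor
    shrunken_tumor: BinaryMask   # posttreatment truth
    body: BinaryMask
    couch_box: VoxelBox
    seed: int


def make_shrinkage_study(
    seed: int = 0,
    volume_factor: float = 0.67,
    prescription_gy: float = 70.0,
    anatomic_mean_mm: float = 5.0,
    spec: PhantomSpec | None = None,
) -> ShrinkageStudy:
    """Generate the standard seeded shrinkage study (lethal in-tumor dose).

    The posttreatment image differs from planning by (a) concentric tumor
    shrinkage with a hypodense residual and a local inward tissue pull and
    (b) a smooth 2nd-order anatomic deformation with mean in-body
    magnitude ``anatomic_mean_mm`` — head-and-neck patients change posture
    and lose weight over a treatment course, so the surrounding anatomy
    moves too, and the deformable stage has real work to do outside the
    tumor.  The truth contour is the shrunken mask carried through the
    same anatomic deformation.
    """
    from .metrics import propagate_mask

    spec = replace(spec or PhantomSpec(), seed=seed)
    ph = make_head_phantom(spec)
    post0, shrunk0 = simulate_shrinkage(
        ph.image,
        ph.tumor,
        volume_factor=volume_factor,
        soft_hu=spec.soft_hu,
        noise_hu=spec.noise_hu,
        seed=seed + 1_000_003,
    )
    if anatomic_mean_mm > 0:
        _, anat = polynomial_transform(
            post0, target_mean_mm=anatomic_mean_mm, body=ph.body, seed=seed + 2_000_003
        )
        # the patient deforms, the couch and surrounding air do not: taper
        # the field to zero away from the body (10 mm decay)
        dist_out = ndimage.distance_transform_edt(~ph.body.values, sampling=ph.body.spacing)
        anat = DisplacementField(
            anat.vectors * np.exp(-((dist_out / 10.0) ** 2)),
            anat.spacing,
            anat.origin,
        )
        post = warp(post0, anat, method="trilinear")
        shrunk = propagate_mask(shrunk0, anat)
        body = propagate_mask(ph.body, anat)
    else:
        post, shrunk, body = post0, shrunk0, ph.body
    dose = make_dose(ph.tumor, prescription_gy=prescription_gy)
    return ShrinkageStudy(
        planning=ph.image,
        posttreatment=post,
        dose=dose,
        tumor=ph.tumor,
        shrunken_tumor=shrunk,
        body=body,
        couch_box=ph.couch_box,
        seed=seed,
    )
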