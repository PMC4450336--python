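"""Geometric image model shared by every pipeline stage.

Conventions
-----------
* Arrays are indexed ``(z, y, x)`` — slice, row, column.
* World coordinates follow the DICOM patient (LPS) convention and are
  stored in the same ``(z, y, x)`` component order as the array axes.
  Axes are assumed axis-aligned with the patient axes.
* Voxel indices are 0-based; ``origin`` is the world position (mm) of the
  *center* of voxel ``(0, 0, 0)``.
* Displacements are millimeters in the static frame; they are converted
  to (anisotropic) voxel units only inside :func:`warp`.
* Samples taken outside an image's extent return −1000 HU (air) unless a
  different fill value is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import GridCompatibilityError, ParameterError

AIR_HU = -1000.0

__all__ = [
    "AIR_HU",
    "VolumeImage",
    "DisplacementField",
    "BinaryMask",
    "resample",
    "resample_to_grid",
    "warp",
    "gradient",
]


def _as_vec3(v) -> np.ndarray:
    a = np.asarray(v, dtype=float).reshape(3)
    return a


@dataclass
class VolumeImage:
    """A 3-D scalar grid (HU for CT, Gy for dose) with its geometry.

    Parameters
    ----------
    values : (nz, ny, nx) float array
    spacing : per-axis voxel size in mm, order (z, y, x); strictly positive
    origin : world position (mm, LPS, order (z, y, x)) of the center of
        voxel (0, 0, 0)
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ParameterError("values must be a 3-D array")
        self.spacing = _as_vec3(self.spacing)
        self.origin = _as_vec3(self.origin)
        if not np.all(self.spacing > 0):
            raise ParameterError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("values must be finite everywhere")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def same_grid(self, other) -> bool:
        """Grid compatibility: identical shape, spacing and origin."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def require_same_grid(self, other, what: str = "operands"):
        if not self.same_grid(other):
            raise GridCompatibilityError(
                f"{what} are not grid-compatible: "
                f"{self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.shape}/{other.spacing}/{other.origin}"
            )

    def copy(self, values: np.ndarray | None = None) -> "VolumeImage":
        return VolumeImage(
            self.values.copy() if values is None else np.asarray(values, float),
            self.spacing.copy(),
            self.origin.copy(),
        )

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1-D arrays of voxel-center world coordinates (mm)."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)
        )


@dataclass
class DisplacementField:
    """Per-voxel 3-vector displacements (mm) on a static-image grid.

    ``vectors`` has shape ``(3, nz, ny, nx)``; component ``c`` is the
    displacement along world axis ``c`` (same (z, y, x) order as the grid).
    The field points from a static-grid voxel to its corresponding
    location in the moving image (backward-mapping convention).
    """

    vectors: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[0] != 3:
            raise ParameterError("vectors must have shape (3, nz, ny, nx)")
        self.spacing = _as_vec3(self.spacing)
        self.origin = _as_vec3(self.origin)
        if not np.all(self.spacing > 0):
            raise ParameterError("spacing must be strictly positive")
        if not np.all(np.isfinite(self.vectors)):
            raise ParameterError("displacement vectors must be finite")

    @classmethod
    def zeros_like(cls, image: VolumeImage) -> "DisplacementField":
        return cls(np.zeros((3, *image.shape)), image.spacing.copy(), image.origin.copy())

    @classmethod
    def constant(cls, image: VolumeImage, t_mm) -> "DisplacementField":
        t = _as_vec3(t_mm)
        vec = np.broadcast_to(t.reshape(3, 1, 1, 1), (3, *image.shape)).copy()
        return cls(vec, image.spacing.copy(), image.origin.copy())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[1:]

    def same_grid(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def magnitude(self) -> np.ndarray:
        """Per-voxel Euclidean displacement magnitude (mm)."""
        return np.sqrt(np.sum(self.vectors**2, axis=0))

    def copy(self) -> "DisplacementField":
        return DisplacementField(self.vectors.copy(), self.spacing.copy(), self.origin.copy())


@dataclass
class BinaryMask:
    """Boolean voxel mask on the grid of a parent :class:`VolumeImage`."""

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ParameterError("mask values must be a 3-D array")
        self.spacing = _as_vec3(self.spacing)
        self.origin = _as_vec3(self.origin)
        if not np.all(self.spacing > 0):
            raise ParameterError("spacing must be strictly positive")

    @classmethod
    def from_image(cls, image: VolumeImage, values: np.ndarray) -> "BinaryMask":
        return cls(values, image.spacing.copy(), image.origin.copy())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def same_grid(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def voxel_count(self) -> int:
        return int(self.values.sum())

    def volume_mm3(self) -> float:
        return self.voxel_count() * float(np.prod(self.spacing))

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.values.copy(), self.spacing.copy(), self.origin.copy())


_ORDER = {"nearest": 0, "trilinear": 1}


def _interp_order(method: str) -> int:
    try:
        return _ORDER[method]
    except KeyError:
        raise ParameterError(f"unknown interpolation method {method!r}") from None


def _sample(values: np.ndarray, idx: np.ndarray, order: int, fill: float) -> np.ndarray:
    """Sample ``values`` at fractional index coordinates ``idx`` (3, ...)."""
    return ndimage.map_coordinates(
        values, idx, order=order, mode="constant", cval=fill, prefilter=False
    )


def resample(image: VolumeImage, target_spacing, method: str = "nearest") -> VolumeImage:
    """Resample onto a grid with ``target_spacing`` covering the same physical extent.

    The physical extent is the voxel-boundary box: lower boundary at
    ``origin − spacing/2``, size ``shape·spacing``.  The output voxel count
    per axis is ``ceil(extent / target)`` and the output origin sits half a
    target voxel inside the lower boundary, so two images sharing a world
    extent resample onto identical grids regardless of native spacing.
    """
    ts = _as_vec3(target_spacing)
    if not np.all(ts > 0):
        raise ParameterError("target_spacing must be strictly positive")
    order = _interp_order(method)
    shape = np.array(image.shape)
    extent = shape * image.spacing
    lower = image.origin - image.spacing / 2.0
    # guard against ceil(3.0000000001) from float noise
    out_shape = np.ceil(extent / ts - 1e-9).astype(int)
    out_shape = np.maximum(out_shape, 1)
    out_origin = lower + ts / 2.0
    ax = [
        (out_origin[a] + ts[a] * np.arange(out_shape[a]) - image.origin[a]) / image.spacing[a]
        for a in range(3)
    ]
    idx = np.stack(np.meshgrid(*ax, indexing="ij"))
    # the output grid covers the same extent, so boundary samples that land
    # in the outer half-voxel are clamped to the edge rather than treated
    # as outside
    for a in range(3):
        idx[a] = np.clip(idx[a], 0, image.shape[a] - 1)
    out = _sample(image.values, idx, order, AIR_HU)
    return VolumeImage(out, ts, out_origin)


def resample_to_grid(
    image: VolumeImage, reference: VolumeImage, method: str = "trilinear", fill: float = AIR_HU
) -> VolumeImage:
    """Sample ``image`` at the voxel centers of ``reference``'s grid."""
    order = _interp_order(method)
    ax = [
        (reference.origin[a] + reference.spacing[a] * np.arange(reference.shape[a]) - image.origin[a])
        / image.spacing[a]
        for a in range(3)
    ]
    idx = np.stack(np.meshgrid(*ax, indexing="ij"))
    out = _sample(image.values, idx, order, fill)
    return VolumeImage(out, reference.spacing.copy(), reference.origin.copy())


def warp(
    image: VolumeImage,
    field: DisplacementField,
    method: str = "trilinear",
    fill: float = AIR_HU,
) -> VolumeImage:
    """Backward-map ``image`` through ``field``.

    The output lives on the field's (static) grid; the voxel at static world
    position ``x`` takes the value of ``image`` sampled at ``x + field(x)``.
    Samples outside the image extent return ``fill`` (−1000 HU by default).
    """
    order = _interp_order(method)
    idx = np.empty_like(field.vectors)
    for a in range(3):
        world = (
            field.origin[a]
            + field.spacing[a]
            * np.arange(field.shape[a]).reshape([-1 if i == a else 1 for i in range(3)])
            + field.vectors[a]
        )
        idx[a] = (world - image.origin[a]) / image.spacing[a]
    out = _sample(image.values, idx, order, fill)
    return VolumeImage(out, field.spacing.copy(), field.origin.copy())


def gradient(image: VolumeImage) -> np.ndarray:
    """Spatial gradient, shape ``(3, nz, ny, nx)``, units HU/mm.

    Central differences in the interior, one-sided at the boundary.  A
    degenerate axis (length 1) yields a zero component.
    """
    out = np.zeros((3, *image.shape))
    for a in range(3):
        if image.shape[a] >= 2:
            out[a] = np.gradient(image.values, image.spacing[a], axis=a)
    return out
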