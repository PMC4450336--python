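"""Bone-driven translation-only rigid registration.

Head-and-neck patients are immobilised in thermoplastic masks, so a pure
translation initialises the deformable stage.  Both images are thresholded
at ~500 HU so only the skeleton remains, and the translation maximising
the Pearson correlation coefficient of the thresholded intensities is
found by exhaustive grid search with parabolic sub-step refinement:

1.  coarse stage — exhaustive integer-voxel search over the whole search
    radius, evaluated for all offsets at once through an FFT
    cross-correlation surface of the mean-subtracted thresholded images;
2.  fine stage — exhaustive ``step_mm`` search in a ±3 mm cube around the
    coarse peak, Pearson correlation evaluated over the static bone shell
    (bone mask dilated by 2 voxels) with trilinear sampling of the moving
    image, recentred if the peak lands on the cube boundary;
3.  per-axis parabolic refinement of the correlation peak.

Self-registration returns exactly zero: the zero offset is always a
candidate and refinement is skipped when the peak correlation is already
perfect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .errors import DegenerateInputError, ParameterError
from .grid import BinaryMask, DisplacementField, VolumeImage, warp

__all__ = ["RigidParams", "bone_threshold", "register_translation", "apply_translation"]

_MAX_FINE_SITES = 40_000


@dataclass
class RigidParams:
    bone_threshold_hu: float = 500.0
    search_radius_mm: float = 20.0
    step_mm: float = 1.0

    def __post_init__(self):
        if self.search_radius_mm <= 0 or self.step_mm <= 0:
            raise ParameterError("search radius and step must be positive")


def bone_threshold(image: VolumeImage, threshold: float = 500.0) -> BinaryMask:
    """Mask of voxels at or above the bone threshold."""
    return BinaryMask.from_image(image, image.values >= threshold)


def apply_translation(image: VolumeImage, t_mm) -> VolumeImage:
    """Warp with the constant field ``t_mm`` (output at x samples input at x+t)."""
    return warp(image, DisplacementField.constant(image, t_mm), method="trilinear")


def _masked(image: VolumeImage, thr: float) -> np.ndarray:
    return np.where(image.values >= thr, image.values, 0.0)


def _coarse_voxel_offset(a: np.ndarray, b: np.ndarray, spacing, radius_mm: float) -> np.ndarray:
    """Integer-voxel offset t maximising sum_x a(x)·b(x+t), |t·spacing| ≤ radius."""
    a0 = a - a.mean()
    b0 = b - b.mean()
    # C[k] = sum_x a0(x) * b0(x - s) with s = k - (N-1); we want s = -t
    c = signal.fftconvolve(a0, b0[::-1, ::-1, ::-1], mode="full")
    shape = np.array(a.shape)
    center = shape - 1
    max_vox = np.floor(radius_mm / np.asarray(spacing)).astype(int)
    sl = tuple(
        slice(center[i] - max_vox[i], center[i] + max_vox[i] + 1) for i in range(3)
    )
    window = c[sl]
    k = np.unravel_index(np.argmax(window), window.shape)
    s = np.array(k) - max_vox  # offset of b relative to a
    return -s  # t such that b(x + t) aligns with a(x)


def _fine_corr(values_a, moving_masked, base_idx, spacing, t_mm):
    idx = base_idx + (np.asarray(t_mm, float) / spacing)[:, None]
    vb = ndimage.map_coordinates(
        moving_masked, idx, order=1, mode="constant", cval=0.0, prefilter=False
    )
    sa = values_a.std()
    sb = vb.std()
    if sa == 0 or sb == 0:
        return -np.inf
    return float(np.mean((values_a - values_a.mean()) * (vb - vb.mean())) / (sa * sb))


def register_translation(
    static: VolumeImage, moving: VolumeImage, params: RigidParams | None = None
) -> np.ndarray:
    """Translation t (mm, order z,y,x) such that ``warp(moving, t) ≈ static``."""
    p = params or RigidParams()
    static.require_same_grid(moving, "register_translation inputs")
    a = _masked(static, p.bone_threshold_hu)
    b = _masked(moving, p.bone_threshold_hu)
    if not (a > 0).any() or not (b > 0).any():
        raise DegenerateInputError("no bone voxels above threshold in one of the images")

    spacing = static.spacing
    t_coarse = _coarse_voxel_offset(a, b, spacing, p.search_radius_mm) * spacing

    # correlation support: static bone shell (captures the bone/soft edge)
    shell = ndimage.binary_dilation(a > 0, iterations=2)
    sites = np.argwhere(shell)
    if len(sites) > _MAX_FINE_SITES:
        stride = int(np.ceil(len(sites) / _MAX_FINE_SITES))
        sites = sites[::stride]
    base_idx = sites.T.astype(float)
    values_a = a[sites[:, 0], sites[:, 1], sites[:, 2]]

    step = p.step_mm
    offsets_1d = np.arange(-3, 4) * step
    t_best = t_coarse.astype(float)
    for _recentre in range(5):
        best = (-np.inf, np.zeros(3))
        cube = {}
        for dz in offsets_1d:
            for dy in offsets_1d:
                for dx in offsets_1d:
                    t = t_best + np.array([dz, dy, dx])
                    cval = _fine_corr(values_a, b, base_idx, spacing, t)
                    cube[(dz, dy, dx)] = cval
                    if cval > best[0]:
                        best = (cval, t)
        peak_corr, t_peak = best
        if not np.isfinite(peak_corr):
            raise DegenerateInputError("empty bone overlap at every candidate translation")
        dpk = t_peak - t_best
        on_edge = np.any(np.abs(dpk) >= offsets_1d[-1] - 1e-9)
        t_best = t_peak
        if not on_edge:
            break

    # parabolic sub-step refinement per axis (skip if the match is already perfect)
    if peak_corr < 1.0 - 1e-12:
        refined = t_best.copy()
        for axis in range(3):
            e = np.zeros(3)
            e[axis] = step
            c0 = peak_corr
            cm = _fine_corr(values_a, b, base_idx, spacing, t_best - e)
            cp = _fine_corr(values_a, b, base_idx, spacing, t_best + e)
            den = cm - 2.0 * c0 + cp
            if np.isfinite(cm) and np.isfinite(cp) and den < 0:
                delta = 0.5 * (cm - cp) / den
                refined[axis] += float(np.clip(delta, -1.0, 1.0)) * step
        t_best = refined

    return np.clip(t_best, -p.search_radius_mm, p.search_radius_mm)
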