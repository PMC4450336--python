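"""Image preparation: couch removal, air clamping, ROI crop, standard resampling.

Nonuniformities outside the patient (couch, immobilisation gear, streaks)
would feed spurious forces into the registration, so they are pushed to
air (−1000 HU) first; both images of a study are then brought to the
common working resolution of 2×2×3 mm with nearest-neighbour sampling.
Fixed order: couch → air clamp → crop → resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import AIR_HU, VolumeImage, resample

__all__ = ["PreprocessParams", "VoxelBox", "remove_couch", "clamp_air", "crop_to_roi", "standardize", "preprocess_image"]

#: a voxel-index box: ((z_lo, z_hi), (y_lo, y_hi), (x_lo, x_hi)), half-open
VoxelBox = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

DEFAULT_SPACING = (3.0, 2.0, 2.0)  # (z, y, x) mm — working resolution


@dataclass
class PreprocessParams:
    couch_box: VoxelBox | None = None
    air_threshold: float = -500.0
    crop_box: VoxelBox | None = None
    target_spacing: tuple[float, float, float] = DEFAULT_SPACING


def _clip_box(box: VoxelBox, shape) -> tuple[slice, slice, slice]:
    return tuple(
        slice(max(0, int(lo)), min(int(shape[a]), int(hi)))
        for a, (lo, hi) in enumerate(box)
    )


def remove_couch(image: VolumeImage, couch_box: VoxelBox | None) -> VolumeImage:
    """Set every voxel inside the (clipped) box to air; no-op for None/empty box."""
    out = image.copy()
    if couch_box is None:
        return out
    sl = _clip_box(couch_box, image.shape)
    out.values[sl[0], sl[1], sl[2]] = AIR_HU
    return out


def clamp_air(image: VolumeImage, threshold: float = -500.0) -> VolumeImage:
    """Values strictly below ``threshold`` become −1000 HU; the rest pass through.

    −500 itself is kept: the clamp applies to values *below* the threshold.
    """
    out = image.copy()
    out.values[out.values < threshold] = AIR_HU
    return out


def crop_to_roi(image: VolumeImage, box: VoxelBox) -> VolumeImage:
    """Keep the voxels in ``box``; the origin shifts so world positions are preserved."""
    sl = _clip_box(box, image.shape)
    lo = np.array([s.start for s in sl], float)
    out_vals = image.values[sl[0], sl[1], sl[2]].copy()
    return VolumeImage(out_vals, image.spacing.copy(), image.origin + lo * image.spacing)


def standardize(
    image: VolumeImage,
    air_threshold: float = -500.0,
    target_spacing=DEFAULT_SPACING,
) -> VolumeImage:
    """Air clamp followed by nearest-neighbour resampling to the working grid.

    Two images covering the same world extent come out grid-compatible
    regardless of their native spacing.
    """
    return resample(clamp_air(image, air_threshold), target_spacing, method="nearest")


def preprocess_image(image: VolumeImage, params: PreprocessParams | None = None) -> VolumeImage:
    """Full preparation chain: couch → clamp → crop → resample."""
    p = params or PreprocessParams()
    out = remove_couch(image, p.couch_box)
    out = clamp_air(out, p.air_threshold)
    if p.crop_box is not None:
        out = crop_to_roi(out, p.crop_box)
    return resample(out, p.target_spacing, method="nearest")
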