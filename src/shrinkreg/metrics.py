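"""Evaluation: Dice overlap, mask propagation, field statistics, shift recovery."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridCompatibilityError
from .grid import BinaryMask, DisplacementField, VolumeImage, warp

__all__ = [
    "dsc",
    "propagate_mask",
    "shift_recovery",
    "field_stats",
    "FieldStats",
    "evaluation_report",
]


def dsc(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient in percent: 2|A∩B| / (|A|+|B|) × 100.

    100 means a perfect match, 0 completely uncorrelated masks.  Two empty
    masks are defined to match perfectly (limit convention).
    """
    if not a.same_grid(b):
        raise GridCompatibilityError("DSC requires grid-compatible masks")
    na, nb = a.voxel_count(), b.voxel_count()
    if na == 0 and nb == 0:
        return 100.0
    inter = int(np.count_nonzero(a.values & b.values))
    return 200.0 * inter / (na + nb)


def propagate_mask(mask: BinaryMask, field: DisplacementField) -> BinaryMask:
    """Deform a structure mask through a displacement field.

    Backward mapping with nearest-neighbour interpolation of the binary
    values; the result lives on the field's (static) grid.  Out-of-extent
    samples are background.
    """
    img = VolumeImage(mask.values.astype(float), mask.spacing, mask.origin)
    out = warp(img, field, method="nearest", fill=0.0)
    return BinaryMask(out.values > 0.5, field.spacing.copy(), field.origin.copy())


def shift_recovery(
    true_field: DisplacementField,
    recovered_field: DisplacementField,
    body_mask: BinaryMask,
    tol_mm: float = 2.0,
) -> float:
    """Fraction of body voxels whose vector error magnitude is ≤ ``tol_mm``."""
    if not true_field.same_grid(recovered_field) or not body_mask.same_grid(true_field):
        raise GridCompatibilityError("shift_recovery requires one common grid")
    err = np.sqrt(np.sum((recovered_field.vectors - true_field.vectors) ** 2, axis=0))
    inside = body_mask.values
    if not inside.any():
        return 1.0
    return float(np.count_nonzero(err[inside] <= tol_mm) / np.count_nonzero(inside))


@dataclass
class FieldStats:
    mean_magnitude_mm: float
    max_magnitude_mm: float
    mean_per_axis_mm: tuple[float, float, float]  # (z, y, x)


def field_stats(field: DisplacementField, mask: BinaryMask | None = None) -> FieldStats:
    """Displacement-magnitude summary over ``mask`` (whole grid if None)."""
    if mask is not None:
        if not mask.same_grid(field):
            raise GridCompatibilityError("field_stats mask grid mismatch")
        sel = mask.values
    else:
        sel = np.ones(field.shape, bool)
    if not sel.any():
        return FieldStats(0.0, 0.0, (0.0, 0.0, 0.0))
    mag = field.magnitude()[sel]
    per_axis = tuple(float(np.mean(field.vectors[c][sel])) for c in range(3))
    return FieldStats(float(np.mean(mag)), float(np.max(mag)), per_axis)


def evaluation_report(cases: list[dict], path=None):
    """Per-case DSC table (rigid / plain Demons / with intensity modification).

    ``cases`` is a list of dicts with keys ``case``, ``dsc_rigid``,
    ``dsc_imp``, ``dsc_no_imp`` and optionally ``mean_field_mm`` /
    ``max_field_mm``.  Returns a DataFrame with a trailing ``mean`` row;
    if ``path`` is given, also writes it as a tab-delimited table.
    """
    import pandas as pd

    columns = ["case", "dsc_rigid", "dsc_imp", "dsc_no_imp", "mean_field_mm", "max_field_mm"]
    df = pd.DataFrame(cases)
    df = df[[c for c in columns if c in df.columns]]
    numeric = df.columns.drop("case")
    summary = df[numeric].mean().to_frame().T
    summary.insert(0, "case", "mean")
    df = pd.concat([df, summary], ignore_index=True)
    if path is not None:
        df.to_csv(path, sep="\t", index=False, float_format="%.1f")
    return df
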