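"""Intensity-Modification Procedure (IMP).

Radiation kills tumor cells, so between planning and posttreatment CT the
primary tumor loses density and volume and voxelwise correspondence breaks
down, which derails intensity-based deformable registration.  The IMP
restores an approximate correspondence *before* registration by predicting
each planning-CT tumor voxel's posttreatment intensity from the planned
dose it receives:

1.  CT number to linear attenuation:  mu = I0 * mu_W / 1000 + mu_W
    (air −1000 HU -> 0, water 0 HU -> mu_W).
2.  Attenuation is proportional to the number of cells in the voxel, so
    after irradiation  mu_S = mu_0 * SF  with the linear-quadratic (LQ)
    surviving fraction

        SF = exp( -alpha * D * (1 + d / (alpha/beta)) ),

    D the total voxel dose (Gy), d = D / n_fractions the dose per
    fraction; cell proliferation is neglected.
3.  Back to CT numbers:  IS = (mu_0 * SF - mu_W) * 1000 / mu_W,
    algebraically IS = (I0 + 1000) * SF - 1000.
4.  A scale step matches the tumor-region intensity sum of the modified
    planning image to that of the (rigidly aligned) posttreatment image,
    absorbing the large uncertainty in the radiobiological parameters.

Sums and the multiplicative scale operate on the offset scale
``value + 1000`` (proportional to attenuation and hence to cell count);
raw HU sums can be negative or zero, which would make the ratio
ill-defined.

Only tumor voxels are touched; every other planning-CT voxel passes
through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, GridCompatibilityError, ParameterError
from .grid import BinaryMask, VolumeImage, resample_to_grid

__all__ = [
    "RadiobiologyParams",
    "hu_to_mu",
    "mu_to_hu",
    "survival_fraction",
    "modify_intensity",
    "resample_dose_to_ct",
    "scale_tumor",
    "apply_imp",
]


@dataclass
class RadiobiologyParams:
    """LQ-model parameters.

    alpha : LQ alpha, Gy^-1 (default 0.33, a literature value for
        nasopharyngeal carcinoma)
    alpha_beta : alpha/beta ratio, Gy (default 10, nominal for tumors)
    n_fractions : number of treatment fractions; the per-voxel dose per
        fraction is d = D / n_fractions (default 35, a conventional
        2-Gy-per-fraction schedule for a 70 Gy prescription)
    mu_water : linear attenuation coefficient of water (default 0.1928).
        The HU conversions are scale-invariant in mu_water (it cancels),
        so any consistent unit works.
    """

    alpha: float = 0.33
    alpha_beta: float = 10.0
    n_fractions: int = 35
    mu_water: float = 0.1928

    def __post_init__(self):
        if self.alpha <= 0:
            raise ParameterError("alpha must be positive")
        if self.alpha_beta <= 0:
            raise ParameterError("alpha/beta must be positive")
        if self.n_fractions < 1:
            raise ParameterError("n_fractions must be >= 1")
        if self.mu_water <= 0:
            raise ParameterError("mu_water must be positive")


def hu_to_mu(hu, params: RadiobiologyParams | None = None):
    """CT number (HU) to linear attenuation coefficient."""
    p = params or RadiobiologyParams()
    return np.asarray(hu, float) * p.mu_water / 1000.0 + p.mu_water


def mu_to_hu(mu, params: RadiobiologyParams | None = None):
    """Exact inverse of :func:`hu_to_mu`."""
    p = params or RadiobiologyParams()
    return (np.asarray(mu, float) - p.mu_water) * 1000.0 / p.mu_water


def survival_fraction(dose_gy, params: RadiobiologyParams | None = None):
    """LQ surviving fraction for total voxel dose ``dose_gy`` (Gy).

    SF = exp(-alpha * D * (1 + d/(alpha/beta))), d = D/n_fractions.
    Strictly decreasing in D and in alpha; SF(0) = 1.
    """
    p = params or RadiobiologyParams()
    D = np.asarray(dose_gy, float)
    if np.any(D < 0):
        raise ParameterError("dose must be non-negative")
    d = D / p.n_fractions
    return np.exp(-p.alpha * D * (1.0 + d / p.alpha_beta))


def modify_intensity(hu, sf, params: RadiobiologyParams | None = None):
    """Post-kill CT number: attenuation scaled by the surviving fraction.

    Computed through the attenuation domain,
    ``IS = (hu_to_mu(I0) * SF - mu_W) * 1000 / mu_W``;
    algebraically identical to ``(I0 + 1000) * SF - 1000``.
    """
    p = params or RadiobiologyParams()
    mu = hu_to_mu(hu, p) * np.asarray(sf, float)
    return mu_to_hu(mu, p)


def resample_dose_to_ct(dose: VolumeImage, ct: VolumeImage) -> VolumeImage:
    """Trilinearly sample the dose grid at the CT voxel centers.

    Alignment is purely by world (DICOM patient) coordinates; CT voxels
    outside the dose grid's extent receive 0 Gy.
    """
    out = resample_to_grid(dose, ct, method="trilinear", fill=0.0)
    out.values = np.clip(out.values, 0.0, None)
    return out


def scale_tumor(
    modified: VolumeImage, tumor_mask: BinaryMask, static: VolumeImage
) -> VolumeImage:
    """Scale tumor voxels so their offset-intensity sum matches the static image.

    With o = value + 1000, let S0 = sum of o over the tumor mask in
    ``modified`` and S the same sum in ``static``; every tumor voxel's o is
    multiplied by S/S0.  Non-tumor voxels are untouched.
    """
    modified.require_same_grid(static, "scale_tumor images")
    if not tumor_mask.same_grid(modified):
        raise GridCompatibilityError("tumor mask grid does not match the images")
    m = tumor_mask.values
    if not m.any():
        raise DegenerateInputError("tumor mask is empty")
    s0 = float(np.sum(modified.values[m] + 1000.0))
    s = float(np.sum(static.values[m] + 1000.0))
    if s0 <= 0:
        raise DegenerateInputError("tumor region of the modified image sums to air")
    out = modified.copy()
    out.values[m] = (modified.values[m] + 1000.0) * (s / s0) - 1000.0
    return out


def apply_imp(
    planning: VolumeImage,
    dose: VolumeImage,
    tumor: BinaryMask,
    static: VolumeImage,
    params: RadiobiologyParams | None = None,
) -> VolumeImage:
    """Full IMP: dose resampling, LQ modification, sum-matching scale.

    ``planning`` and ``static`` must already be on a common grid (i.e.
    after preprocessing and rigid alignment); ``dose`` may live on its own
    grid and is resampled here.  Returns the planning image with only the
    tumor voxels modified.
    """
    p = params or RadiobiologyParams()
    planning.require_same_grid(static, "apply_imp images")
    dose_ct = resample_dose_to_ct(dose, planning)
    out = planning.copy()
    m = tumor.values
    if not m.any():
        raise DegenerateInputError("tumor mask is empty")
    sf = survival_fraction(dose_ct.values[m], p)
    # the modify -> scale composition evaluated on the offset scale
    # (value + 1000, proportional to attenuation): algebraically identical
    # to modify_intensity followed by scale_tumor, but it never stores the
    # near-air intermediate HU values, whose offsets underflow at strongly
    # lethal doses (SF below ~1e-13)
    o_mod = hu_to_mu(planning.values[m], p) * sf * (1000.0 / p.mu_water)
    s0 = float(o_mod.sum())
    if s0 <= 0:
        raise DegenerateInputError("tumor region of the modified image sums to air")
    s = float(np.sum(static.values[m] + 1000.0))
    out.values[m] = o_mod * (s / s0) - 1000.0
    return out
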