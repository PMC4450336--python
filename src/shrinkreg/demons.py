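"""Single-resolution symmetric-force ("active force") Demons registration.

The displacement field D on the static grid is iterated as

    D_n = G_sigma * ( D_{n-1} + u_n ),

where the per-voxel update combines the static- and moving-gradient
(passive and active) force terms with a shared normalisation::

    u = (I - I') * [ grad(I)  / (|grad(I)|^2  + k^2 (I - I')^2)
                   + grad(I') / (|grad(I')|^2 + k^2 (I - I')^2) ]

with I the static intensity, I' the intensity of the moving image warped
by the current field, and gradients in HU/mm so that u is in mm.  The
sign follows from the backward-mapping warp convention used throughout
the package (the warped moving image at x samples the moving image at
x + D(x)): linearising I'(x) in an increment of D gives the update above,
which drives I' toward I.  k (default 0.4) limits the per-iteration step
to 1/k mm in uniform-gradient regions; sigma (default 1 voxel) is the
width of the Gaussian regulariser.

No multiresolution pyramid and no diffeomorphic composition: the field
is additively updated and smoothed as a whole, exactly as written above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import NumericalFailureError, ParameterError
from .grid import DisplacementField, VolumeImage, gradient, warp

__all__ = ["RegistrationParams", "RegistrationResult", "demons_force", "regularize", "register"]

#: floor under the force denominators; a term whose denominator falls
#: below this contributes nothing (flat region with matched intensities)
DENOMINATOR_FLOOR = 1e-9


@dataclass
class RegistrationParams:
    """Demons tuning knobs.

    sigma : Gaussian regulariser width in voxels (default 1)
    k : force normalisation factor (default 0.4, dimensionless)
    max_iterations : iteration budget (default 200)
    convergence_tol : stop when the best mean squared intensity difference
        seen has improved by less than this (relative) over the last
        ``convergence_window`` iterations
    convergence_window : plateau-detection window in iterations (default 25)
    """

    sigma: float = 1.0
    k: float = 0.4
    max_iterations: int = 200
    convergence_tol: float = 1e-4
    convergence_window: int = 25

    def __post_init__(self):
        if self.sigma <= 0:
            raise ParameterError("sigma must be positive")
        if self.k <= 0:
            raise ParameterError("k must be positive")
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")


@dataclass
class RegistrationResult:
    """Field plus per-iteration convergence log."""

    field: DisplacementField
    msd: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def iterations(self) -> int:
        return len(self.msd)


def demons_force(static: VolumeImage, warped_moving: VolumeImage, k: float = 0.4) -> np.ndarray:
    """Per-voxel displacement update (mm), shape ``(3, nz, ny, nx)``."""
    static.require_same_grid(warped_moving, "demons_force inputs")
    diff = static.values - warped_moving.values  # I - I'
    gs = gradient(static)
    gm = gradient(warped_moving)
    k2d2 = (k * k) * diff * diff
    out = np.zeros_like(gs)
    for g in (gs, gm):
        den = np.sum(g * g, axis=0) + k2d2
        ok = den >= DENOMINATOR_FLOOR
        w = np.where(ok, diff / np.where(ok, den, 1.0), 0.0)
        out += w * g
    return out


def regularize(field: DisplacementField, sigma: float) -> DisplacementField:
    """Componentwise Gaussian smoothing, sigma in voxels, truncated at 3 sigma.

    Boundaries are handled by nearest-edge replication so a constant field
    passes through unchanged.
    """
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    vec = np.empty_like(field.vectors)
    for c in range(3):
        vec[c] = ndimage.gaussian_filter(
            field.vectors[c], sigma=sigma, mode="nearest", truncate=3.0
        )
    return DisplacementField(vec, field.spacing.copy(), field.origin.copy())


def register(
    static: VolumeImage,
    moving: VolumeImage,
    params: RegistrationParams | None = None,
    initial_field: DisplacementField | None = None,
) -> RegistrationResult:
    """Iterate force computation, additive update and regularisation.

    Stops at ``max_iterations`` or when the mean squared intensity
    difference (MSD) between static and warped moving has decreased by
    less than ``convergence_tol`` (relative) over the last 5 iterations.
    """
    params = params or RegistrationParams()
    static.require_same_grid(moving, "register inputs")
    if initial_field is None:
        D = DisplacementField.zeros_like(static)
    else:
        if not initial_field.same_grid(static):
            raise ParameterError("initial_field grid must match the static image")
        D = initial_field.copy()

    msd_log: list[float] = []
    converged = False
    for n in range(params.max_iterations):
        warped = warp(moving, D, method="trilinear")
        msd = float(np.mean((warped.values - static.values) ** 2))
        msd_log.append(msd)
        # stop when the best MSD seen has improved by less than tol
        # (relative) over the last convergence_window iterations; comparing
        # running minima over a window long enough to span the plateaus
        # characteristic of Demons keeps transient stalls and MSD wiggles
        # from ending the run early
        w = params.convergence_window
        if len(msd_log) > w:
            ref = min(msd_log[:-w])
            best = min(msd_log)
            if ref <= 0 or (ref - best) / ref < params.convergence_tol:
                converged = True
                break
        u = demons_force(static, warped, params.k)
        vec = D.vectors + u
        if not np.all(np.isfinite(vec)):
            raise NumericalFailureError(
                f"non-finite displacement at iteration {n}", iteration=n
            )
        D = regularize(
            DisplacementField(vec, D.spacing.copy(), D.origin.copy()), params.sigma
        )
    return RegistrationResult(field=D, msd=msd_log, converged=converged)
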