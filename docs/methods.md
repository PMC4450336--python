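# Methods

## Model and assumptions

The pipeline targets the specific correspondence failure of adaptive
head-and-neck radiotherapy: between the planning CT (moving image) and a
posttreatment CT (static image), the irradiated primary tumor loses
cells, hence density and volume, so voxel intensities inside the tumor no
longer have counterparts across the pair. All other anatomy is assumed to
deform smoothly and to be registrable from intensity alone.

The intensity-modification procedure (IMP) rests on three assumptions:

* CT numbers are affine in linear attenuation, μ = I·μ_W/1000 + μ_W, so
  the offset *I* + 1000 is proportional to attenuation (air = 0). The
  value of μ_W (default 0.1928) cancels in the round trip, so its unit
  convention is irrelevant.
* Attenuation in a tumor voxel is proportional to the number of intact
  cells, and the surviving fraction after total dose *D* delivered in *n*
  fractions follows the linear-quadratic model
  SF = exp(−α·D·(1 + d/(α/β))), d = D/n. Cell proliferation over the
  treatment course is neglected. Each voxel is treated as an
  independently, homogeneously dosed subvolume, which is what an IMRT
  dose grid resampled to the CT lattice provides.
* Radiosensitivity parameters are highly uncertain per patient, so the
  absolute level of the modified intensities is not trusted: a scale
  step multiplies the tumor-region offsets so their sum matches the same
  region of the rigidly aligned posttreatment image. With a spatially
  uniform in-tumor dose the scale makes the result *exactly* independent
  of α and α/β (SF factors out of the ratio); with a realistic dose
  plateau over the target the residual sensitivity is negligible, which
  the sensitivity test confirms (measured DSC range 0.0 points across
  α ∈ [0.1, 1] Gy⁻¹ × α/β ∈ [3, 40] Gy).

Sums and the multiplicative scale operate on the offset scale
(*I* + 1000) rather than raw HU: raw HU sums can be negative or zero,
making a ratio ill-defined, while offsets are non-negative and
proportional to attenuation. The reference sum S₀ is taken over the
*LQ-modified* values, so the scale corrects exactly the discrepancy the
parameter uncertainty introduces. Inside `apply_imp` the modify→scale
composition is evaluated without leaving the offset domain: storing the
intermediate values as HU rounds offsets below ~1e−13 of 1000 to zero
(lethal doses reach SF ≈ 1e−51 at the sweep's extreme corner), which
would make S₀ degenerate even though the algebra is well-defined.

## Registration

**Rigid stage.** Both images are thresholded at 500 HU so only bone
drives the alignment (patients are immobilised in thermoplastic masks, so
translation-only is adequate). The objective is the Pearson correlation
coefficient of the thresholded intensities; the paper-trail wording
"minimized the correlation" is read as a typo for maximised. The search
is exhaustive on an integer-voxel grid over the whole ±20 mm radius
(evaluated for all offsets at once via an FFT cross-correlation surface of
the mean-subtracted images), followed by an exhaustive 1 mm-step Pearson
search in a ±3 mm cube around the coarse peak and per-axis parabolic
refinement. The fine-stage correlation is evaluated over the static bone
shell (bone mask dilated by two voxels), which contains the high-contrast
bone/soft-tissue edge carrying the sub-voxel information; support is
capped at 40 000 voxels by deterministic striding. Self-registration
returns an exact zero: the zero offset is always a candidate and
refinement is skipped when the peak correlation is already 1 to 1e−12.

**Deformable stage.** Single-resolution symmetric-force Demons. With the
backward-mapping convention used throughout (the warped moving image at
static position x samples the moving image at x + D(x)), Gauss–Newton
linearisation of the residual I′(x) − I(x) in an increment of D gives the
per-voxel update

    u = (I − I′) · [ ∇I / (|∇I|² + k²(I−I′)²) + ∇I′ / (|∇I′|² + k²(I−I′)²) ]

— the standard passive + active force pair with a shared normalisation.
The sign is fixed by the warp convention, and was verified numerically
(the opposite sign diverges on a known translation). Gradients are
central differences in HU/mm, so u is in millimetres and the per-term
step is bounded by 1/(2k) mm. Each iteration adds the update and smooths
the whole accumulated field with a Gaussian of σ = 1 voxel truncated at
3σ (nearest-edge boundary); there is no multiresolution pyramid and no
diffeomorphic composition. The moving gradient is recomputed on the
warped moving image every iteration. Denominators below 1e−9 zero their
term (flat regions with matched intensities must not blow up).

**Stopping rule.** The mean squared intensity difference (MSD) of this
scheme is *not* monotone per iteration — the smoothing step is not a
descent step and transient overshoot at strong edges occurs even on
noise-free inputs — and it shows long plateaus followed by renewed
progress. The run therefore stops when the best MSD seen has improved by
less than a relative 1e−4 over the last 25 iterations, or at the
200-iteration budget. Comparing running minima over a plateau-scale
window keeps transient stalls from ending the run early; the per-iteration
MSD log is returned for inspection.

**Units and geometry.** Arrays are (z, y, x); world coordinates are
DICOM patient (LPS) millimetres with the origin at the centre of voxel
(0, 0, 0); displacement fields are millimetres in the static frame
(voxels are anisotropic, so mm is the only unambiguous unit). Samples
outside an image's voxel-centre hull return −1000 HU (air), matching the
treatment of non-patient regions; there is no blending across the
boundary. Nearest-neighbour sampling breaks exact half-voxel ties by
rounding up. Contour rasterisation includes a voxel iff its centre is
inside the polygon under the even-odd rule, with multiple polygons on a
slice combined by XOR (holes and islands).

## The synthetic phantom

The generator emulates a head-and-neck study at the 2×2×3 mm working
resolution on a 96×96×40 grid: an ellipsoidal head with a ~7 mm skull
shell at 1200 HU, soft tissue at 40 HU, a 15 mm-radius spherical tumor at
60 HU, a couch slab at 300 HU outside the patient, and air elsewhere.
Two texture components make the interior registrable the way real tissue
is: band-limited heterogeneity (Gaussian-smoothed noise, ~8 mm
correlation length; std 15 HU in soft tissue and 80 HU in bone, the
latter reflecting trabecular density variation — without it the uniform
shell would leave tangential motion unobservable to any intensity-based
method) and white acquisition noise (std 10 HU) over the whole body.
Every generator is a pure function of its seed.

Ground-truth transformations: constant translations; full 2nd-order
polynomial displacement fields in normalised world coordinates, scaled to
a requested mean in-body magnitude (default 5.5 mm, i.e. above the 5 mm
level the validation experiment calls for); and tumor shrinkage. The
standard shrinkage study combines three changes the method must face
simultaneously: (a) a concentric tumor scaled to volume factor 0.67 whose
residual is markedly hypodense (15 HU — the necrotic/fluid-like
appearance of a regressing mass after a lethal dose, and the condition
that actually breaks local correspondence for plain Demons), with vacated
voxels repainted as soft tissue with fresh noise; (b) a smooth inward
pull of the surrounding tissue (2 mm at the tumor surface, Gaussian decay
over 10 mm), consistent with tissue filling the vacated space; and (c) a
smooth 2nd-order anatomic background deformation with 5 mm mean in-body
magnitude, tapered to zero away from the body so the couch stays put —
head-and-neck patients change posture and lose weight over a course, and
without background deformation the deformable stage has nothing to
recover outside the tumor. The truth contour is the shrunken mask carried
through the same background field. The planned dose is a 70 Gy plateau
over tumor + 8 mm with Gaussian falloff, generated on its own offset
4 mm grid.

What the phantom does **not** emulate: airways, vertebrae and other
discrete anatomy; beam-hardening and streak artifacts; independent noise
realisations outside the repainted tumor region (the posttreatment image
reuses the planning realisation through the deformations, so the tumor
region is the only site of broken correspondence); and biological
shrinkage dynamics (the concentric shrink is geometric, chosen because it
yields exact ground-truth masks). Passing tests therefore demonstrate
the mechanics of the method under controlled correspondence failure, not
clinical-grade accuracy on patient data.

## Problem sizes and runtimes

All experiments run on the 96×96×40 phantom. The deformation-recovery
validation uses one polynomial field and a 200-iteration Demons budget
(~20 s); the rigid validation uses 20 random translations (~20 s); the
with/without-IMP comparison uses a 5-seed suite (two full pipeline runs
per seed, ~8 min total); the sensitivity sweep uses a 3×3 parameter grid
on one study. These sizes keep the full suite at desk scale while leaving
every stage's work non-trivial.

## Known limitations

* At volume factor 0.67 the planning tumor boundary moves only ~1.9 mm —
  under one voxel at the working resolution — so the rigid, plain-Demons
  and IMP tumor DSC values are compressed into a band of roughly ten
  points. The *direction* of the IMP effect (better than plain Demons) is
  robust on every seed, but its magnitude on this phantom (≈ 0.4–5 points)
  is smaller than what patient-scale anatomic change produces.
* Strict per-iteration MSD descent cannot be guaranteed (see Stopping
  rule); convergence monitoring should use the running minimum.
* The Demons variant is non-diffeomorphic; strong shrinkage implies
  locally non-invertible correspondence by construction, and no attempt
  is made to regularise the Jacobian.
* Rotations are excluded from the rigid stage by design (masked,
  immobilised patients); oblique slice geometries are not supported.
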