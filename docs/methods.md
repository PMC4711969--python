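# Methods

## The model

Diffusion tensor imaging (DTI) summarizes water displacement per voxel as a
symmetric positive semi-definite 3×3 tensor **D** (mm²/s) with sorted
eigenvalues λ₁ ≥ λ₂ ≥ λ₃ and eigenvectors e₁, e₂, e₃.  This package implements
a toroid-based alternative to the classical ellipsoid representation, in two
parts: a *supertoroidal glyph* for visualization and two *toroidal scalar
invariants* for quantitative maps.

### Supertoroidal glyph

With the Westin barycentric shape metrics

    CL = (λ₁−λ₂)/Σλ,  CP = 2(λ₂−λ₃)/Σλ,  CS = 3λ₃/Σλ,  CL+CP+CS = 1,

the glyph surface over θ, φ ∈ [0, 2π] is

    CS ≥ CP:  ( cos^η₁θ · [(CL+CP) + CS·cos^η₂φ],
                sin^η₁θ · [(CL+CP) + CS·cos^η₂φ],
                sin^η₂φ )

with the ring and tube amplitudes swapped when CS < CP, where
η₁ = (1−CP)^γ₁, η₂ = (1−CP)^γ₂ and cosᵉ/sinᵉ are sign-preserving superquadric
powers sign(x)·|x|ᵉ (plain fractional powers of negative numbers are
undefined; the signed form yields the symmetric closed shapes).  Defaults
γ₁ = 4 (edge sharpness across the medium/minor directions) and γ₂ = 0.5
(shape along the rotational axis).  The central opening marks e₁ regardless
of viewing angle; in the isotropic corner (CL, CP, CS) = (0, 0, 1) the ring
amplitude vanishes and the glyph closes into a genus-0 blob with no hole.

Numerical choices:

- η exponents are floored at 0.05 so the surface never becomes numerically
  flat as CP → 1.
- When the ring amplitude is ~0 the full polar range would trace the blob
  twice (the revolution profile crosses the axis); the sampler then restricts
  φ to [−π/2, π/2], a single cover with welded poles.  This is what makes the
  "no hole" case a well-formed closed mesh (Euler characteristic 2).
- The η exponent expression is read as exponentiation, (1−CP)^γ; a product
  reading (1−CP)·γ would break the smooth-transition behavior at CP → 0
  (η₁ would jump to 4 instead of 1).
- The two amplitude branches coincide on the CS = CP locus only where CL = 0
  (there both amplitudes are ½).  For CL > 0 the printed parameterization is
  genuinely discontinuous across the branch switch; the continuity test
  therefore probes the CL = 0 edge, and glyph fields near the switch should
  be interpreted with that caveat.
- Degenerate (zero-area) surfaces yield placeholder meshes flagged
  `degenerate` rather than raising, so whole-slice export never aborts.

### Toroidal surface and invariants

Display-parameter-free quantities come from the plain toroidal surface

    T(θ,φ) = (cosθ(α+βcosφ), sinθ(α+βcosφ), γ·sinφ),
    α = (2λ₂+λ₃)/4,  β = λ₃/4,  γ = λ₁/2,

so λ₁ is the z-extent, λ₂ the central-opening diameter, λ₃/2 the tube
thickness.  From it:

- **TV (toroidal volume)** = (λ₁π/3)(λ₂λ₃ + λ₃²/2), units mm⁶/s³.  A
  diffusivity index, nonlinear in the eigenvalues (zero second differences
  for MD along affine eigenvalue paths, nonzero for TV).  Note the analytic
  enclosed volume of T is 2π²αβγ = (π²/8)·λ₁(λ₂λ₃+λ₃²/2), i.e. TV differs
  from the geometric volume by the constant factor 3π/8.  TV is implemented
  with the π/3 prefactor as defined; the constant has no effect on contrasts,
  normalized maps, or rank statistics.  A mesh-quadrature test records the
  ratio.
- **TC (toroidal curvature)** = max over φ ∈ [0, π] of the Gaussian curvature
  K(φ) of the λ₁-normalized surface (α′ = α/λ₁, β′ = β/λ₁, γ′ = ½):

      K(φ) = 4β′γ′²cosφ / ((α′+β′cosφ)·[β′²+γ′² + (γ′²−β′²)cos2φ]²).

  Since β′²+γ′²+(γ′²−β′²)cos2φ = 2(β′²sin²φ + γ′²cos²φ), this closed form is
  exactly the surface-of-revolution Gaussian curvature; the test suite
  verifies it against numerical first/second fundamental forms and against
  the classical circular-torus limit cosφ/(β(α+βcosφ)) at β′ = γ′.  TC is an
  anisotropy index: it grows strictly from the ordinary torus (isotropy)
  toward the tube (anisotropy) and is unbounded as λ₃/λ₁ → 0 with λ₂ > 0,
  whereas FA saturates at 1.  TC is dimensionless — it is computed on the
  λ₁-normalized surface, not in physical mm⁻²·s² units.

  The argmax has no closed form (for γ′ > β′ the bracket grows with cos²φ and
  pushes the maximum off φ = 0 — e.g. the isotropic triple peaks at an
  interior angle with TC ≈ 3.61 versus K(0) = 1), so the maximizer is found
  on a dense 2048-point grid followed by bounded scalar refinement.  For
  whole-volume maps with many distinct eigen-triples the refinement is a
  vectorized golden-section search inside the two bracketing grid cells;
  this matters because profiles with very small β′ peak in a window narrower
  than the grid spacing (near cosφ* ≈ β′/(√3γ′)), where a one-step quadratic
  fit fails.  The two paths agree to ~1e-8 relative.
  λ₁ = 0 (and β′ = 0, where K ≡ 0) map to TC = 0.

### Tensor estimation

Signals follow the monoexponential Stejskal–Tanner model
S_i = S₀·exp(−b_i·gᵢᵀDgᵢ).  The estimator is ordinary log-linear least
squares on ln(S_i/S₀) with S₀ = mean of the b = 0 volumes — the standard
baseline; one-pass signal-weighted LLS is available via `weighted=True`.
Non-positive signals are clipped to 10⁻⁶·S₀ before the log (counted and
logged); all-zero voxels are masked out.  Designs with fewer than six
independent directions raise.  After eigendecomposition, negative
noise-driven eigenvalues are clamped to 0 (the invariants assume λ ≥ 0) and
eigenvector signs are fixed by making the largest-magnitude component
positive, for reproducible orientation colors.  Eigenvalue-configuration
classes (orthotropic λ₁>λ₂>λ₃, prolate λ₁>λ₂=λ₃, oblate λ₁=λ₂>λ₃, isotropic)
declare equality at (λᵢ−λⱼ)/λ₁ ≤ 0.05 by default — a relative threshold so
labels are invariant to uniform scaling; no published threshold exists, and
maps of the classes should be read with the tolerance in mind.

### Color encodings

Orientation: RGB = (|e₁x|, |e₁y|, |e₁z|), optionally FA-weighted.  Normalized
TV: hot-to-cold (blue→cyan→green→yellow→red) piecewise-linear ramp.
Configuration classes: purple (0.5,0,0.5), orange (1,0.55,0), green (0,0.6,0),
gray (0.5,0.5,0.5) with the brightness scaled by normalized TV between a 0.2
floor and 1 (the floor keeps zero-TV voxels visible).  The class colors
follow published naming; exact RGB values are this package's choice.

## Synthetic phantom

`synthetic_phantom` builds the regional structure a glioblastoma ROI analysis
assumes: an ellipsoidal brain mask containing a spherical isotropic
high-diffusivity "necrotic core", a surrounding edema shell, two anisotropic
white-matter bundles (one straight, one 90° arc, so orientation coding and
glyph alignment are exercised), and near-isotropic gray matter elsewhere.
Default grid 48×48×12 voxels at 2.5×2.5×3.3 mm (one ROI ≈ a few thousand mm³,
the scale of equal-volume ROI sampling in regional DTI studies; the grid is
sized so a full 18-subject noisy pipeline runs in tens of seconds).  Default
eigenvalue triples (mm²/s) are literature-typical brain values chosen once to
produce the qualitative orderings regional GBM DTI reports — MD/TV:
tumor > edema > parenchyma; FA/TC: WM > GM:

| region | λ₁, λ₂, λ₃ (×10⁻³) |
|--------|--------------------|
| tumor  | 1.8, 1.7, 1.6 |
| edema  | 1.3, 1.1, 1.0 |
| GM     | 0.9, 0.8, 0.75 |
| WM     | 1.7, 0.4, 0.3 |

Isotropic-ish regions get per-voxel random orientations; WM tensors align e₁
with the local tract direction.  DWI synthesis uses 32 electrostatically
spread directions at b = 800 s/mm² plus one b = 0 volume, with Rician noise
sqrt((S+n₁)²+n₂²), n ~ N(0, (σS₀)²), default σ = 0.02 (Gaussian noise is
available for debugging).  Cohorts apply per-subject, per-region lognormal
eigenvalue jitter: one shared scale factor (sd = jitter_sd, default 0.05) and
three independent shape factors (sd = jitter_sd/2), so the cross-subject CV of
region-mean MD tracks the nominal jitter.  Subject s draws with seed
`master + 1000·(s+1)` while geometry keeps the spec seed, so zero jitter
reproduces identical subjects and everything is bit-reproducible from one
master seed.

What the phantom does **not** emulate: partial-volume mixing at region
borders, spatially varying noise, susceptibility/eddy distortions, crossing
fibers, and realistic anatomy.  Passing the cohort tests therefore shows the
pipeline recovers *designed* regional effects through a noisy
acquisition-and-fit cycle — not that the invariants separate real tumor
tissue.

## ROI statistics

Per subject and invariant, the mean over each ROI's unmasked voxels (fixed
region order tumor, edema, GM, WM).  Omnibus: Friedman rank test across the
four regions (mid-ranks, tie-corrected χ² with k−1 df; via
`scipy.stats.friedmanchisquare`), with an exact-permutation p (all k!ⁿ
within-subject orderings) available for n ≤ 8 as a reference for the χ²
approximation.  Post-hoc, gated on the omnibus rejecting at α = 0.05:
two-sided exact sign tests on all six region pairs, dropping zero differences
(the standard exact convention; with continuous phantom means ties are
measure-zero anyway).  No multiplicity correction by default — matching the
common report-per-pair-at-α practice this design mirrors — with a Bonferroni
option off by default.

## Degenerate-input conventions

- Zero-trace tensor: (CL, CP, CS) := (0, 0, 1), FA := 0, TV = TC = 0 (limit
  conventions, with warnings), never NaN.
- λ₁ = 0: configuration ISOTROPIC; normalized toroid parameters undefined,
  voxel flagged degenerate.
- Constant maps normalize to all-zeros (avoids 0/0 and keeps background dark).
- Non-finite tensor voxels are masked and counted, never propagated.

## File conventions

NIfTI throughout (voxel→world RAS affine; eigenvectors and orientation colors
live in the world frame).  Tensor volumes store six components in
lower-triangular order (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz), recorded in the header
description because the ecosystem has competing conventions; in memory the
order is row-major upper-triangle.  Gradient tables are FSL-dialect text
(.bval one row, .bvec three rows).  Meshes export as binary little-endian PLY
with per-vertex uchar RGB, or OBJ with a CSV color sidecar.  All writers are
deterministic (no timestamps), so identical inputs give byte-identical files.

## Known limitations

- The tensor fit is LLS by default; no claim is made that it matches any
  particular study's (unnamed) fitter.  No motion/eddy/EPI correction is
  performed — inputs are assumed corrected.
- Single-shell Gaussian tensor model only; no multi-compartment models.
- TC of an exactly degenerate λ₃ = 0, λ₂ > 0 triple is 0 (the curvature
  profile vanishes with β′), although TC → ∞ as λ₃ → 0⁺: the map is
  discontinuous at that measure-zero boundary.
- The supertoroid branch discontinuity at CS = CP with CL > 0, inherited from
  the parameterization, is documented above.
- Glyph export is per-slice; no interactive rendering.
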