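# Methods

## Scope and model

`usvolren` renders a 3D ultrasound intensity volume as a participating
medium — a density field that absorbs and scatters light — rather than as a
shaded isosurface. Per-pixel radiance along a ray from the eye through the
volume is

    L(x_s, w0) = L0 * T(x0, x_s)
               + ∫ lambda_s(x') L_ss(x', w0) T(x', x_s) dx'   (direct)
               + ∫ lambda_s(x') L_ms(x', w0) T(x', x_s) dx'   (indirect)

with `T(a, b) = exp(-∫ tau_t)` the Beer-Lambert transmittance, `tau_t`
the extinction coefficient, and `lambda_s = a * tau_t` the scattering
coefficient given albedo `a`. Emission is neglected: ultrasound tissue does
not glow. The split into a single-scattering term (light scattered exactly
once between source and eye) and a multiple-scattering term is exact and
the two HDR passes are therefore strictly additive — a property the test
suite checks pixel-exactly.

All integrals are discretized by midpoint-rule Riemann sums. Both render
passes place exactly `samples_per_ray` samples on the in-box segment of
each ray; transmittance marches use a fixed step in mm and integrate only
the portion of the segment inside the volume's bounding box (outside is
vacuum by convention, so the clipping is exact).

### Optical classification

A piecewise-linear transfer function maps normalized intensity to
`(color, tau_t, albedo)`. Parameterizing by extinction and albedo rather
than by independent absorption/scattering coefficients guarantees
`lambda_a + lambda_s = tau_t` exactly at every lookup. Intensity at an
arbitrary world point is trilinear interpolation of the 8 surrounding
voxels; voxel `(i,j,k)` is centered at `origin + (i sx, j sy, k sz)`, the
bounding box extends half a voxel beyond the outer centers, and sampling
inside that half-voxel shell clamps to the edge.

### Phase function

Scattering anisotropy uses the Henyey–Greenstein density

    p(cos t) = (1/4pi) (1 - g^2) / (1 + g^2 - 2 g cos t)^{3/2}

in its normalized form (the exponent 3/2 and the 1/4pi factor are required
for the density to integrate to 1 over the sphere; the tests verify this by
Gauss–Legendre quadrature, and verify by Monte Carlo that the sampled mean
cosine equals `g`). Directions are drawn by the standard inverse-CDF
formula for `cos(theta)` with uniform azimuth.

## Direct pass

In single-scatter geometry both directions at a sample are fixed — the
incident direction points from the light, the outgoing direction to the
eye — so nothing needs to be sampled: the pass evaluates the phase function
at the exact eye–light angle and is fully deterministic and noise-free. Per
sample the contribution is

    T_eye(mid) * lambda_s * p(w_i . w_0) * color * P_light * T(x_l, x') * ds

where `T(x_l, x')` is a midpoint-rule shadow march from the light and
`T_eye(mid)` is the eye transmittance taken at the sample midpoint
(`T * exp(-tau ds / 2)`). The background radiance enters attenuated by the
full-ray transmittance. Shadow marches are skipped once the accumulated eye
transmittance falls below `min_transmittance` (default 0.005); the cheap
extinction accumulation continues so the background term stays exact.

## Photon pass (indirect illumination volume)

Photons are emitted sequentially, photon `i` consuming RNG substream `i` of
the master seed (splitmix64 streams), which makes the flux grid bit-stable
for a given scene and seed and independent of any threading. Each photon
starts at the light with flux equal to the per-photon exposure and a
direction drawn uniformly over the solid angle the volume's bounding box
subtends from the light (cone rejection sampling against the bounding
sphere; a light inside the box emits isotropically).

Free paths use per-segment exact exponential inversion: marching in steps
of `photon_step`, the segment's midpoint extinction `tau` gives interaction
probability `p = 1 - exp(-tau * seg)`, and conditional on the uniform draw
`u < p` the interaction distance within the segment is `-log(1-u)/tau`.
For piecewise-constant media this composes to exact exponential free-path
sampling — in a homogeneous `tau = 0.5/mm` medium the measured mean free
path is `1/tau = 2 mm` to within Monte-Carlo error, which the acceptance
suite checks against the box-truncated closed form.

At an interaction, Russian roulette with survival probability equal to the
local albedo decides scatter versus absorption. On scatter the photon's
*undiminished* launch flux is splatted trilinearly over the 8 surrounding
voxels of the flux grid (weights summing to exactly 1) and a new direction
is drawn from the phase function; on absorption the photon dies. The
roulette carries attenuation stochastically, so no per-bounce
down-weighting is applied — every deposit equals the launch flux exactly,
total deposited flux is exactly linear in exposure, and
`n_absorbed + n_escaped = n_emitted` holds exactly. A hard bounce cap
(default 32) guarantees termination and counts as absorption.

## Indirect pass and screen-space density estimation

The flux grid stores flux only, not incident directions, so the pass
collects isotropically:

    sigma_s * L_ms(x') = Phi_local(x') / (4 pi * V_voxel)

with `Phi_local` the trilinear interpolation of the flux grid and
`V_voxel = sx sy sz`. The eye ray accumulates this with the same
front-to-back transmittance weights as the direct pass. The density
estimation is then completed in 2D image space: one separable Gaussian blur
(default 3×3 taps, sigma 1 px, clamp-to-edge) applied once to the indirect
screen image. The two 1-D passes are algebraically identical to the full
2-D convolution at (n+m)/(n·m) of the multiplies.

Two validation routes exist for this estimator. The conventional
spherical-kernel estimate

    L_ms ~= sum_i p(w_i . w_0) Phi_i / ((4/3) pi r^3)

over the n nearest photon records (r = distance to the n-th) is implemented
independently in numpy/scipy (`knn_radiance`, `render_indirect_reference`,
brute-force-checked KD-tree neighbors); on a smooth photon field the
screen-space image and the KNN image are two discretizations of the same
density and correlate with Pearson r > 0.99 in practice (the acceptance
suite requires > 0.9). A uniform flux grid in a transparent medium gives a
pixel value exactly proportional to the ray's chord length through the box,
which is checked against the analytic line–box intersection.

## Local baseline and tone mapping

The comparison baseline is classical gradient-shaded emission–absorption
compositing: normal `-grad(I)/|grad(I)|` by central differences,
Blinn–Phong shading (ambient 0.2, diffuse 0.7, specular 0.2, shininess 32),
ambient-only where the gradient magnitude is below `grad_eps` (1e-4), and
early ray termination at accumulated opacity 0.995.

HDR radiance is mapped to the display range by Reinhard's global operator
on luminance, `L_d = key L / (1 + key L)`, with chrominance preserved by
uniform channel scaling. It is the same strictly monotone curve at every
pixel, maps into [0, 1), and `key L = 1` lands exactly on 0.5. The default
key 0.4 matches the default per-photon exposure scale.

## Synthetic phantoms

No clinical volumes ship with the package, so the test bed is a seedable
phantom generator: nested, arbitrarily oriented ellipsoids of distinct mean
intensity ("tissue") over a low-intensity background ("fluid"), softened by
a small Gaussian kernel (sigma 1 voxel) so the local-illumination baseline
has usable gradients, then corrupted by multiplicative Rayleigh speckle —
the standard first-order model of fully developed ultrasound speckle:
`out = clamp(vol * R / E[R], 0, 1)` with `R ~ Rayleigh(sigma)` and
`E[R] = sigma sqrt(pi/2)`, mean-preserving before the clamp (at mid-range
intensities the clamp bias is ~1%, and the test oracle accounts for it by
quadrature). The stock `fetal_phantom` places a tilted trunk, a head with a
darker interior, and a limb bud in fluid, with speckle sigma 0.15.

What the phantom does *not* emulate: ultrasound beam physics — point-spread
anisotropy, attenuation and shadowing artifacts, refraction, and the
cone/fan acquisition geometry. Passing tests therefore demonstrate correct
light transport and estimator behavior on ultrasound-like density and noise
structure, not clinical image quality.

## Preprocessing

Despeckling is 3D Perona–Malik anisotropic diffusion with exponential
conductance `exp(-(d/kappa)^2)`, explicit 6-neighbor updates and
replicated (zero-flux) boundaries. Defaults: 20 iterations, `dt = 0.15`
(inside the strict 1/6 stability bound, so the scheme is a convex
combination and obeys the discrete extremum principle; the accepted input
range for `dt` is (0, 0.25]), `kappa = 0.1` in normalized intensity units —
comfortably above speckle-scale differences after smoothing and below the
~0.5 tissue/fluid contrast. Zero iterations is the identity.

## Numerical and design choices

- Canonical volume I/O is uncompressed MetaImage (.mhd/.raw) via SimpleITK,
  float32 payload; NIfTI is read-only. Min–max normalization maps a
  constant volume to all zeros (avoids 0/0 on degenerate inputs).
- HDR images are written as PFM (a three-line header plus raw little-endian
  float32 scanlines; the codec is small enough to live in `volume_io` and
  round-trips bit-exactly).
- Default marching steps: eye pass `diag/samples_per_ray`, shadow
  `diag/128`, photon `diag/256`, with `diag` the box diagonal. These set
  the bias floor of the midpoint rules; the Beer–Lambert tests run at
  0.01 mm where the closed form must be met to 1e-4.
- Deposits exactly on the box boundary clamp into the outermost cell;
  deposit positions outside the box are a counted no-op rather than an
  error, since they can only arise from caller-constructed positions.
- The sequential photon counter replaces any work-sharing scheme a GPU
  implementation would use; scheduling is a performance detail with no
  bearing on the computed flux, and the sequential loop makes results
  thread-count independent by construction.

## Problem sizes

Unit tests run on 16³–48³ volumes with 32²–48² images. The acceptance
checks use 64³ phantoms, 10⁵ photons and 128×128 images at 800 samples per
ray — small enough to run on one CPU core in minutes while keeping every
statistical tolerance at its stated value.

## Known limitations

- The indirect pass is achromatic with respect to the medium (isotropic
  collection of stored flux; the transfer-function color modulates only the
  direct pass). Colored lights propagate, colored media do not tint
  multiple scattering.
- Stored flux discards incident directions, so anisotropic collection
  (evaluating the phase function at gather time) is only available through
  the KNN reference path, not the fast screen-space path.
- The screen-space blur is applied once per frame, so its effective world-
  space footprint varies with depth along the ray.
- Regular-step interaction sampling is exact only for media that are
  piecewise constant at the `photon_step` scale; smooth gradients incur
  O(step²) bias.
- No GPU path and no interactive viewer; the package is a reference
  implementation meant for correctness, not frame rates.
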