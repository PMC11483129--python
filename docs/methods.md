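# Methods

This note documents the models, numerics, and design choices behind
ufiberlab, and what the synthetic experiments do and do not demonstrate.

## Phantom geometry

The phantom is a pair of concentric boundaries: an outer "gray/white"
sphere of radius b = 20 mm (optionally perturbed radially by a smooth
angular function scaled by a gyrification amplitude) and an inner
"ventricle" sphere of radius a = 10 mm, rasterized on an isotropic voxel
grid (default 1 mm) with the voxel-center convention.  The boundary mesh
is a recursively subdivided icosahedron (10·4^k + 2 vertices at order k;
two order-5 hemispheres give the 20,484-vertex convention of standard
surface templates).  ROI labels partition the surface into 12 spherical
Voronoi sectors seeded at icosahedron directions.

The unperturbed sphere is deliberately simple: the Laplace problem has
the closed form φ(r) = (1/r − 1/b)/(1/a − 1/b), streamlines are radial
lines, and the depth-d sample sits at radius b − d, so every geometric
stage has an exact oracle.  The phantom stores signed-distance volumes
for both boundaries (radial distances; exact for spheres, a first-order
approximation under gyrification).

## Laplace potential and laminar streamlines

The potential is relaxed by red-black successive over-relaxation
(ω = 1.9, tolerance 1e-6 on the max update, max 10,000 sweeps) on a
7-point stencil.  Where the signed-distance volumes are available,
boundary crossings use the Shortley–Weller one-sided stencil with the
interface located by quadratic interpolation of the signed distance
along the link; this places the Dirichlet condition at its sub-voxel
position and reduces the closed-form error at 1 mm voxels from ~0.14
(staircase placement) to ~8e-4.  Voxel centers exactly on an interface
belong to the Dirichlet set.  Non-mask neighbors with no interface
crossing are treated as insulating (mirror condition), so masking
artifacts do not act as spurious zero-potential sinks; components
touching neither boundary are filled from the nearest boundary value
with a warning.

Streamlines are seeded at every surface vertex and integrated with
fixed-step Euler (0.1 mm, truncated at 5 mm) along the trilinearly
interpolated, renormalized gradient.  Within one voxel of the outer
boundary the direction is blended with the boundary's inward normal
(from the signed distance): the discrete gradient is corrupted by the
staircase representation exactly there, while the equipotential
parallels the boundary by construction.  With the blend, 100% of first
segments are within 0.4° of the vertex normal on the sphere phantom;
without it, staircase noise reaches ~11°.  Streamlines stop on entering
the ventricles, on leaving the mask, when the gradient vanishes
(< 1e-8, with one 0.05 mm inward nudge retried at the seed), or at the
5 mm cap.  Depth samples are linear interpolations of the polyline at
arc lengths 0–2 mm; depths beyond a truncated streamline are missing,
not errors.

## Fixels and the AFD decomposition

FODs are real even-degree spherical harmonics up to lmax 8 (45
coefficients).  A fixel is rendered as an axially symmetric lobe whose
spherical integral equals its AFD.  The lobe kernel is the square of the
degree-lmax/2 truncation of exp(κ(t² − 1)) (κ = 12 by default): squaring
makes the kernel exactly band-limited at lmax and provably non-negative,
avoiding the truncation ringing a hard-truncated Gaussian-on-sphere lobe
exhibits at lmax 8.

Segmentation renders the FOD on an order-4 icosphere tessellation (2562
directions, vertex quadrature weights from incident face areas) and
assigns every direction to its uphill local maximum (discrete
watershed).  Function values are quantized at 1e-6 of the maximum so
numerical jitter cannot shatter plateaus (an isotropic FOD is one
plateau and yields a single fixel); plateau peaks connected at peak
height are merged; antipodal peak pairs form one axial fixel; basins of
peaks below 0.1 × max are reassigned to the nearest retained axis.  By
construction the fixel AFDs sum to the quadrature integral of the FOD
exactly (the quadrature total itself differs from the analytic SH
integral by ~1e-5 relative, the resolution of the vertex weights).
Round-trip accuracy: a single fixel is recovered to < 0.001% in AFD and
< 3° in direction; two orthogonal fixels at lmax 8 are recovered within
~3% (lobe overlap bounds this).

Classification against the local streamline tangent (central difference
of the bracketing polyline points) takes the single fixel with the
smallest axial angle as the parallel population, counted only below a
45° cutoff; tan = total − par holds identically.  Depth samples use the
containing voxel's fixel list (no interpolation across voxels — fixel
sets do not interpolate meaningfully).  The cohort sampler precomputes
the geometric plan (voxel index and tangent per vertex × depth) once and
classifies each subject vectorized; it is exactly equal to the
per-subject reference path (asserted in tests).

Surface smoothing is iterated self+neighbor averaging; the iteration
count is 2(FWHM/2.3548)²/m where m is the mean per-step added variance
estimated from the mesh edge lengths.  The impulse response's geodesic
FWHM is within 15% of the request on a regular sphere mesh.  Missing
vertices are excluded from averages and stay missing; constant fields
are preserved exactly.  The pipeline default FWHM is 3 mm — the 15 mm
kernel used on human cortex scaled to the 20 mm phantom (a 15 mm kernel
would span ~43° of the phantom and erase the planted ROI).

## Tapping simulator and metrics

Synchronization epoch: asynchronies follow the linear phase-correction
process A[n+1] = (1 − α)A[n] + T[n] + M[n+1] − M[n] (α = 0.9 default,
timekeeper SD 10 ms, motor SD 5 ms), started from the stationary
distribution and offset so the mean asynchrony is negative with
magnitude `asynchrony_scale` (default 40 ms; taps anticipate the
metronome).  The visual modality multiplies offset and noise by 1.5,
reproducing larger and more variable visual asynchronies.

Continuation epoch: the two-level timekeeper/motor model
I[n] = C[n] + M[n+1] − M[n] with C ~ N(μ_c, σ_T²).  Its lag-1
autocorrelation has the closed form −σ_M²/(σ_T² + 2σ_M²) ∈ [−0.5, 0]
(−0.5 at σ_T = 0, −1/3 at σ_T = σ_M), used as a Monte-Carlo oracle.  The
timekeeper mean regresses toward the indifference interval,
μ_c = target + w(654 − target) with w = 0.15, so short targets are
overestimated, long ones underestimated, and the constant-error line
crosses zero at 654 ms (the auditory indifference interval; recovered to
±2 ms from 60 trials per target).

Trial validity follows the task's correct-trial rule: every produced
interval within 30% of the target during synchronization and 40% during
continuation; summaries use trials valid in both epochs and keep the
discarded count.  Metric conventions: sample SD (n − 1); per-trial lag-1
with trial-mean subtraction, averaged across trials without Fisher-z;
taps paired to the nearest stimulus within half a target interval, ties
to the earlier stimulus (verified against optimal assignment on jittered
streams).

## Cohort construction and planted truth

Subject pairs (tan_amplitude, asynchrony_scale) are affine images of a
standardized pair constructed by Gram–Schmidt so the empirical
correlation equals ρ exactly (amplitude 1.5 ± 0.35, asynchrony
40 ± 10 ms; rare floor-clipping at 5 ms can perturb the correlation
within the ±0.05 contract).  The amplitude scales the tangential profile
(Gaussian in depth, peak 0.5 at 1.5 mm, SD 1.0 mm — a U-fiber band
spanning roughly 0.5–2.5 mm; the radial profile is a constant 0.5)
inside one ROI's radial sector.  Two deliberate calibration choices make
the construction satisfy its own contract:

* per-fixel AFD noise (SD 0.02) gives every vertex independent
  across-subject variance — required for type-I calibration of the
  vertex-wise test — while attenuating the planted correlation by < 2%;
* the planted voxel sector extends 3° beyond the ROI's Voronoi cell, so
  every ROI-labeled vertex samples planted voxels despite half-voxel
  quantization at the sector boundary.

The behavioral link is planted at the auditory 650 and 750 ms targets
(the asynchrony scale there is the correlated subject variable); other
targets and the visual modality get independent subject effects, so a
multivariate analysis should flag exactly those two variables.

## Statistics

Vertex-wise inference is the Pearson correlation with t = r√(df/(1−r²)),
df = n − 2, two-tailed; `critical_r` inverts this by bisection (0.355 at
df = 29, α = 0.05).  Cluster correction permutes the behavior vector,
recomputes the full r map (vectorized as a single matrix product of
standardized data), thresholds at the cluster-forming p < 0.001, and
compares observed edge-connected cluster extents with the null maximum
extent: p_cluster = (1 + #{null ≥ obs})/(1 + n_perm).  Permutation
inference replaces parametric random-field theory deliberately: it is
exact under subject exchangeability and its calibration is itself
testable (family-wise rate ≤ α over 200 null cohorts).  One consequence
of the phantom's construction is that the planted block is almost
perfectly inter-vertex correlated, so the null max extent is bimodal and
the true cluster p sits near 2–5 × 10⁻⁴; recovery runs therefore use
10,000 permutations (pipeline default 5,000) so the estimate resolves
below α = 0.001 reliably.

rCCA regularizes both block covariances with ridge terms and models the
first canonical pair only.  With many more vertices than subjects the
in-sample canonical correlation is identically 1 at λ_y = 0, so the
regularizers are chosen by cross-validated out-of-fold variate
correlation; the reported CV correlation of the winner is re-estimated
on a fresh fold split to remove the maximum-selection bias (under pure
noise it is centered near 0).  The λ⁻¹ᐟ² action on the wide block uses
the thin SVD of the data, never forming a vertices × vertices matrix.
Sign convention: the behavioral weight of largest magnitude is positive
and corr(U, V) ≥ 0; under this convention the planted negative
anatomo-behavioral association appears as negative vertex-side loadings
(asynchrony-side loadings positive).  Permutation CIs shuffle rows of Y,
refit at fixed λ, and take the central 99% of each variable's null
loadings; under independence the flag rate is ≈ 1%.

## Problem sizes and determinism

Default experiments use the order-3 sphere phantom (642 vertices, 45³
voxels); calibration and recovery cohorts use n = 200 subjects, 200 null
replicates at 199 permutations for family-wise calibration, and 10
replicate cohorts (order-2 mesh, 162 vertices) for the rCCA driver
recovery.  All randomness flows from explicit seeds; the pipeline writes
a manifest of SHA-256 output hashes, NIfTI volumes are uncompressed
(gzip embeds timestamps), and re-running a config reproduces
bitwise-identical files.

## Limitations

The phantom has no realistic cortical folding, no partial-volume or
Rician noise model, and no raw diffusion signal simulation; FODs are
synthesized from planted fixels, not estimated by spherical
deconvolution.  The planted ROI amplitude is a single subject-level
scalar, which makes within-ROI vertices nearly perfectly correlated —
stronger spatial coherence than real anatomy — and is the reason the
cluster-extent null is bimodal here.  Passing recovery tests therefore
demonstrates correctness of the geometry, decomposition, and inference
machinery under the stated generative model, not robustness to the
artifacts of measured diffusion MRI.  The behavioral simulator
reproduces the classical phenomena (negative mean asynchrony, negative
lag-1, visual > auditory asynchronies, central-tendency bias) but not,
e.g., drift, lapses, or outlier taps beyond the validity filter.
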