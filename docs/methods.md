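# Methods

This note documents the models, numerical choices, and defaults behind
`morphoframe`, and what the synthetic benchmark does and does not show.

## Trajectory model

The cell's position at time t is the unweighted arithmetic mean of its
mesh vertices (`mesh_io.mass_center`) — deliberately *not* the
area-weighted or volumetric centroid, so the trajectory definition does
not depend on meshing density assumptions. A config path
(`volumetric_centroid`) exposes the solid centroid for users who prefer
it.

Each coordinate sequence is modeled as s(t) = f(t) + ε with f ~ GP(0, k)
and ε ~ N(0, σ²) i.i.d. The kernel is squared-exponential with length
scale ℓ = e¹ ≈ 2.72 and variance v = 1. Sequences are standardized to
mean 0 / sd 1 (population sd, n in the denominator) before fitting and
destandardized afterwards; a zero-variance axis bypasses the GP and is
carried through as a constant.

**Kernel time axis.** ℓ ≈ 2.7 is only meaningful relative to the sample
spacing. The kernel therefore measures distance on the *observation
index* axis (observations numbered 1..n) by default, so ℓ = e spans about
three observations whatever the acquisition stride; `GPConfig(time_scale
= "raw")` switches to the raw time stamps. On the default synthetic cell
(26 observations of 250 frames) the index scale reconstructs the
trajectory to a mean squared error orders of magnitude below the path
scale, while the raw scale decorrelates adjacent observations entirely.

**Noise variance.** σ² is not a stated constant; by default it is
estimated by maximizing the marginal likelihood with (ℓ, v) fixed
(`WhiteKernel` bounds 1e−10..1e2, two seeded optimizer restarts), and can
be pinned with `GPConfig(noise_variance=...)`. All randomness in the
restart initialization is seeded, so smoothing is deterministic.

**Interpolation.** The dense grid inserts `interpolation_factor − 1 = 9`
equally spaced points per observation interval by default — enough that
finite differences on the dense grid are an accurate substitute for
analytic GP derivatives, which we do not use. Speed |r′|, curvature
κ = |r′×r″|/|r′|³, and torsion τ = (r′×r″)·r‴/|r′×r″|² come from central
differences (`numpy.gradient`, one-sided at the ends). κ and τ are
reported as missing (NaN) when |r′| < 1e−12, and τ additionally when
|r′×r″| < 1e−8·|r′|³, where the formulas are numerically meaningless.
With fixed σ² the whole smoother is affine per axis and hence exactly
equivariant under rigid motions; with optimized σ² the per-axis noise
estimates can differ slightly between orientations.

## Parallel-transport frame

Tangents are normalized finite-difference velocities; a zero-speed sample
inherits its predecessor's tangent (a fully stationary trajectory is an
error). The initial normal N₀ is the coordinate axis least aligned with
T₀, Gram–Schmidt-orthogonalized — deterministic and reproducible. Each
step rotates N about U = T_i × T_{i+1} by θ = arccos(clamp(T_i·T_{i+1}))
(the dot product itself is a cosine, not an angle); ‖U‖ < 1e−10 copies N
unchanged, and an antiparallel tangent pair (a reversal, which the
transport rule cannot orient) is handled by composing two quarter-turn
rotations about a perpendicular axis, with a logged warning. After every
step N is re-orthogonalized against T to stop numerical drift; B = T × N.

The N₀ gauge is a genuine degree of freedom: any deterministic rule built
from T₀ alone cannot be rotation-covariant, so descriptors are invariant
under rigid scene motions *given* that N₀ is transported with the scene
(the invariance tests pass R·N₀ explicitly). Within one dataset processed
in one coordinate system this gauge is fixed and comparisons across cells
are consistent. Reorientation maps v ↦ M(v − origin) with M = rows
(T, N, B); the standard-basis ablation substitutes identity frames and
changes nothing else.

## Spherical parameterization

Shape analysis needs a bijective map from each (closed, genus-0;
validated via edge-manifoldness and V − E + F = 2) mesh to the unit
sphere. Two stages:

1. **First-order-ellipsoid normalization.** Vertices are centered on the
   volumetric centroid and whitened by the inverse symmetric square root
   of the enclosed solid's second-moment tensor (exact divergence-theorem
   integrals). An ellipsoid maps exactly to a round sphere, so its
   spherical parameterization is its affine preimage and the degree-1
   coefficient ratios recover the semi-axis ratios exactly — the property
   the eccentricity indices are defined by. The transform is a full
   symmetric matrix (no eigenvector picking), hence continuous for
   near-isotropic shapes and commuting with rotations. Intrinsic flows
   alone do not have this property: on a 2:1:1 ellipsoid the conformal
   limit gives a degree-1 ratio of ≈1.16, radial projection ≈1.34, and an
   exact authalic map ≈1.78 (all measured numerically), versus the
   defining value 2.
2. **Conformalized mean-curvature flow.** The residual non-ellipsoidal
   shape is driven round by implicit Euler steps
   x ← (M_t − δL₀)⁻¹ M_t x, with the cotangent stiffness L₀ frozen at the
   initial mesh (this is what prevents neck-pinch singularities on
   non-convex shapes; raw MCF with a recomputed Laplacian is also
   discretely unstable on coarse meshes) and the barycentric lumped mass
   M_t recomputed per step. After each step the surface is re-centered on
   its *area-weighted* centroid and rescaled to unit mean radius — the
   area weighting counters the flow's Möbius drift, which vertex-mean
   centering does not. Defaults: δ = 0.05 (scale-free, since the surface
   is renormalized each step), tol = 0.01 on the radius coefficient of
   variation ("sphericity"), max 500 iterations. The discrete flow has a
   resolution-limited fixed point; a stall (relative sphericity change
   < 1e−6) below sphericity 0.05 is accepted as converged, since the
   residual radius spread is removed by the final radial projection onto
   the unit sphere. Cotangents of corners with near-zero triangle area
   are replaced by 1e−8; legitimately negative cotangents of obtuse
   triangles are kept. Flipped spherical triangles (orientation against
   the outward normal) are counted as a bijectivity proxy and are zero on
   all test shapes.

## Spherical-harmonic descriptor

Orthonormal real spherical harmonics without the Condon–Shortley phase;
flat index j = l² + l + m + 1, k = (l_max+1)² basis functions, default
l_max = 6 (k = 49). The basis is evaluated at each vertex's sphere
position using the **polar axis along +y** (colatitude arccos(u_y),
azimuth atan2(u_z, u_x)): with this pole the degree-1 harmonics (1,1),
(1,0), (1,−1) are proportional to x, y, z respectively, which is the
pairing the eccentricity indices assume. `SphericalMap.to_angles` keeps
the conventional z-pole angles for I/O; only the basis evaluation uses
the y-pole.

Coefficients solve the n×k least-squares system per coordinate function
(unweighted by default; optional vertex-area weighting). Eccentricities
use absolute degree-1 coefficients — signs encode pole alignment, not
shape — and E_yz = E_xz/E_xy is redundant, so features keep only E_xy and
E_xz. The shape distance is the plain L2 norm over the concatenated 3k
vector including l = 0; dropping the translation component is possible by
slicing but is not the default, matching the literal descriptor
definition. Global normalization constants cancel in all ratios.

## Synthetic cell

The generator encodes the benchmark conditions: 250 frames; observations
at t = 1, 10, 20, …, 250 (26 meshes; the rest is holdout); speed =
0.05 + two Gaussian bumps (centers 65/185, widths 25, amplitudes 0.6, in
cell-scale units per frame) giving the accelerate–decelerate–accelerate–
decelerate pattern; a sigmoidal 1.2-rad heading turn centered at t = 115
(width 10), placed in the slow phase so curvature and torsion peak
between t ≈ 100 and 130; a gentle pitch oscillation makes the path
non-planar. The surface is a subdivided icosphere (level 3, 642 vertices)
with a pseudopod: vertices within a Gaussian angular cap (σ = 0.5 rad)
around the motion direction displaced radially by
0.6·(speed/max speed) cell radii — the speed-locked protrusion law —
plus seeded low-order (l ≤ 4) spherical-harmonic radial noise of
amplitude 0.02. Every mesh is rescaled to unit volume and translated so
its vertex mean sits exactly on the intended path; the ground-truth
trajectory, speed, curvature, torsion, and protrusion direction are
recorded at all 250 frames. An `isotropic` mode spends the same
deformation on an axisymmetric degree-2 breathing mode with no relation
to the motion direction; the two-group cohort generator applies an
independent random rigid rotation per cell, which is what makes
world-frame coordinates uninformative and the moving frame necessary.

What the benchmark does *not* emulate: segmentation/meshing artifacts,
topology errors, anisotropic imaging resolution, mass-center measurement
noise (vertex means sit exactly on the path), or biological shape
variability beyond the two deformation laws. Passing tests therefore
demonstrate correctness of the machinery and the qualitative
shape–movement coupling, not performance on real microscopy data.

## Statistics

MAD is the raw median absolute deviation (no 1.4826 factor); percentiles
interpolate linearly between order statistics. Peak counting collapses
runs of equal values (a plateau is one peak) and counts strict interior
maxima above a prominence threshold (default 0). Cells need ≥ 6 usable
time points; meshes failing the topology check are excluded with a
logged reason. Kendall correlation is τ-b; UMAP runs with
n_neighbors = 20, min_dist = 0.1, 2 components, Euclidean metric, fixed
seed; KNN uses stratified 10-fold CV over k ∈ {3, 5, 10, 15, 20, 25}
with the *same* seeded fold partition for the moving-frame and
standard-basis feature sets, so the per-fold accuracy differences feeding
the one-sample t-test are properly paired. Permutation importance is the
seeded mean accuracy drop per shuffled column.

## Problem sizes in tests

The test-suite cohorts use shortened movies (40–60 frames, observation
stride 6–8, icosphere level 2 = 162 vertices) with all profile parameters
rescaled proportionally (`SyntheticCellConfig.scaled`); the single-cell
qualitative benchmark and the acceptance computation run at the full
default conditions (250 frames / 26 observations / 642 vertices). The
KNN benchmark averages 10 seeded fold partitions over a 22-cell cohort.

## Known limitations

- The N₀ gauge freedom above: descriptor components in the (N, B) plane
  are defined up to a fixed twist per trajectory.
- The degree-1 eccentricity semantics rest on the first-order-ellipsoid
  normalization; a purely intrinsic (conformal/authalic) parameterization
  would compress the ratios, and descriptors from the two choices are not
  comparable.
- Spherical parameterization assumes the whitened shape flows to the
  sphere without fold-over; extremely long or branched protrusions could
  violate the flipped-triangle check, which is reported but not repaired.
- GP smoothing degrades near the trajectory ends (no data beyond the
  boundary), visible as larger reconstruction error at the first and last
  frames.
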