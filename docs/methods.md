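# Methods

`meshmorph` implements two complementary routes for comparing 3-D biological
shapes — typically bone surfaces segmented from µCT — and the machinery to
validate both on synthetic populations with known ground truth.

## From volumes to surfaces

Bone masks are produced by intensity thresholding (`threshold_mask`,
inclusive `>= tau`), cleaned by a morphological opening-then-closing with a
ball structuring element (`morph_open_close`; opening removes speckle and
thin cartilage remnants, closing fills comparably small holes — the
composition is an alternating filter and is idempotent away from the volume
border), reduced to the largest connected component (26-connectivity
default; ties broken deterministically by smallest flat voxel index), and
optionally parcellated into parts by marker-based watershed on the negated
Euclidean distance transform, which cuts at constrictions between marked
regions.

Surfaces are extracted with marching cubes at iso-level 0.5.  The binary
field is pre-smoothed with a Gaussian of 0.8 voxels before contouring:
contouring the raw staircase inflates surface area by roughly 10% on a
digitised ball, while the pre-smoothed surface is within ~3% of the analytic
area and its vertices stay within half a voxel of the mask boundary.  Set
`smooth_sigma=0` for the raw behaviour.  Vertices are in physical
millimetres (spacing and origin applied) and faces are oriented outward.

Mesh hygiene follows the usual sequence: merge near-duplicate vertices
(default tolerance 1e-6 mm), drop degenerate and duplicate faces and faces
on non-manifold edges, uniform-weight Laplacian smoothing (default step 0.5,
10 iterations), and quadric edge-collapse decimation.  Decimation enforces
the edge link condition and rejects collapses that flip or degenerate
triangles, so closed surfaces keep their genus.  Decimation fractions are
per-study choices (dense µCT meshes are commonly reduced to a few percent of
their original face count); the synthetic fixtures here are generated at the
target resolution directly.

## Landmark-based route

Sparse homologous landmarks drive the classical geometric-morphometrics
path: Umeyama closed-form similarity/rigid alignment (at least four
non-collinear matched points; reflections never returned), Generalised
Procrustes Analysis (centre, optional scaling to unit centroid size,
iterative rotation to the evolving mean until the mean changes by less than
1e-10 relative, 100-iteration cap, reflections disallowed), and a
permutation test on the Euclidean distance between group mean shapes in
tangent space with the conservative `(count + 1) / (n_perm + 1)` convention,
so p is never exactly zero.  Centroid size is `sqrt(sum ||x_i - mean||^2)`;
the normalised variant divides by the point count and is comparable only
within a fixed landmarking scheme.

## Landmark-free route: control-point atlas under a varifold metric

The core model represents each subject as a diffeomorphic deformation of a
shared template.  A Gaussian kernel `K(x, y) = exp(-||x - y||^2 / sigma_V^2)`
turns momenta `alpha_k` at control points `c_k` into a velocity field
`v(x) = sum_k K(x, c_k) alpha_k`; control points and momenta follow the
Hamiltonian geodesic equations, integrated with RK2 (midpoint) over
`n_timesteps = 10` by default (the Hamiltonian is conserved to well under 1%
at 20 steps on typical momenta).  Surfaces are compared without
correspondence through a kernel metric on face centres and area-weighted
normals.  The default orientation kernel is the varifold (squared,
orientation-invariant) form — robust to the inconsistent orientations
marching cubes can produce — with a signed currents variant behind
`mode="currents"`.

Atlas estimation minimises

    J = sum_i [ d_W^2(phi_{alpha_i}(T), S_i) / (2 sigma_eps^2)
                + 1/2 alpha_i^T K_V(c) alpha_i ]

jointly over template vertices, control points and per-subject momenta.
Gradients are hand-derived adjoint (reverse-mode) sweeps through the RK2
integrator and the varifold term; the test suite checks them against central
finite differences at 1e-4 relative.  The optimiser is block gradient
descent: each block's step is renormalised from its current gradient
magnitude every iteration (a block's gradient can be exactly zero early on —
the control-point gradient vanishes at zero momenta — so a one-time step
calibration would blow up), with a single adaptive global factor backtracked
until the objective decreases and grown by 1.5x after clean steps.  The
objective therefore never increases across accepted iterations.  Stopping:
relative objective change below `tol` (1e-4 default) or `max_iter` (150
default); hitting the cap returns the best iterate with a warning flag.

Defaults follow the usual working ratios for this model family:
`sigma_V = sigma_W` (deformation resolved at the same scale as shape) and
`sigma_eps = sigma_W / 20` (data term weighted strongly relative to
deformation cost).  `sigma_W` itself is a per-study resolution choice with
no universal default; it is the main dial between coarse and fine shape
differences.  Control points start on a regular grid of spacing `sigma_V`
covering the pooled bounding box plus a one-spacing margin, and drift toward
regions of variation during optimisation unless frozen (`freeze_cp`).  The
template initialises at the medoid subject (smallest summed varifold
distance to the rest) unless an initial template is supplied.  Kernel sums
are exact O(N^2) — appropriate at the mesh and control-point counts this
package targets.

Group mean shapes are produced by shooting the template with the arithmetic
mean of a subset's momenta, which preserves one-to-one vertex correspondence
with the template — the property the difference maps rely on.

## Identifiability of momenta, and how the recovery study is designed

Two gauge freedoms limit what "recovering the true momenta" can mean:

1. Tangential re-parameterisation: a velocity field tangent to the surface
   slides points along it without changing the shape.  Correspondence-free
   metrics are blind to it, so tangential momentum components are
   unrecoverable in principle.
2. Kernel-null directions: momentum combinations in small-eigenvalue
   directions of the kernel Gram matrix produce almost no velocity and cost
   almost no energy; they are invisible to the data and essentially free,
   so the estimator leaves them near zero.

The construct-and-recover study (`make_recovery_study`) therefore generates
its ground truth inside the identifiable subspace: control points sampled on
the template surface by farthest-point sampling, and true momenta built as
kernel-smoothed *normal-directed* fields (`+beta` for one group, `-beta` for
the other, plus per-subject jitter).  Default conditions: 2 x 6 subjects on
a 320-face ellipsoid, 60 control points, `sigma_V = 0.5` (ellipsoid radius
1), group field scaled to a maximum surface displacement of 0.25 and jitter
to 0.04.  Under these conditions the estimated momenta correlate with truth
at r > 0.9 elementwise — and noticeably higher when compared in the kernel
metric (velocities at the control points), the canonical geometry for
momenta, which discounts the gauge directions — while per-subject varifold
residuals fall by two orders of magnitude from their initial values.

## Shape statistics

Kernel PCA double-centres the kernel matrix and eigendecomposes it; scores
are `eigenvector * sqrt(eigenvalue)`.  With the linear kernel this equals
ordinary PCA (checked against an SVD oracle); the Gaussian kernel's
bandwidth defaults to the median pairwise distance.  Dimension 5 is the
default shape-space dimension.  Momenta enter statistics flattened to
`n x (3 N_cp)` feature matrices.

Group classification uses a pooled-covariance linear discriminant (with a
small trace-scaled ridge) under stratified k-fold cross-validation, written
directly in numpy so the 500-replicate calibration studies run in seconds;
its fold-wise predictions are cross-checked against scikit-learn's LDA in
the tests.  Significance comes from label permutation with the fold
structure redrawn per permutation and the `+1` convention.  Because CV
accuracy is discrete, tied permutation statistics make the test
conservative; at 20 subjects the empirical type-I rate at alpha = 0.05 runs
around 0.02-0.03, reaching the nominal level by ~60 subjects.  The
calibration study therefore uses 60 subjects.

The scrambled-group diagnostic guards against overfitting in
high-dimensional shape spaces: the between-group mean-score vector magnitude
is compared against group-size-preserving random scrambles; a z-score in
scramble standard deviations and a Shapiro-Wilk normality p for the scramble
magnitudes are reported (the z is only interpretable if the scramble
distribution is roughly normal).  Note the z saturates for very large
effects, since the scrambles themselves inherit the effect variance.

Allometry: the common allometric component is the unit vector along the
covariance of shape features with log centroid size (pooled within groups
when groups are given); CAC scores are the projections on it, and `r2_size`
is the fraction of total shape variance explained by the multivariate
regression of shape on log size.  Log size is the default (`log_size=False`
for raw size).  Bland-Altman agreement between two per-subject measures uses
the standard mean ± 1.96 SD limits.

## Difference maps

Displacement maps are unsigned per-vertex distances between corresponding
meshes.  Signed distance from a reference mesh to a target surface uses
exact point-to-triangle distances with an inside test by ray-crossing parity
(fixed irrational ray direction to avoid edge-grazing); points inside the
target are negative.  A non-watertight target falls back to a nearest-face
normal-dot sign with a warning.  Local stretch is operationalised as the
per-vertex ratio of summed incident triangle areas (B over A): a uniform
scale `s` maps to exactly `s^2`, local growth to values above 1, with no
global normalisation.  An alternative mean-incident-edge-length ratio
(`method="edge"`, scaling as `s`) is provided because "vertex spacing" can
reasonably be read either way.  3-D thin-plate splines use the `U(r) = r`
biharmonic kernel with exact landmark interpolation; affine relations yield
zero kernel weights.  Morph sequences interpolate vertices linearly with an
optional exaggeration factor.

## Synthetic populations

`generate_population` deforms an icosphere or ellipsoid template with
spherical-Gaussian radial bumps: a group-specific bump (group B only), a
fixed smooth allometric field scaled by each subject's log size, an optional
second bump for a sex effect, i.i.d. vertex noise, and a global scale drawn
log-normally (optionally with a group size ratio; a preset models a ~7%
group size deficit).  Everything is seeded and bitwise reproducible, and the
per-vertex noise-free displacement is recorded as ground truth.  What this
emulates: localised group shape differences, allometry and dimorphism at
realistic effect-to-noise ratios.  What it does not: real µCT artefacts,
segmentation errors, varying mesh topology across subjects, or landmarking
error — so green tests demonstrate correctness of the machinery, not
robustness to every property of real scan data.

## Problem sizes and tolerances

The validation studies run at desk scale by design: 320-face ellipsoids with
60 control points for atlas recovery, 80-face icospheres for the end-to-end
group study, 500 replicates x 200 permutations for calibration.  Numerical
tie-breaks and degenerate-input behaviour (collinear landmarks, coplanar TPS
configurations, zero-area faces, empty masks) raise typed errors rather than
silently proceeding.  Known limitations: the atlas optimiser is first-order
(no L-BFGS), kernel sums are dense, and momenta are compared to ground truth
only up to the gauge freedoms described above.
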