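# Methods

## Convex hulls and volumes

Each functional unit of a skeleton (skull, neck sub-units, trunk, wing and
leg elements, feet) is treated as a bare point set in millimetres; mesh
connectivity, normals and manifold defects in the source files are ignored
because the convex hull depends only on the points. Duplicate points are
removed before hulling, and a segment whose distinct points number fewer
than four or are coplanar/collinear raises a hard `DegenerateGeometry`
error rather than contributing zero volume — a silent zero would corrupt
the whole-body total. Hulls are built with Qhull (via
`scipy.spatial.ConvexHull`) and re-oriented so every triangular facet's
normal points outward; the volume is the sum of signed tetrahedra spanned
by the facets and the origin, which is exact for a closed oriented surface
and independent of the origin choice.

Numerical tolerances are scale-free: point-in-hull tests use a planarity
tolerance of 1e-8 × the hull's bounding-box diagonal, and volume
comparisons a relative tolerance of 1e-9. Both are far below measurement
error for mm-scale skeletal data but large enough to absorb floating-point
noise under rigid motions.

Whole-body hull volume is the sum of per-segment hull volumes. Because
hulls fitted to feet are strongly influenced by the (frozen or mounted)
posture of the digits, totals are carried both with and without the
segments explicitly flagged as feet; feet are never auto-detected from
labels. A `mirror_segment` operation reflects a segment across a supplied
plane, for restoring bilateral symmetry when one side of a mount is
incomplete; reflection is an involution and preserves hull volume.

Segment partitioning itself (which bone belongs to which unit, where to cut
at joints) is taken as given input — it is an anatomical decision made
upstream in the digitization workflow, not something the toolkit infers.

## Calibration

The mass–volume relationship is fitted as `log10 M = a + b·log10 V + ε`
with M in grams and V in mm³; the intercept is meaningless in any other
units, so inputs must be converted first. The fit is ordinary least
squares; because the equation's purpose is prediction, type-I regression is
used rather than reduced major axis. Summary statistics retained with each
model are everything prediction needs without refitting: n, x̄, Sxx, SSE,
MSE = SSE/(n−2), r², coefficient standard errors and 95% t-intervals, and
AIC. Datasets that happen to be exactly collinear are snapped to SSE = 0
(MSE = 0, zero-width intervals, AIC = −∞ sentinel) so the noiseless
synthetic path is well defined.

PGLS assumes residuals are multivariate normal with covariance σ²C, where
C(i, j) is the branch length shared by tips i and j on a rooted tree
(depth of their most recent common ancestor). Branch lengths absent from
the Newick input default to 1, matching the unit-branch-length convention
used for the packaged analysis; no Pagel's λ or other transforms are
applied. Estimation is GLS via a Cholesky factorization of C;
a non-positive-definite C raises `SingularCovariance`. The stored x̄, Sxx
and SSE are the C⁻¹-weighted analogues, so the same prediction-interval
formulas apply and PGLS with C = I reproduces OLS exactly. Species are
matched to tips by exact string equality after trimming whitespace — fuzzy
matching would corrupt C silently.

AIC uses the full Gaussian log-likelihood (2π constants included) at the
ML variance SSE/n with k = 3 parameters (a, b, σ²); for PGLS the
likelihood includes ½·log|C|, making the two covariance structures
comparable on the same data. AIC conventions vary across software by
additive constants, so published AIC values are treated as soft,
magnitude-level checks only.

One data note: in the packaged pigeon table, the superb fruit dove's
minus-feet volume is stored as 74,691 mm³, correcting an obvious
typesetting slip (a shifted comma) in the printed source; the corrected
value is consistent with its with-feet volume of 77,882 mm³.

The intact-carcass calibration (n = 7) is retained despite its weak fit
(r² ≈ 0.70): intact masses vary with gut and crop contents, and the
combined model exists to bracket predictions rather than replace the
eviscerated one.

## Prediction

Back-transforming a log-linear fit to the arithmetic scale biases the
point estimate low; the correction applied is the factor `e^(MSE/2)` with
MSE on the log10 scale. This is the form quoted with the original
calibration even though the strictly consistent base-10 smearing factor
`10^(ln(10)·MSE/2)` differs slightly; at MSE ≈ 0.005 the two differ by
about 0.2%, below reporting precision, and fidelity to the published
convention was preferred. The correction multiplies the prediction-interval
bounds as well as the point estimate, which keeps the interval symmetric
about the corrected estimate in log space; whether the bounds are corrected
or not is likewise invisible at reporting precision.

Prediction intervals use the standard new-observation formula with n − 2
degrees of freedom. Each fitted model carries a `predictor_variant` tag:
pigeon-calibrated models predict from minus-feet volumes, while externally
published ground-bird coefficients are applied to with-feet volumes, and a
fossil table lacking the required column is a hard `VariantMismatch` error
rather than a silent substitution. The density floor always uses the full
with-feet hull volume, since it is a statement about the whole body.
`apply_external_model` evaluates bare published coefficients (point mass
only) and promotes to a full interval-bearing prediction when the source
regression's n, x̄, Sxx and MSE are supplied.

Reported tables round grams to integers and kilograms to 0.1 kg; unrounded
values are always retained alongside.

## Segment composition

Per-segment fractions of total (with-feet) hull volume are compared between
a fossil and the extant sample with a one-sample t-test (df = n − 1). The
tail is an explicit argument: whether a fossil trunk is expected to be
proportionally smaller or larger than extant relatives is a hypothesis the
analyst states, not something inferred from the sign of the data. Fractions
default to with-feet totals. No multiple-testing correction is applied
across segments; tests are reported raw.

## Synthetic data

The geometric generator emits point clouds on convex polytopes of exactly
known volume: cuboids (abc), regular tetrahedra (e³/(6√2)), and octahedral
ellipsoid approximations with semi-axes a, b, c (volume 4abc/3 — the
octahedron's own volume is the ground truth, deliberately, so no
approximation tolerance couples the generator to the hull code). Every
polytope vertex is included in the cloud; interior points are Dirichlet
convex combinations of the vertices scaled toward the centroid by a jitter
amplitude in (0, 1], so no jitter setting can move a point outside the
generating polytope and the analytic volume remains exact. Segments are
posed with uniformly random rotations and translations within ±100 mm.
Ground-truth volumes come from the closed-form shape formulas, never from
the hull module under test.

The statistical generator draws calibration datasets from
`M = 10^(a + b·x + ε)` with x uniform on a configurable log10-volume range
and ε either i.i.d. Gaussian or multivariate normal with covariance σ²C on
a supplied tree. Defaults mirror the extant-pigeon calibration regime:
n = 13, a = −2.31, b = 0.90, residual SD 0.065 on the log10 scale
(≈ √MSE of the eviscerated fit), x ∈ [4.6, 6.2] (≈ 40,000–1,600,000 mm³).
Synthetic specimens receive a with-feet volume 3% above the minus-feet
value, a typical feet share in the extant table. All generators are pure
functions of (spec, seed) via `numpy.random.default_rng`; no global state.

What the synthetic data do not emulate: real bone-surface geometry, CT
segmentation artefacts, digit-posture variation in feet, measurement error
in volumes (the model places all noise in mass), and non-Brownian
evolutionary covariance. Passing recovery tests therefore demonstrates
correctness of the geometry and inference machinery, not robustness to
those real-data effects.

## Verification scale

The test suite exercises Monte-Carlo containment oracles at 2–4 × 10⁵
samples per hull (volume agreement within 1%), prediction-interval coverage
over 1,000 replicated fits (empirical coverage required in 0.93–0.97), and
coefficient recovery over 500 replicated calibrations (bias within 4
Monte-Carlo standard errors; slope bias < 0.005). These sizes give stable
verdicts while keeping the default suite around a minute on one CPU.

## Known limitations

* Convex hulls overestimate the volume of concave regions (e.g. between
  splayed toes) and are sensitive to missing skeletal extremities; damage
  inside the hull is invisible, damage at the extremes propagates directly
  into volume.
* The calibration assumes the target shares the density and soft-tissue
  proportions of the calibration species; extrapolation far beyond the
  calibration size range widens intervals but cannot reveal a shape break.
* PGLS supports only plain Brownian motion with fixed branch lengths.
* Centre-of-mass and inertial properties are out of scope; convex hulls do
  not carry a realistic mass distribution.
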