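# Methods

This note records the models, parameter choices and numerical decisions
behind `headcirc`, and what the synthetic evaluation does and does not
demonstrate.

## Geometry and conventions

All internal geometry is in millimetres in the camera-origin frame (z
along the optical axis, into the scene); circumferences cross the API
boundary in centimetres, the clinical unit. Depth images are 16-bit
millimetre grids; 0 is the sensor's no-return sentinel, and NaNs are
normalised to 0 on ingest. Pixel offsets `(u_d, v_d)` are measured from
the principal point, which defaults to the image centre when intrinsics
omit it. The back-projection `x_p = -(z_p/f) u_d`, `y_p = -(z_p/f) v_d`
and its exact inverse are used consistently by the pipeline and the
renderer, so the sign convention cancels end to end; the round trip is
exact to floating-point rounding.

## Mat plane

The bedding is modelled as `Ax + By + Cz = 1`, fitted by linear least
squares (pseudoinverse of the stacked coordinates against ones). This
parameterization cannot express a plane through the camera origin; the
camera never lies on the mat, but the degenerate case is detected anyway
by comparing the constrained fit's orthogonal residual with the
total-least-squares residual (factor 10 plus an absolute floor) and
raising a clear error. Heights above the mat are signed perpendicular
distances, positive toward the camera.

Robustness to towel folds and outliers comes from RANSAC: 500 iterations
of {sample 3 points, fit, count points within 3 mm}, best consensus wins,
ties keep the earlier iteration (deterministic under the surfaced seed),
and the winner is refit by least squares on its full inlier set. The
iteration count and tolerance are sized for 640×480-scale clouds
(subsampled to 4,000 mat points) and are exposed in `PipelineConfig`. A
fit supported by under 30% of points is flagged low-confidence.

## Head sphere

The sphere is fitted in standard form `x² + y² + z² + kx + ly + mz + n =
0`, linear in `(k, l, m, n)`, solved by pseudoinverse; centre
`(-k/2, -l/2, -m/2)` and `r² = a² + b² + c² − n` (guarded for `r² ≤ 0`
and rank deficiency on coplanar input). Because the system stays
full-rank for any non-coplanar sample, recovery is exact on noiseless
data even when only the camera-facing hemisphere is visible — the
situation every top-down scene presents. No nonlinear refinement is
applied; the sphere only localises the measurement plane, so millimetre
accuracy of its centre suffices.

Before sectioning, the pipeline drops head points whose distance from the
fitted sphere surface exceeds 15 mm and refits once. This is outlier
rejection on the cloud, not curve smoothing: gross depth outliers (the
specular/transparency artefacts incubator hoods produce, simulated at 2%
of pixels displaced 30–80 mm) otherwise capture isolated lateral bins and
inflate the polyline arc length by centimetres. The 15 mm threshold sits
between the ellipsoid-vs-sphere mismatch of a real head (a few mm at the
anisotropies considered) and the 30 mm minimum outlier displacement.

## Body frame and cross-section

The longitudinal axis is the first principal direction of the body cloud
(the long axis dominates the variance), projected into the mat plane so
that "vertical" is always the mat normal rather than the camera axis —
heights are mat-referenced, and the camera need not be exactly
perpendicular to the bedding. A conditioning guard requires the top two
eigenvalues to differ by a factor ≥ 1.5, else the orientation is declared
ambiguous. The PCA sign ambiguity is resolved solely by the head
position: the frame is flipped 180° about the vertical axis if needed so
the head centroid sits on the negative longitudinal side. PCA uses the
body cloud only (configurable); including the head would bias the axis
toward the head's offset.

The measurement plane is coronal: it contains the mat normal and the
lateral axis and passes through the sphere centre, i.e. it is orthogonal
to the body's longitudinal axis. For a supine infant this is the closest
analog of the occipital-to-brow tape path. Head points within 2 mm of
the plane are projected to (lateral coordinate, height above mat), binned
at 1.5 mm, and reduced to the median per bin — the median resists stray
pixels without distorting the curve. Fewer than 5 occupied bins raises an
error. An optional moving median (window 3) over the binned curve exists
in config and is off by default.

The three features are: height at the smallest-s occupied bin, height at
the largest-s bin (the lateral extremes where the camera loses sight of
the head), and the polyline length of the binned curve. "Edge height" is
an operational definition: for a convex head seen from a finite-distance
camera the visible silhouette ends slightly above the widest point, so
these heights are large (several cm) for real head shapes and near zero
only for objects, like a hemispherical dome, whose rim is visible.
Optional extras (sphere radius, max height, section width) are off by
default.

A known discretization property: the binned-median polyline cannot
resolve near-vertical curve segments — the extreme bin collapses a
vertical span of roughly `sqrt(2 r w)` (bin width `w`) into one point, so
the arc of a full dome is reproduced to well under 1% only when the
sampling grid places points on the rim itself. This is immaterial for
head measurement (the visible curve never reaches the mat) but matters
when validating against analytic domes; the test suite checks the
truncated-profile case against a quadrature oracle of the generating
curve.

## Regression and evaluation

Four tree-based regressors are supported: decision tree, extra trees,
AdaBoost and random forest (the default: 100 trees, unrestricted depth,
all features per split, seeded). Tree ensembles cannot extrapolate beyond
observed targets, which is desirable here — a corrupt feature vector
yields an in-range, flaggable estimate rather than a wild one. Models
persist via joblib and reload bit-identically.

Accuracy is MAE in centimetres; MSE/RMSE over-weight the occasional
badly-posed scene, and a stable, interpretable centimetre figure is what
clinical users need (RMSE is reported alongside for diagnostics only).
The error distribution is additionally binned at ≤1 cm / 1–2 cm / >2 cm,
1 cm being roughly the variability of manual taping. The study-analog
protocol is a single seeded 135/49 split of a 184-scene cohort.

## Synthetic scenes

The simulator emulates a top-down incubator view: a head ellipsoid (three
semi-axes; coronal aspect ratio `a_vert/a_lat` drawn from 0.85–1.15,
longitudinal semi-axis 1.25× the mean coronal radius) and a body
ellipsoid resting on a mat plane at 900 mm depth (f = 580 px, 640×480),
with subject yaw uniform in 0–360°, head tilt uniform within ±10° per
axis, mat tilt within ±3°, and the head placed at either longitudinal end
so the head-left canonicalisation is exercised both ways. Head-mat
tangency is exact by construction: the centre is placed at the
ellipsoid's support height above the ideal plane, so the minimum surface
height is zero to numerical precision — the constraint the whole
measurement leans on.

The mat deviates from its ideal plane by two seeded sinusoids (total
amplitude up to 8 mm, wavelengths 80–250 mm), emulating towel thickness
and folds; ray/heightfield intersections are solved by three fixed-point
iterations (exact when flat). Depth noise is Gaussian (σ = 1 mm default)
and 2% of valid pixels are displaced by ±30–80 mm. Ground truth is the
analytic perimeter of the head's own coronal section (complete elliptic
integral of the second kind), the quantity a tape measure would report.
Scenes regenerate bit-exactly from their stored spec and seed.

What the simulator does not model: real cranial shape (an ellipsoid has
no occipital flattening or molding), hair, bedding that partially covers
the head, limbs overlapping the head box, sensor-specific noise structure
(axial bias, edge fattening), or detector errors (tests use oracle
boxes). Passing the synthetic study therefore demonstrates that the
geometry and learning chain recovers circumference when its assumptions
hold — not clinical accuracy on real infants, which requires real paired
data.

## Problem sizes and determinism

The study analog uses 184 scenes (135/49 split) — about a minute on one
CPU; unit tests use 12–24-scene cohorts. Every stochastic component
(RANSAC sampling, cohort generation, regressor training, splits) takes an
explicit seed, and `scripts/acceptance.py` derives all of them from its
`--seed` argument. Reports embed the effective configuration, per-stage
timings and stage-tagged warnings/errors; a stage failure always
produces a tagged error report, never a silent partial result.
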