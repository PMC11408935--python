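# Methods

## Scope and model

`fruitherm` computes fruit-level water stress indices from a
temperature-annotated 3D point cloud of an orchard row. The underlying
measurement model is: a time-of-flight LiDAR supplies geometry and a
per-point apparent return intensity at 905 nm (R_ToF); a thermal camera
supplies a 640×480 raster of surface temperatures; known intrinsics and
extrinsics relate the two, so every visible point can sample a pixel and
become a T_Raw reading. Fruit are then isolated geometrically and
radiometrically — temperature is never used for segmentation — and their
calibrated surface temperatures T_Est feed three stress indices.

Assumptions worth stating explicitly:

* **Slender-spindle architecture.** Stem detection assumes the point
  density maximum in the horizontal plane is the stem; that holds for a
  single dominant vertical leader and fails for open-vase or multi-leader
  training. The stem map flags peaks barely above the detection threshold
  as low-confidence.
* **Single global intensity calibration.** The white/black checkerboard
  references define one affine map to percent reflectance; no range or
  incidence-angle dependence is modelled. Values outside [0, 100] are
  clipped (downstream thresholds assume percent semantics) and the clip
  count reported.
* **Radiometric pixels are sampled, never interpolated.** Nearest-pixel
  sampling avoids inventing mixed temperatures across fruit/sky edges;
  the cost is a half-pixel geometric sampling error.
* **Day-scoped extremes.** minT_Est and maxT_Est are taken over all
  segmented fruit points of one measuring day, so FWSI_N of that day's
  own data lies in [0, 1] by construction and attains both ends.

## Index definitions and the air-temperature window

SVP uses the Magnus form `610.7 · 10^(7.5T/(237.3+T))` Pa; VPD is
`(1 − RH/100) · SVP`, reported in kPa. (A formulation that multiplies RH
into SVP without the parenthesis is dimensionally inconsistent; the
package implements the standard deficit form.)

T_a is the mean of the four hourly means for hours n−5 … n−2, where n is
the measurement hour: a four-hour window ending two hours before the
reading. The offset acknowledges fruit thermal inertia — a ~100 g apple
equilibrates to air temperature with a lag, so the air it "remembers" is
not the air of the current hour. The Irmak-style upper reference is
`T_a + 5 °C`; the offset is an explicit parameter (`offset=5.0`).

FWSI_J is implemented and tested but marked *not recommended* in its
output metadata: wet (soap-water) and dry (Vaseline) reference surfaces
are unreliable on apple — the wet film dries, the coating alters both the
thermal and the 905-nm optical behaviour — and values far outside [0, 1]
result. The function warns rather than rejects such values.

## Eigen-features and segmentation criteria

For each point, the covariance of its k = 30 nearest neighbours (self
included, covariance normalised by k) is eigen-decomposed into
λ1 ≥ λ2 ≥ λ3 ≥ 0:

* linearity `L = (λ1 − λ2)/λ1`;
* curvature `C = 100 · (λ3/Σλ)/(1/3)` — surface variation rescaled so a
  plane is 0 and an isotropic neighbourhood 100.

k = 30 balances noise suppression against feature locality at the
generator's point spacing; it is exposed in the configuration. Thresholds
are distribution modes, found as the argmax of a Gaussian KDE (Silverman
bandwidth, 512-point grid over the data range); modes are recomputed per
cloud and per date, never hard-coded, and carry a provenance stamp so
thresholds from one cloud cannot silently be applied to another.

Wood points satisfy three criteria jointly on (L, C, R_ToF); fruit
candidates two criteria on (C, R_ToF). Every comparison direction is a
configuration switch. The defaults are chosen from the geometry and the
reflectance ordering of the synthetic scenes (wood ≈ 20 %, leaf ≈ 40 %,
fruit ≈ 60 % at 905 nm): wood is the most linear (L ≥ L_th) and darkest
(R ≤ R_th) class, and — less obviously — the one with the **highest**
surface-variation curvature (C ≥ C_th): a k-neighbourhood on a 2-cm
trunk cylinder wraps both sides of the stem and is nearly volumetric
(measured trunk C ≈ 32), while a neighbourhood on a 7-cm fruit is a
shallow spherical cap (C ≈ 11). Fruit candidates are curved and bright
(C ≥ C_th,A, R ≥ R_th,A). With these defaults the intensity criterion
does most of the fruit/foliage separation and the curvature criterion
removes flat leaf interiors.

Threshold derivation mirrors a labelled-reference workflow: wood
thresholds default to full-cloud modes (the foliage-dominated
distribution places them at the wood tails), fruit thresholds come from a
fruit reference subset — ground-truth labels on synthetic scenes, a
manually delineated reference on real data. Without a fruit reference the
full-cloud fallback is used and a warning raised.

DBSCAN runs on candidate coordinates only, with minPts = 10 and
eps = mean manual fruit diameter / 2 (radius semantics). The DBSCAN
implementation is in-package (cKDTree neighbourhoods, BFS expansion,
core point = neighbourhood of ≥ minPts including self) so the test suite
can cross-check it against an independent reference implementation.
Detection scoring: a cluster is a true positive when more than half its
points share one unmatched true fruit id; duplicates of an already
matched fruit count as false positives.

## Fusion and registration numerics

Projection is pinhole with optional k1/k2 radial distortion (defaults
zero; a wide-angle thermal lens certainly has distortion, but no
coefficients are assumed). Occlusion uses a per-pixel z-buffer built from
the cloud itself; points within `depth_tolerance` (default 0.10 m) of
the nearest point on their pixel are annotated, all others keep a missing
temperature. Missing temperature is always NaN — never 0 °C — in memory,
CSV (empty field), and PLY (NaN double property).

Extrinsics from ≥ 6 non-coplanar 3D–2D correspondences: DLT on
intrinsics-normalised coordinates, sign fixed by median depth, rotation
projected onto SO(3) by SVD, then Levenberg–Marquardt refinement of pixel
reprojection error. The reprojection RMSE is reported both in pixels and
as percent of the image diagonal (the latter because "percent per pixel"
is not a well-defined unit; both numbers are returned).

ICP is point-to-point with closed-form Kabsch updates, identity
initialisation (the two sides are assumed coarsely georeferenced), a
1.0-m correspondence gate, and convergence when the mean inlier distance
stops improving by 1e-7. Disjoint inputs (no correspondence within the
gate) return a non-convergence flag rather than a spurious alignment.
The mean correspondence distance is non-increasing across iterations.

Stem peaks must exceed mean + 2·SD of occupied-bin counts in a 0.10-m
bivariate histogram; greedy suppression keeps peaks at least
0.7 × planting distance apart (a literal ≥ planting-distance rule would
reject legitimate stems that jitter inward), and each peak is refined to
the count-weighted centroid of its 3×3 bin neighbourhood. The cylinder
crop boundary is closed (≤ radius).

## Calibration

T_Ref is regressed on T_Raw (so the fitted line predicts the manual
reference), OLS on the calibration partition only. The blockwise split
assigns floor(0.8 · n_block) records per date block by seeded shuffle —
floor, not round, which with blocks of 84/84/84/50 gives exactly 241/61.
RMSE is reported in °C and as percent of the partition's mean reference
temperature (the normalisation behind a bare "RMSE %" is otherwise
ambiguous; the absolute value always accompanies it).

## The synthetic generator

The generator emulates a slender-spindle 'Gala' row at desk scale:
0.95 m planting distance, 2.8 m trees, a 2-cm-radius trunk (700 points),
~8 oblique 8-mm branches, 6-cm leaf disks of 20 points at 3000 points/m³
crown density, and ~7 cm fruit spheres of 220 surface points with ≥ 12 cm
centre separation. Reflectance is class-conditional Gaussian
(wood/leaf/fruit ≈ 20/40/60 ± 5 %); temperature is
`air_T + class offset + gradient·(z − z0) + N(0, σ)` with defaults
wood +0.6, leaf −1.7, fruit +1.5 °C (wood slightly above air and foliage
below it, matching typical midday canopy readings) and gradient
−0.8 °C m⁻¹ (cooler canopy tops; the magnitude is a free parameter, not
a field claim). Weather is a diel sinusoid (T minimum 05:00, maximum
17:00, RH in antiphase) at 15-min cadence. One mandatory seed drives all
randomness; identical seeds give bit-identical scenes.

What the generator does **not** emulate — and therefore what passing
tests do not establish about field data: wind-induced motion and mixed
pixels at fruit edges, radiative energy balance (sunlit/shaded fruit
asymmetry), sensor drift, beam-divergence footprint effects, occlusion by
dense foliage beyond simple line-of-sight, and the true reflectance
distributions of bark/leaf/fruit at 905 nm. Detection scores on synthetic
scenes (F1 ≈ 1 at defaults) are an upper bound; on real orchard data the
same pipeline class achieves F1 in the 0.8–0.95 range, improving with
fruit size.

## Problem sizes and degenerate inputs

Default test scenes use one to five trees (≈ 6 000–30 000 points), sizes
at which every stage runs in seconds on one core while keeping ≥ 70
points per fruit after candidate selection — comfortably above the
minPts = 10 clustering floor. Degenerate inputs are contracts, not
crashes: empty crops and all-background frames warn and return empty
results; constant series return their constant with a zero-bandwidth
warning; coincident-point neighbourhoods yield NaN features; degenerate
index days (max = min, or air reference equal to the day minimum) raise
informative errors.

## Known limitations

* The curvature-direction default for wood is tied to structure scale:
  at much higher point densities (or much thicker trunks) wood
  neighbourhoods become locally planar and the direction should be
  flipped via the configuration.
* Fruit thresholds need a labelled or manually delineated reference
  subset; fully unsupervised threshold derivation is out of scope.
* The calibration is a single global affine map; per-tree effects,
  nonlinearity, and robust loss are not modelled.
* LAS/LAZ input, streaming I/O, emissivity correction, and rolling-shutter
  compensation are out of scope.
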