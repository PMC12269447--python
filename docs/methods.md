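# Methods

This note records the models, numerical choices and study conditions
behind `roomct`, in the spirit of a methods appendix: what is computed,
under which assumptions, and what the synthetic validation does and does
not demonstrate.

## Coordinate conventions

All coordinates are physical millimetres. The IEC-61217 axes are fixed
package-wide as X lateral, Y longitudinal (scanner travel, zero at the
scanner parking position), Z vertical. Named frames: `f_ISO` (room frame
at isocenter), `f_IMA` (room frame at the imaging position), `s` (table
support), `CT` (scanner), `pCT` (planning CT), `topo2D` (topogram rasters:
column = lateral mm at the rotation-axis plane, row = IEC-Y mm). Every
point, fiducial set and transform carries a frame tag and frame mismatches
are hard errors. Rotations are stored as matrices and only parameterized
as ZXY Euler angles (degrees) at optimizer boundaries. Voxel indices are
0-based with the origin at the center of voxel (0, 0, 0).

The room-frame chain beyond `f_IMA` (table-sag compensation, the
`f_IMA → f_ISO` transform) is device-specific and enters only as a
user-supplied rigid transform; it is never fitted here.

## Longitudinal distortion model

A scan acquired with its range centered at `y_c` shows a point whose true
longitudinal coordinate is `Y_true` at the image coordinate
`Y_img = (Y_true − c)/(1 + m)`; the compensation applied everywhere in the
package is the affine map

    Y' = (1 + m)·Y_img + c ,

leaving X and Z untouched. `m` is dimensionless (order 1e-3), `c` is in mm,
and the map is invertible for `m > −1`. Because the distortion depends on
the scan range, `(m, c)` are calibrated per range and each coefficient is
interpolated independently with a quadratic polynomial in `y_c` (three
calibrated ranges make the quadratic interpolatory; joint interpolation of
the pair was considered and rejected as unidentifiable with three support
points). Queries beyond the calibrated span are allowed with a warning up
to 10% of the span and rejected beyond — the model has no support there.
The scan-range center is defined as the Y-coordinate of the acquisition's
mid-slice. Topograms use a single `(m, c)` model for all positions: a
global scaling versus distance from the parking position is sufficient for
that modality, whereas volumetric scans need the range-dependent model
(plausibly because the spinning gantry's mechanics differ between the two
acquisition modes).

## Joint frame + distortion calibration

Given per-range mean imaging coordinates of the 12 phantom spheres and
their reference positions in `f_IMA`, the fit minimizes the total squared
FRE over 6 rigid parameters plus `(m_r, c_r)` per range. Structure: for
any candidate scalings, the optimal rigid transform has the closed-form
orthogonal-Procrustes (Kabsch/SVD) solution on the pooled corrected
points, so the outer search runs only over the 2R scaling parameters. The
outer problem is solved with damped least squares (TRF) using numerical
Jacobians, parameter scaling (1e-3 on slopes), and multi-starts at zero
and ±1e-3 slope perturbations; a derivative-free simplex was tried first
and abandoned because the problem contains one exactly flat direction (see
below) that degrades simplex convergence.

**Gauge freedom.** Adding a common offset δ to all intercepts is exactly
compensated by changing the rigid translation by `−R·δ·e_y`; the data
cannot distinguish these solutions, and every downstream prediction
(corrected FRE, the interpolated model composed with the transform) is
invariant. The fit reports the minimum-norm representative (zero-mean
intercepts); recovery tests assert gauge-invariant quantities — slopes,
intercept *differences*, and the composed point mapping.

The correction is applied to imaging coordinates *before* the rigid
transform, matching the order of the positioning chain. FRE is reported
per range before (rigid-only fit) and after correction, as per-point
errors, RMSE and 95th percentile.

## Topogram distortion regression

The longitudinal error `y_topo − y_ref` (reference = distortion-corrected
3DCT positions of the same fiducials) is regressed on position with Huber
loss (δ = 1.0 mm) plus an L2 penalty (λ = 1e-3) on the slope only,
solved by iteratively reweighted least squares to 1e-14; with λ = 0 and no
outliers this reproduces ordinary least squares to machine precision. The
regressor defaults to the reference position (`predictor="reference"`,
switchable to the topogram position; at slopes of order 1e-3 the two are
numerically indistinguishable). δ and λ are configuration-exposed: δ is
set above the localization scatter (≈0.1–0.5 mm) and below gross-error
magnitude; λ only stabilizes the slope under short lever arms and is
deliberately tiny. The fitted regression is inverted exactly into the
standard correction form.

## Fan-beam DRT engine

Topograms are modelled as a 2D fan per detector row with the source
translating along Y (no longitudinal divergence — this is why row = Y
exactly), the virtual detector on the plane through the rotation axis, and
the source at angle α about Y (90° = LAT, source at +X; 180° = PA, source
at −Z) at distance `sad` (default 570 mm, a nominal placeholder — the true
value is device-specific and is exactly what projection calibration
estimates). A point at lateral offset `s` and signed distance `d` toward
the source maps to column `u = s·sad/(sad − d)`. Pixel values are exact
Siddon–Jacobs voxel traversals (incremental parametric face crossings;
numba-compiled) of the attenuation volume, with HU mapped by the
water-linear ramp `μ = max(0, (HU + 1000)/1000)` so values are mm of
water-equivalent path — adequate for geometric registration, not
dosimetry. One pixel-center ray per pixel by default; 3× supersampling is
available and is required when imaging sub-resolution objects (2 mm dots
on a 2 mm raster alias away with single rays). Rigid volume shifts are
rendered by offsetting ray endpoints rather than resampling — exact and
cheap, which is what makes iterative 2D/3D registration affordable.

Projection-geometry calibration fits (α, sad, column origin, column
spacing) to ≥ 4 labelled 3D–2D pairs by least squares from the nominal
geometry; observed coordinates are interpreted in the nominal raster's
physical mapping, so the column parameters absorb detector offset and
field-of-view scale errors. Configurations with all points on the
rotation-axis plane are rejected (SAD unobservable). Residuals are
reported as the RMS of per-point 2D distances.

## Registration

`mattes_mi` estimates mutual information (bits) from a 50×50 joint
histogram with zero-order binning of the first image and a cubic B-spline
Parzen window on the second. 2D/3D registration maximizes the summed MI
between measured topograms and DRTs re-rendered at each candidate
translation, with Nelder–Mead (initial simplex edge 2 mm, parameter
tolerance 0.1 mm — the tolerance is interpreted in mm of simplex extent);
a coarse pass on ~2 mm rasters precedes one full-resolution refinement.
Two orthogonal projections (LAT + PA) give 3-axis observability; a single
projection leaves the source-axis direction essentially unconstrained and
is flagged. An optional per-topogram mask (nonzero = excluded) removes
regions such as an isocenter marker from the metric.

3D/3D translation registration uses the same metric machinery through
SimpleITK's registration framework (Mattes MI, dense deterministic
sampling, Amoeba/Nelder–Mead, multi-resolution shrink 4/2). Smoothing
sigmas default to (2, 1) voxels in physical units: histogram metrics with
linear interpolation exhibit a grid-aligned artifact (the metric can peak
at sub-voxel offsets between identical rasters), and keeping about one
voxel of Gaussian smoothing at the finest level suppresses it.
Translations only, throughout: the table corrects translations, so
rotational offsets are deliberately out of scope.

## Synthetic study conditions

The generators default to the study conditions used by the validation
experiments; they are conditions, not tuning knobs.

* CT raster 0.98 × 0.98 mm in-plane, 1 mm slices; topograms at 1 mm
  (small FoV) and 2 mm (large FoV).
* Calibration: twelve 20 mm spheres per range (a fixed generic layout
  spanning ≥ 150 mm per axis, non-coplanar), ranges centered at 850, 1000
  and 1150 mm from parking; three repeated localizations averaged per
  range. Ground-truth scalings m = (−2, −3, −4)·10⁻³,
  c = (0.3, 0.5, 0.8) mm joined by the unique quadratic profile through
  them, so interpolation error is isolated from model error. Validation
  scans at 984 and 1015.5 mm sit between the calibrated ranges.
* Localization noise is isotropic Gaussian with the per-axis σ chosen so
  the 95th percentile of the displacement *magnitude* equals the measured
  reproducibility (0.2 mm for 3DCT spheres and small-FoV dots; the χ(3)
  and χ(2) 0.95-quantiles convert p95 to σ). Repeated-scan averaging is
  part of the emulated protocol and is applied wherever the physical
  procedure averaged repeats.
* 13 pseudo-random 2 mm dots sample a 240–250 mm field of view with
  ≥ 20 mm pairwise separation and guaranteed transverse spread (depth
  leverage for SAD).
* The head phantom is nested ellipsoids (soft-tissue HU 0–80 with an 80 HU
  shell) with asymmetric internal blobs, an 8 mm dense cranial sphere
  marking the isocenter, and a smooth deterministic sum-of-sines intensity
  modulation (±15 HU, 37/53/71 mm periods) standing in for anatomical
  texture — piecewise-constant rasters are pathological for histogram
  metrics. The texture is anchored to the phantom so it moves with it.
  Displacements follow the clinical scenario: ~10 mm lateral and vertical,
  ~20 mm longitudinal.
* HU assignments (spheres +1500, dots +800, background −1000) are
  arbitrary but fixed; only contrasts matter. No CT physics is simulated
  (no beam hardening, scatter or noise texture; optional additive noise
  only).

**What passing these experiments shows — and doesn't.** The closed loop
validates the geometry chain: distortion algebra, the joint fit, the
projector/renderer pair, and the optimizers recover known ground truth
under realistic noise and raster conditions. It does not validate against
real scanner physics: measured topograms contain scatter, detector blur
and anatomy-dependent contrast that the DRT does not model, and real
localization errors need not be isotropic Gaussian. The registration
experiments use DRTs as the "measured" images, so they probe geometric
consistency and optimizer behaviour, not cross-modality robustness.

## Numerical choices and degenerate inputs

* Rigid fits reject < 3 points and collinear configurations (second
  singular value < 1e-9 of the first); reflections are excluded by the
  determinant correction in the SVD solution.
* Distortion models reject m ≤ −1; interpolants reject evaluation beyond
  the 10% extrapolation margin.
* Sphere localization: Otsu threshold, connected components, discard of
  components smaller than a sphere of half the expected diameter,
  intensity-weighted centroid over a one-voxel-dilated mask. A count
  mismatch (including dots merged below the resolution limit) is an error
  reporting the found count and threshold. Detected-to-reference matching
  is mutual nearest neighbour and must be a perfect bijection.
* Siddon traversal is exact for rays missing the volume (zero) and clips
  corner crossings robustly; the independent accuracy oracle is dense
  0.01 mm nearest-voxel sampling (agreement to ≤ 0.5% on random oblique
  rays).
* Nelder–Mead non-convergence (iteration cap without tolerance) raises
  with the optimization trace rather than returning a best guess.
* Fiducial CSVs are written with 17 significant digits and parsed with
  round-trip float precision, making file round-trips exact.

## Problem sizes

The validation experiments run at the full stated rasters (the head
phantom is ≈ 8.7 M voxels at 0.98/0.98/1.0 mm; topogram pairs ≈ 63 k
pixels per view at 1 mm). Monte-Carlo components use 50 replicates
(validation FRE), 20 experiments (projection calibration) and 100 trials
(FRE-improvement), sizes at which the reported means are stable to well
inside the tolerances they are compared against. Unit tests use smaller
rasters (2–2.5 mm) chosen to exercise identical code paths.

## Known limitations

* The intercept/translation gauge means per-range intercepts are only
  meaningful relative to each other (or composed with the transform).
* The fan model has no longitudinal divergence; scanners with appreciable
  cone angle in scout mode would need a 3D source model.
* MI-based registration assumes enough shared structure between DRT and
  topogram; strongly truncated fields of view or metal artifacts are not
  handled.
* DICOM series reading assumes an axis-aligned patient orientation
  (identity direction matrix); oblique acquisitions are rejected rather
  than resampled.
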