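# Methods

## Coordinate conventions

World coordinates are the DICOM patient system (LPS), millimetres. Voxel
indices are 0-based; the affine maps index (0,0,0) to the first voxel
*centre*. NIfTI stores affines in RAS, so the first two world rows are
negated symmetrically on write and read; NRRD (via SimpleITK) is natively
LPS. DICOM series are sorted by the projection of ImagePositionPatient onto
the slice normal rather than InstanceNumber, which some exporters populate
unreliably; a non-uniform slice gap beyond 1e-3 mm or mixed
SeriesInstanceUIDs is an error, not a warning, because a silently wrong
affine corrupts every downstream measurement.

## Anatomic frames

The femoral frame: PROX is the unit vector from the knee centre (midpoint
of the epicondyles) to the femoral head centre; with t the unit
medial→lateral transepicondylar direction, AP = unit(t × PROX) and
ML = unit(AP × PROX). AP and ML are then flipped *jointly* if ML·t < 0, so
ML always points medial→lateral and handedness (det = +1) is preserved.
This sign rule is a package choice: cross-product order alone does not fix
signs, and a deterministic, side-independent rule is what makes the
pose-equivariance property testable. Whether +AP lands anterior or
posterior for a given limb side is self-consistent but anatomically
unvalidated; it cancels in any within-convention comparison.

The tibial frame shares the femoral ML axis (knee as a hinge), takes its
long axis from the talus centre to the knee centre, and completes the triad
with the same joint-flip rule (PROX forced proximal). The talus centre is a
direct input point; no operational definition is imposed.

The head centre, when not given directly, is fitted to ≥4 non-coplanar
head-surface points: an algebraic least-squares sphere (linear in centre
and radius via |x|² = 2c·x + d) followed by one Gauss–Newton step on
geometric distances. The algebraic fit alone is biased for noisy,
partial-coverage point sets; one refinement step removes the practical bias
without iteration-count nondeterminism.

Degeneracy guards are fixed constants — 1 mm point separations, 1° axis
angles — far below anatomical scale and far above numerical noise.

Realignment between frames is reported as the total rotation angle of
R = axes_bᵀ·axes_a, computed as atan2(‖R − Rᵀ‖-vee, trace(R) − 1) rather
than acos((trace−1)/2); the atan2 form keeps full precision near 0° and
180°. The axial component is the signed angle by which the image of ML has
turned about PROX.

## Resampling

Volumes are resampled onto grids axis-aligned with an anatomic frame by
trilinear interpolation (nearest-neighbour available for masks); samples
outside the input read as air (−1024) for CT and zero counts for SPECT.
Trilinear is a deliberate default: SPECT is smooth at its 3–10 mm intrinsic
resolution, and higher-order splines can ring at the phantom's hard edges.

## Reference region and normalisation

The reference region is an axis-aligned box in femoral-frame coordinates,
by default spanning PROX 80–130 mm above the knee centre over the full
bone cross-section (±25 mm) — mid-shaft for the package's default phantom
geometry, and configurable for other anatomies. Voxel membership is
"centre in the half-open box [min, max)", which prevents double counting
at shared faces and makes the brute-force oracle unambiguous. Statistics
use the sample SD (n−1). Three normalisation modes are provided —
scale-by-mean, offset-by-mean, z-score — with none declared canonical;
which correlates best with clinical outcome is an open question, so the
choice is a config field. Hotspot-vs-reference testing uses Welch's
unequal-variance t-test from summary statistics with Welch–Satterthwaite
degrees of freedom: the two regions have no reason to share a variance.
The degenerate both-variances-zero case returns t = 0, p = 1 for equal
means and the infinite-separation limit (t = ±∞, p = 0) otherwise, so the
noiseless phantom path stays total. An optional CT HU mask can restrict
the reference region to bone; it is off by default.

## Hotspot segmentation and metrics

Thresholds are inclusive (≥): deterministic boundary behaviour. Metrics are
computed on the whole mask by default (per-component metrics via
26-connectivity labelling are available; labels are ordered by descending
size with ties broken by smallest linear index). The centroid is
intensity-weighted by default — it localises the uptake peak — with an
unweighted option. Physical volume is voxel count × |det| of the SPECT
grid's linear affine part: metrics live on the SPECT grid, localised via
CT-derived frames. The mean-uptake readout is threshold-dependent by
construction (e.g. a 4×-mean threshold focuses the mean on the hotspot
core); the API takes the threshold explicitly so any reading is
expressible.

## Surfaces

Marching cubes (scikit-image's Lewiner implementation, linear edge
interpolation) at +150 HU for bone and at the clinical threshold for the
hotspot boundary; vertices are mapped through the volume affine to mm and
optionally into an anatomic frame. Mesh area and enclosed volume use exact
triangle sums (divergence theorem); on an analytic 20 mm sphere at 1 mm
pitch both agree with closed forms well within 2%.

## The phantom: what it emulates and what it does not

The generator emulates the features the pipeline's correctness depends on:
CT geometry with identifiable landmarks (head, condyles whose outermost
points are the epicondyles, talus), a uniform SPECT background uptake b
(default 100 counts), ellipsoidal hotspots at uptake ratio r, Poisson
counting noise (SPECT is count data; Gaussian CT noise is not modelled),
and an arbitrary rigid pose realised by sampling the analytic scene on a
world-aligned grid — rotated *data*, not a relabelled array. Hotspot edges
are hard by default; an optional isotropic Gaussian PSF (FWHM in mm)
emulates SPECT's limited spatial resolution for robustness checks. One RNG
stream per phantom (numpy default_rng seeded from the spec), consumed once
for the Poisson draw in C order, makes volumes bit-reproducible.

It does not emulate realistic bone shape, attenuation, scatter, or
projection-space reconstruction. Passing tests therefore demonstrate the
*analysis* is correct (geometry, normalisation, segmentation, statistics),
not that the method's clinical readouts are accurate on real scans with
PSF blur and partial-volume effects.

Default problem sizes were chosen so a full phantom pair builds in about a
second: a 180 mm femoral segment and 160 mm tibial segment at 2 mm CT and
3 mm SPECT pitch (≈1.0M CT / 0.3M SPECT voxels). The packaged two-patient
scenario fixes the study conditions echoed throughout the tests: P1 one
patellofemoral ellipsoid at ratio 4.5 in neutral pose; P2 a larger
ellipsoid plus a secondary lobe toward the tibiofemoral compartment at
ratio 5.5, posed 8° axially rotated and translated.

## Numerical choices

- Histograms: 64 uniform bins spanning [0, global max] for the
  global/reference/ROI triplet; near-constant samples get a widened range
  so bins keep resolvable width.
- Reference-region and mask oracles in the tests are literal per-voxel
  triple loops; agreement is exact (count) and ≤1e-12 (moments).
- Rotation-angle tests compare against an independent quaternion
  implementation (scipy Rotation) at 1e-9 degrees.
- All tolerances in tests are stated against analytic truths
  (closed forms, generated parameters) or CLT bounds (3·SE) — never tuned
  to observed outputs.

## Known limitations

- No SUV computation (needs injected dose and patient weight) and no
  partial-volume correction.
- The DICOM writer exists to exercise the reader; it emits a minimal
  CT-like single-frame series (int16, identity rescale), not a
  standards-complete export.
- `scene_export` writes geometry (PLY + manifest); rendering style is a
  display concern and out of scope.
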