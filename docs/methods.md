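# Methods

## Problem and model

Standard pelvic CT delivers an effective dose several-fold above plain
radiographs. A tin-filtered ultra-low-dose (ULD) protocol can, in
principle, match the radiograph dose while still supporting bone
assessment — provided (a) its image quality per unit dose is adequate and
(b) radiograph-equivalent projections ("virtual radiographs", VRs) can be
computed from the CT volume with correct projective geometry, so that
standard radiographic measurements remain valid. This package implements
that analysis chain and exercises it end-to-end on synthetic phantoms with
exactly known ground truth.

## Phantom

The phantom is a deliberately simple constructive-solid-geometry pelvis:
an air background (−1000 HU), a soft-tissue trunk ellipsoid plus two
proximal-thigh cylinders (muscle, default 55 HU), two solid cortical
femoral heads (default 1300 HU; per-protocol overrides of roughly 1500 HU
for a standard spectrum and 1124 HU for a tin-hardened one are used in the
cohort pipeline), femoral shafts with a cortical wall around a trabecular
core (300 HU), and 4 mm cortical marker spheres at the lateral acetabular
rim and the inferior teardrop of each hip. Tissues are composited
last-writer-wins in the order background → soft tissue → trabecular →
cortical, which gives deterministic overlap semantics. World coordinates
are mm on LPS-like axes (x left, y posterior, z superior), voxel-center
convention, 0-based indices; default grid 180×120×110 voxels at 2 mm.

The rim marker is placed on the ray from the head center tilted laterally
off vertical by the configured CE angle; the teardrop is placed down the
line from the rim that makes the configured Sharp angle with the
horizontal. Both therefore hold *exactly* by construction, and all hip
landmarks lie in one coronal plane through the projection target. That
plane is detector-parallel in the default anteroposterior geometry, so
cone-beam projection scales the landmark constellation uniformly
(magnification sdd/sod) and preserves the configured angles — the geometric
mechanism that makes VR angle measurement equivalent to radiographic
measurement.

Noise is white Gaussian in HU, added voxel-wise with a seeded generator.
This matches the operational noise definition used downstream (the SD of
HU in an air ROI) but deliberately omits CT noise texture, streaks,
beam hardening, scatter and metal artifacts. Consequently the tests
demonstrate correctness of the *measurement chain* (a known injected SD is
recovered; known angles survive projection), not the realism of any
particular scanner's noise. Air-noise SD per protocol is a free parameter;
the defaults (standard-like 15 HU, ULD-like 20 HU) encode the ordinal fact
that the tin-filtered ULD protocol is noisier, with plausible magnitudes
for bone-kernel pelvic reconstructions.

## Projection

HU convert to linear attenuation by `mu = mu_water (1 + HU/1000)`, clamped
at zero, with `mu_water = 0.19/cm` by default (monoenergetic model; the
value is configurable because a tin-filtered 140 kV spectrum has no single
canonical effective energy). Each detector pixel gets one ray from the
point source through the pixel center (cone) or along the beam direction
(parallel). The integral is midpoint quadrature over the segment clipped
to the volume's bounding box, sampling mu by trilinear interpolation at a
uniform step of half the smallest voxel dimension by default. Halving the
step changes smooth-phantom integrals by well under 0.5%; slab and
sphere-chord closed forms agree to ≈1%. No detector-area integration,
scatter, blur or energy weighting is modeled. Default geometry: film-focus
distance sdd = 1200 mm, source-to-target distance sod = 1000 mm
(patient-to-detector standoff is not standardized; configurable), detector
430×430 mm at 1 mm pitch. The 15° internal leg rotation used in pelvic
radiography is treated as a property of the input volume, not a resampling
step. Display mapping is a linear window to 16-bit with more attenuation
rendered brighter (radiographic convention), inversion optional.

## Metrics, dose, angles

ROI statistics use the sample SD (n−1). Image noise is the SD of HU in an
air ROI anterior to the body wall (≈3×10⁴ voxels in the default phantom,
so the SD estimator's sampling error is ≈0.4%). Quality indices are
computed per volume and only then summarized (median, Q1, Q3 by linear
interpolation between order statistics) — ratios are never formed from
cohort medians, because medians do not commute with ratios. SNR uses
bone mean over air SD; CNR uses the bone-muscle contrast over bone SD;
FOM = CNR²/effective dose is the dose-efficiency measure, exactly inverse-
linear in dose.

Effective dose: `0.013 mSv/mGy·cm × DLP` (adult pelvis CT) and
`0.00029 mSv/mGy·cm² × DAP` (pelvic radiograph). Report rounding is half
away from zero (2 decimals for mSv, 1 for percent/fold); percent/fold
reductions are computed from the rounded doses, the convention that
reproduces conventional printed tables self-consistently.

CE angle: angle at the circle-fitted femoral head center between image
vertical and the ray to the lateral rim, signed positive lateral-superior.
Sharp angle: angle at the teardrop between the inter-teardrop horizontal
and the line to the rim, in [0°, 90°]. The head center comes from a Kåsa
algebraic least-squares circle fit (closed form, exact on noiseless
circles; geometric refinement is unnecessary at sub-millimetre landmark
noise). Landmarks are supplied (from phantom ground truth or JSON); there
is no automatic landmark detection on images.

## Agreement statistics

Bland-Altman uses the 1.96 normal multiplier, so the limit range is
3.92×SD of the paired differences. Cohen's κ is unweighted; when several
pathology categories are pooled, categories are namespaced per task before
concatenation. ICC is the two-way random-effects, absolute-agreement,
single-measure form ICC(2,1) — chosen because method comparison must
penalize systematic offsets. Wilcoxon signed-rank drops zero differences,
uses the exact sign-permutation distribution for n ≤ 25 and a tie- and
continuity-corrected normal approximation above; all-zero differences give
p = 1 by convention. McNemar is the exact binomial test on discordant
counts with p = 1 when there are none. Confidence intervals for κ/ICC and
binomial prevalence CIs are out of scope.

## Cohort pipeline

Each synthetic subject draws hip geometry (CE angle uniform on 16–40°,
Sharp on 33–46°, head radius 22–26 mm) and per-protocol DLP (log-normal
around the protocol median: 177.85 mGy·cm standard, 28.85 ULD — a ≈6-fold
dose gap). Both protocols share the anatomy; they differ in tissue HU
anchors and noise. Angle "readings" on the cone-beam VR and on the
parallel reference projection add Gaussian landmark-placement jitter
(0.75 mm SD) on both images to emulate manual caliper placement; without
it the two in-plane measurements agree to floating-point precision and
agreement statistics degenerate. Pathology calls (dysplasia: CE < 25°)
derive from jitter-free parallel measurements per protocol, so protocol
concordance is exact by design and McNemar's p = 1. All randomness flows
from one root `SeedSequence`; a fixed seed reproduces every CSV/JSON
output byte-for-byte. The default problem sizes (12 subjects, 2 mm
voxels, 220² detector at 2 mm pitch for pipeline projections) keep a full
run in tens of seconds on one core while leaving ≥10⁴ air voxels for noise
recovery.

Degenerate inputs are handled explicitly: zero noise SD makes SNR/CNR
undefined (division errors are caught per volume and reported as NA; the
run completes), zero-length rays, sources inside the volume, collinear
circle fits, ROIs outside the volume and non-binary McNemar input all
raise typed errors.

## Known limitations

The phantom is geometric, not anatomical: no realistic pelvis mesh,
sourcil, joint space or soft-tissue heterogeneity, so reader-style
qualitative image grading is out of scope. The projector is
monoenergetic without scatter or detector physics, so absolute VR
intensities are not calibrated to any scanner — only geometry and relative
attenuation are meaningful. Angle validity is demonstrated for landmarks
in the detector-parallel plane; out-of-plane anatomy incurs the usual
projective distortion that positioning controls in practice.
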