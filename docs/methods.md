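# Methods

This note documents the models, numerical choices and limitations of
`reachmap`. Millimetres and degrees throughout; wheel-axis frame
(origin at the rear-wheel axis, y up, x positive toward the rear, so
forward reach has negative x).

## Kinematic simulation

The synthetic cohort emulates quasi-static reach trials of a seated
person. The body is a planar three-segment chain — trunk TR, arm AR,
forearm FA — anchored at a hip pivot on the seat. Defaults describe a
50th-percentile adult male: FA = 441 mm, AR = 312 mm (so AR + FA =
753 mm, the arm+forearm reach found in anthropometric atlases), TR =
540 mm, hip pivot (50, 190), backrest tilt 4° from vertical. Joint
mobility per area:

* **AoC** — elbow only, flexion 0–150°, arm parallel to the trunk;
* **AoA** — shoulder −30° to 170° relative to the trunk, elbow 0–150°;
* **AoR** — additionally hip (trunk) flexion 0–40° forward of the
  backrest posture. Trunk participation differs strongly between real
  users, so the hip range is a configuration knob, not a constant.
* **AoP** — not quasi-static: the hand follows push-recovery arcs on
  the handrim, modelled as an annular band `handrim_radius ±
  band_width` (defaults 290 ± 35 mm) over an arc from −20° to 75°
  around the top of the wheel, positive toward the front.

Joint angles are sampled *quasi-uniformly* over the mobilised joint
box: half of the samples on a regular grid that includes the box
corners (so extreme postures are always represented), half uniformly at
random. Only the boundary of the cloud is consumed downstream, so
density inhomogeneity inside the box is harmless. Marker/detection
jitter is isotropic Gaussian noise, default sd 5 mm. Subject segment
lengths vary log-normally around the 50th-percentile targets with
coefficient of variation 0.02, matching the few-percent height spread
of a percentile-matched cohort. All randomness flows from a single
`numpy.random.SeedSequence`, so cohorts are byte-reproducible.

What the simulator does **not** emulate: joint-limit coupling (e.g.
scapular rhythm), hand orientation, segment-length/height correlation,
out-of-plane motion, occlusion dropouts, or trajectory autocorrelation
within a trial. Passing tests on synthetic data therefore validate the
*geometry and statistics pipeline*, not the physiology of any measured
cohort.

## Boundary extraction

Per trial the cloud is reduced to a closed loop with the alpha shape:
Delaunay triangulation (scipy), removal of every triangle whose
circumradius exceeds a threshold, outer boundary of the largest
remaining edge-connected component. The dimensionless `alpha` is the
*inverse* threshold in units of the cloud's RMS radius about its
centroid (`r_thresh = rms_radius / alpha`), so alpha → 0 keeps all
triangles and returns the convex hull, and the admissible band
0.7–0.9 is meaningful across cloud scales. A raw mm threshold
(`radius_override`) bypasses the normalisation. Automatic selection
maps the median nearest-neighbour spacing (in RMS-radius units)
monotonically onto the band: sparser clouds get the more permissive
end. Alpha is chosen per trial; a global override is available.

Robustness rules: if the boundary is non-simple, the complex is
fragmented, or the loop encloses < 95% of the points, the radius
threshold is relaxed in 10% steps (max 10). Interior rings (holes, as
in the annular AoP cloud) are discarded — areas are filled outlines.
Degenerate clouds (collinear, < 3 distinct points) and exhausted
relaxation raise errors rather than returning junk.

Canonical form: counter-clockwise orientation, start vertex at maximum
x (ties: maximum y) — a deterministic anchor for cross-trial
correspondence. Resampling places 100 points at equal arc-length steps
along the closed polyline, point 0 at the canonical start; it is
idempotent (re-resampling moves vertices < 1e-6 mm) and preserves the
perimeter to well under 1% for loops with ≥ 20 source vertices.

## Averaging and confidence statistics

The reference loop is the one of median perimeter rank (ties: lower
subject/trial label). For each reference index i the nearest vertex of
every other loop is matched to it; the coordinate-wise mean of the
matched set is the averaged contour point `P̄_i`, and per-coordinate
half-widths are Student-t confidence intervals of the mean,
`t_{1-p/2, n-1}·s/√n`, at level 1 − p (default p = 0.05, i.e. 95%,
the standard choice at n = 30). Nearest-vertex matching is
deterministic and order-free, and reduces to index pairing for loops
that differ by less than the vertex spacing; for large rigid offsets
between loops it is biased toward the reference loop (measured mean
shift ≈ −d/2 for two circles offset ±d = 40% of the radius), which is
tolerable for the tight loop families the pipeline averages but makes
the mean contour a *correspondence-dependent* statistic, not a Fréchet
mean. Mutual-nearest matching was considered and rejected as it leaves
unmatched indices.

Control points are the extreme mean points (max x, min x, max y,
min y; labels A1–A4 in that order, ties to the first index). Their
uncertainty summary is the confidence diagonal Δ = 2·√(δx² + δy²) —
the distance between opposite corners of the (x ± δx, y ± δy) box.
Reported mm values round half away from zero. Area size is the control
-point bounding box (length = x-extent, height = y-extent).

## Map composition

The wheelchair is parametrised by levels FDL = −30, FUL = 170, ARL =
420, SL = 190, SH = 730 ± 30, backrest plane x = 80, and the wheel
disc of radius 300 about the origin (defaults; all overridable, with
ordering validated). The wheel obstacle is the *full disc* — the whole
swept region of the spinning wheel — discretized at 1° (360 vertices);
boolean operations snap vertices at 1e-6 mm for robustness (shapely).

Because the raw envelopes are nested, the map carves three disjoint
bands by priority: band(AoC) = AoC − WB − AoP; band(AoA) = AoA − AoC −
WB − AoP; band(AoR) = AoR − AoA − AoC − WB − AoP; everything clipped
to y ≥ FDL. Nothing is clipped above: the armrest strip (FUL–ARL) is
annotated on overlapping zones as removable-support territory, not cut
away, since armrests are occasionally disassembled in use. If a
difference fragments a band, the largest part is kept and a warning
emitted. Seat position (SL, SBV) can be overridden freely; the
designated areas must then be shifted by the same offset, and a rigid
`translate()` of the whole geometry is provided for equivariance
checks.

Export decimates each zone ring by Douglas–Peucker simplification,
binary-searching the tolerance for the smallest one that meets the
vertex budget while keeping the polygon area within 2%; if budget and
area bound conflict, area fidelity wins.

The anthropometric check reports |min x| of the AoA envelope (to be
compared with the arm+forearm length) and |min x| of the AoC envelope
plus the backrest offset SBV (to be compared with the forearm length):
with the arm hanging along the backrest plane, the elbow pivot sits at
x ≈ SBV, so the offset must be added back before comparing with a limb
length.

## Reference tables

The package bundles, as validation fixtures, the control-point table,
composed-map point list and summary dimensions measured on a
ten-subject 50th-percentile cohort in a cross-frame semi-active
wheelchair (N = 30 trials per area, p = 0.05). The AoA block's printed
Δ column is not reproducible from its own half-widths under the
confidence-diagonal identity; those cells are stored as missing and
excluded from consistency checks (the AoA coordinates themselves are
consistent with the published 1009 × 553 mm dimensions). `reachmap
check-tables` recomputes every checkable quantity and reports
pass/fail.

## Problem sizes and determinism

The test suite and the acceptance script use 10 subjects × 3 trials ×
4 areas with 400–600 samples per trial — the cohort size the analysis
is designed around; a full run takes a few seconds. Synthetic
parameter-recovery checks use a zero-noise, zero-spread cohort so the
analytic workspace extents (elbow_x − FA for AoC, shoulder_x − (AR+FA)
for AoA) are exact targets; the pipeline recovers them to ≈ 0.5%,
dominated by the 100-point resampling sagitta. Sample-hull containment
checks use a 10 mm buffer: finite sampling of a curved workspace
boundary leaves chord-sagitta gaps of up to ~1% of the 753 mm reach
radius at the sample sizes used.

## Known limitations

* Sagittal plane only; frontal/rear-plane maps are out of scope.
* The alpha band 0.7–0.9 is calibrated for cloud densities of a few
  hundred to a few thousand points; very sparse trials fall back to
  the relaxation path and may return near-convex outlines.
* The mean contour depends on the chosen correspondence (see above);
  no Procrustes alignment or functional-data averaging is attempted.
* Geometry defaults describe a cross-frame semi-active wheelchair;
  fixed-frame active chairs need level overrides, and only rigid
  translations of the seat/backrest are modelled.
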