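# Methods

## Data model

A *structure* is the 3D region delineated on CT: an ordered stack of
closed planar polygons ("contours"), one or more per axial slice, on a
regular slice grid. Internal units are cm throughout (volumes cm³),
matching the scale on which the comparison statistics are reported. Axes
follow the radiological convention — x left–right, y anterior–posterior,
z superior–inferior with larger z more superior — so "the observer's
contour is on a more superior slice" is literally a positive z
difference.

Contours are normalized on construction: an explicit closing repeat of
the first vertex and consecutive duplicates are dropped, orientation is
forced counter-clockwise (positive shoelace area), and self-intersecting
or collinear input is rejected as an error rather than repaired —
malformed clinical contour data should fail loudly at ingest.
Normalization is idempotent. Holes/annular polygons are not modelled
(none of the pelvic structures concerned are annular); multiple disjoint
polygons per slice are supported and their areas add, which is how
seminal-vesicle lobes coexist with the prostate on a slice.

Two contours belong to the same slice when their axial positions differ
by ≤ 0.01 cm. This tolerance is far below the thinnest clinical slice
spacing in scope (0.25 cm), so it can only merge genuinely identical
planes. Structures whose grids are offset by more than this are never
silently resampled: volume comparison across incompatible grids raises an
error, because the comparisons this package models are same-image,
same-grid comparisons.

## Volumes and overlap

Volume is a slab sum: per occupied slice, total polygon area × slice
thickness, with no end-cap tapering and no interpolation between slices —
the simplest model consistent with planar-contour storage. Its
discretization error is bounded empirically: a 2.0 × 1.5 × 1.8 cm
ellipsoid sliced at 0.3 cm reproduces the closed form $\tfrac43\pi abc$
within 0.5% (the test budget allows 3%), and the error decreases
monotonically as the thickness shrinks once the in-plane polygon
resolution is fine enough not to dominate (512-gon contours in the
convergence test; with 64-gons the −0.16% inscribed-polygon area deficit
becomes the floor).

Intersections and unions are computed per slice with a robust polygon
clipper (shapely/GEOS). Degenerate contact — shared edges, single shared
vertices — yields measure-zero components that are dropped; they
contribute nothing to volumes. Correctness of the clipper route is pinned
by an independent rasterization oracle: pixel-centre point-in-polygon
tests (even-odd rule, matplotlib's path implementation) on grids down to
0.005 cm. Clipped areas and mask areas agree within 1% over randomized
convex and star-shaped polygon pairs, and the inclusion–exclusion
identity $A(a)+A(b)=A(a\cup b)+A(a\cap b)$ holds to 1e−9 cm². Both routes
are kept because it is not knowable which representation (polygon or
voxel) produced any given published volume.

The scalar statistics are ratios of these volumes: percentage volume
difference ΔV, Dice similarity coefficient, and the intersection fraction
I (share of the observer's volume inside the reference). Multi-observer
aggregation uses the arithmetic mean and the sample SD (n−1), computed
from full-precision values and rounded only for display (volumes and ΔV
to 1 decimal, DSC and I to 2) — the convention of the published tables
this package reproduces. Observer exclusion (e.g. a gross volume outlier)
is explicit and recorded; note that in the reproduced tables the outlier
is included in the scalar footers and excluded only from the spatial
surface statistic, and the package follows whatever exclusion list the
caller provides per statistic.

## Axial extent differences

`z_extent_diffs` returns (z_sup,obs − z_sup,ref, z_inf,obs − z_inf,ref):
positive when the observer's terminal slice is more superior. An observer
extending a prostate apex 4 extra slices inferiorly at 0.3 cm therefore
scores dz_inf = −1.2 cm exactly; this sign convention is asserted in
tests because it is the easiest thing in the pipeline to get silently
wrong.

## Fiducial-based realignment

Planning-system import/export round trips can translate the coordinate
origin and invert axes — but, in the corruption model adopted here, never
rotate or scale. Each axis is therefore estimated independently: sign
s ∈ {+1, −1} and offset t minimising Σ(ref − (s·mov + t))², with
t = mean(ref − s·mov) for each candidate sign. At least two label-matched
fiducial pairs with per-axis spread are required. A residual RMS above
0.1 cm (a third of the benchmark 0.3 cm slice spacing) rejects the fit as
*ambiguous* rather than applying it: a large residual means the
discrepancy is not a pure translation/inversion (e.g. a rotation) and
silently "correcting" it would corrupt the data. With noiseless fiducials
the estimate inverts the corruption exactly; with 0.02 cm Gaussian
fiducial noise, signs are recovered exactly and offsets within 0.05 cm
across 100 seeded trials (the default fiducial spread per axis exceeds
10× that noise). Unlabeled fiducial sets are not matched combinatorially
by default; exhaustive assignment is deliberately left out of scope of
the estimator's contract.

## Surface disagreement maps

The map is sampled at the vertices of the reference structure's contours
— the available discretization of "each point comprising the structure".
For each vertex at slice z and each observer, the package takes the
minimum boundary distance to that observer's contours on slices within
±w·Δz (default w = 1: the slice and each adjacent slice); the map value
is the mean over observers that have any contour in the window, and the
vertex is flagged *undefined* (not zero) when none does. Two choices here
are genuinely underdetermined and are therefore explicit, switchable
assumptions:

* **min vs mean over the window** — the minimum is the default because it
  is the only choice under which an observer identical to the reference
  scores exactly 0 everywhere; `reduce="mean"` is available.
* **2D vs 3D distance** — distances are in-plane by default (the
  statistic is defined slice-wise); `distance_3d=True` adds the
  out-of-plane offset in quadrature.

Excluded observers are dropped before averaging. Exports write one row
per vertex with the value, contributing-observer count and defined flag
(undefined rows carry a −1 sentinel), plus the recorded global
colour-scale maximum so maps of several structures can share one scale.

## Synthetic cohort

The generator emulates a benchmarking exercise, not patient anatomy per
se. Defaults are fixed at the study conditions: 0.3 cm slice grid; a
prostate ellipsoid of semi-axes 2.0 × 1.5 × 1.8 cm (≈ 23 cm³) merged with
two seminal-vesicle lobes into a high-risk-style CTV; a superellipsoid
bladder (≈ 165 cm³) superior to and touching the prostate; a curving
rectal tube (≈ 53 cm³) posterior to it; four skin fiducials at the
lateral/anterior/posterior body surface (patient separations 40.6 cm
left–right, 25.1 cm anterior–posterior), at distinct axial positions so
every axis is constrained. The default cohort has 11 observers (the
high-risk plan count; 7 suits an intermediate-risk-style run).

Observer variation has four axes, matching the documented disagreement
modes: (1) smooth radial noise — a low-order Fourier series (4 harmonics)
in the vertex index applied along outward normals, RMS 0.15 cm by
default; correlated noise keeps contours anatomically smooth, where
i.i.d. per-vertex noise would produce jagged self-intersecting polygons
and test nothing realistic; (2) a global scale factor (log-normal, ~6%)
for systematic over/under-contouring; (3) extra tapered copies of the
apex contour extending the CTV 3–5 slices inferiorly (the ~1.2 cm apex
over-extension pattern); (4) a ±2-slice shift of the rectal superior
extent. Noise RMS is capped at a third of a contour's smallest centroid
distance so near-degenerate pole slices cannot be turned inside out, and
a draw that pinches a narrow neck (where the seminal-vesicle lobes join
the prostate) into a self-crossing is repaired by keeping the largest
simple component of its valid decomposition; only if repair fails across
ten draws does generation abort. Everything is deterministic per seed.

The auto-segmenter surrogate is purely deterministic: each structure
scaled in 3D about its own centroid (default CTV scale 0.78, i.e. the
automatic volume is ≈ 0.78³ ≈ 0.47 of the reference — the atlas
small-volume bias; bladder/rectum nearly unbiased) plus an optional
systematic shift, resampled onto the slice grid by nearest-slice lookup.
Coordinate scrambling applies a random sign/offset transform per exported
set and records the truth in a manifest separate from the data, so
recovery is testable without being readable from the corrupted set.

What the generator does **not** emulate: CT image content and
contrast-driven observer behaviour, real prostate shape statistics,
inter-observer correlation structure, and rotational export errors.
Passing tests on this cohort therefore demonstrate the pipeline's
bookkeeping, geometry and statistics — not that the default disagreement
magnitudes match any real observer population, although they are chosen
to land in the published DSC ranges (bladder ≈ 0.9 ≫ CTV ≈ 0.6, with the
bladder > CTV ordering guaranteed by the surface-to-volume effect under
equal noise).

## Numerical conventions

* Shoelace areas on open CCW loops; positivity enforced at normalization.
* Clipper outputs drop components below 1e−12 cm².
* Raster membership at pixel centres, even-odd rule; raster grids store a
  corner origin with centres at half-pixel offsets.
* Printed-table reproduction: derived cells recomputed from printed
  (rounded) volumes match print at 2 decimals for 97 of 102 overlap
  cells; the five exceptions differ by exactly one unit in the last
  printed digit and are attributable to input rounding (half-ulp shifts
  of the inputs recover them). Footer means/SDs reproduce likewise, with
  three one-ulp exceptions where the published footers were evidently
  computed from unrounded values.
* Report rounding: volumes/ΔV 1 d.p., DSC/I 2 d.p.; means computed at
  full precision before rounding.

## Problem sizes used in the test suite

Unit and acceptance tests run the cohort at 24–48 vertices per contour
and 2–11 observers, the raster oracle at 0.005–0.01 cm pixels over ~3 cm
polygons, the noise-calibration sweep at 5 noise levels × 20 replicates,
and alignment recovery at 100 seeded trials — sizes chosen so the whole
suite completes in well under a minute while each assertion still has
the statistical room its tolerance requires.

## Known limitations

* Volumes ignore partial-slice end caps; absolute volumes of thin
  structures carry O(Δz) error even though comparisons between structures
  on the same grid are consistent.
* The surface map is vertex-sampled; disagreement concentrated between
  vertices of a coarse contour can be under-resolved.
* The alignment model cannot represent rotations; it refuses (by design)
  rather than approximates.
* The DICOM-RT reader ingests CLOSED_PLANAR geometry only and is not a
  compliance-grade implementation.
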