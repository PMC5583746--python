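# Methods

## Object morphometry

Each segmented object is reduced to the geometry the filters consume.
Connected components are 8-connected; contours come from subpixel
marching-squares on the padded mask (pixel-corner convention, 0-based
(row, col) coordinates).

**Centerline.**  The mask is skeletonized; the centerline is the longest
geodesic path through the skeleton's adjacency graph (Euclidean edge
weights, double-Dijkstra endpoints), which prunes side branches
implicitly.  The path is lightly smoothed (5-point moving average) and
prolonged along its end directions until it leaves the mask, so the arc
length `L(c)` spans telomere to telomere.  A point-like skeleton (discs,
round debris) yields a zero-length centerline and the object is flagged
unprocessable.

**Width profile.**  At 41 evenly spaced centerline points the local
normal is intersected with the mask ("traceline"); width is the chord
length between the two exits.  The mask is sampled with bilinear
interpolation on a zero-padded float raster so boundaries resolve to
~0.1 px; on rendered constant-width bars of 6/10/16 px the profile
statistics land within 2 % of truth.  Samples whose center misses the
mask or whose traceline fails to close are dropped; losing more than
half flags the object unprocessable.  Range normalization to [0, 1] maps
an exactly constant profile to all zeros.

**Centromere candidates.**  Local minima of the 5-sample moving-average
smoothed profile qualify as candidates when their constriction depth
`1 − w/shoulder` reaches `min_depth` (default 0.2), with the shoulder
being the lower of the maximum smoothed widths on either side.  Depth is
evaluated at the raw-profile argmin within the smoothing half-window —
the smoothed value alone underestimates the depth of short chromosomes,
whose constriction spans only a few samples.  The *reported* width at a
candidate is the 3-sample local mean around that argmin: a bare minimum
statistic is biased low by pixel jitter, which matters because the
centromere-width filter ratio sits near its threshold for true
dicentrics.  Candidates closer than `min_separation` (default 0.15 arc
fraction) to a deeper one are suppressed; ranking is by descending
depth.  The defaults were chosen so that the generator's monocentric and
dicentric populations are recovered; both are configurable.

**Geometry.**  The minimum-area bounding rectangle comes from the
rotated-rectangle hull of the contour (shapely).  Contour halves split
the closed contour at the vertices nearest the centerline endpoints.
Intercandidate arcs take the four contour points where the top two
candidates' tracelines exit, partition the contour there, and keep the
two lateral arcs that join one candidate to the other (the two "cap"
arcs between a single candidate's own endpoints are excluded).

**MC/DC heuristic.**  Two or more qualifying candidates → DC; exactly
one → MC; a high-solidity object (> 0.95, contour-polygon solidity) that
is flat (profile max/mean < 1.1 over the central 70 % of the profile —
the trim prevents natural end tapering from defeating the test on
ellipses) or has no candidates at all → non-chromosome; anything else →
unprocessable.  This rule-based call replaces trained centromere/DC
classifiers by design and is pluggable: labels imported from CSV carry
`label_source="external"` and are never overwritten.  On clean synthetic
cells the heuristic recovers ≥ 99 % of object labels and ~96 % of true
dicentrics.

## False-positive filters

Filters i–v normalize a candidate's area and width statistics by the
within-image median over all objects with measurable width profiles,
candidate included; vi–viii are pure shape ratios.  Verdicts use strict
`<` against the thresholds, combined by inclusive disjunction over the
enabled subset; an unevaluable score (e.g. intercandidate symmetry with
fewer than two candidates) never removes a candidate.  Threshold
derivation takes the minimum score among training true positives and
floors it to two significant digits — flooring is the unique rounding
that preserves retention of every training TP.  Forward selection
greedily adds the filter with the largest marginal FP removal (ties to
the lower filter id) until no filter adds removals; because removal is
monotone in the subset, the greedy endpoint equals the exhaustive-subset
optimum.

## Image selection

MW/CD/WD means run over classified chromosomes only; unprocessable and
non-chromosomal objects still count toward the object totals.
`seg_obj_count` counts objects that passed width profiling, and the
classified ratio divides classified chromosomes by that count.  Sample
statistics use the sample standard deviation (ddof = 1); a feature whose
SD is numerically zero cannot flag outliers.  The Combined Z Score signs
follow the quality semantics: high LW/CD and low FD are bad, count
deviations in either direction are bad, high classified ratio is good.
Rankings break ties by image id for determinism.

Group binning classifies each retained object's share of total retained
area with the 2.9 %/2 % thresholds; boundary values fall to the smaller
group (half-open intervals).  The reference fractions are computed from
GRCh38 primary-assembly chromosome lengths over the diploid complement
(two copies of each autosome plus XX or XY) — the normalization under
which chromosome 5 sits just above 2.9 % and chromosome 13 just below
2 %, making the ideal vectors exactly (10, 16, 20) and (10, 15, 21).
With `sex="auto"` (default, since sample sex is usually unknown) the
smaller of the two distances is used.  Weight optimization grid-searches
integer weight vectors, scoring each by the squared residuals between
re-estimated and physical calibration doses after a linear-quadratic
self-fit.

## Dosimetry

The calibration fit is bounded linear least squares on the design
`[1, D, D²]` with `c0, β ≥ 0` (standard practice for background and
quadratic coefficients; α is left free).  Weighting is unweighted by
default with optional 1/variance (Poisson) weighting.  Dose inversion
takes the nonnegative quadratic root, falling back to the linear solve
when `β < 1e−12`; responses below the fitted background report 0 Gy
(`below_background`), responses above the curve at the maximum
calibrated dose report that maximum (`out_of_bounds_high`) — a lower
bound, not an estimate.  Doses are reported continuously; no rounding is
applied internally.

The Poisson quality test uses the Pearson chi-square statistic over the
unmerged count bins 0..max plus one right-tail bin (so expectations sum
to the cell count), with the rate estimated by the sample mean.  Two
p-values are reported.  The asymptotic p uses `dof = bins − 2` (one for
the estimated rate, floored at 1).  Because the unmerged tail bins have
near-zero expectation, the asymptotic reference is anti-conservative
(measured 2–4 % type-I error at α = 0.005 in simulation), so verdicts
instead use a parametric-bootstrap p-value from 1999 seeded Poisson
resamples of the same statistic, which is calibrated (~0.3 % type-I at
α = 0.005) while retaining full power against zero-inflated
contamination.  Samples with no dicentrics return a sentinel, not a
p-value.

## Synthetic generator

The generator emulates the morphology that drives both filter families,
not photorealistic microscopy: no staining texture, banding, harlequin
effects or intensity gradients, and objects never touch (placement is
rejection-sampled with a 3 px dilation margin).  Consequences: passing
tests demonstrate that the measurement and decision logic behaves as
specified on shapes with known truth; they do not certify segmentation
robustness on real Giemsa images, where touching chromosomes and texture
are the dominant difficulty and sit outside this package (upstream
segmentation is out of scope here).

Chromosomes are tubes stamped along arc-length-parameterized quadratic
Bézier spines (curvature = sagitta fraction, default ≈ 0.05–0.2), width
8 px, with Gaussian constrictions (σ = 0.05 arc fraction) at centromere
positions drawn from U(0.25, 0.5) of either end and depths from
U(0.3, 0.5).  Spine lengths invert the rasterization model
(`area = Lw + π(w/2)² − dips`) so rendered areas are proportional to the
reference-genome fractions — group binning compares relative areas
against percent-level thresholds, so proportionality must hold in the
rendered raster, not just nominally.  Dicentrics are full fusions of two
chromosomes, partners drawn with probability proportional to length
(breakage scales with DNA content), each contributing one centromere
whose depth follows the same distribution as monocentrics' — the
constriction is the same biological structure — plus one reciprocal
acentric fragment.  SCS renders as paired chromatids at 40 % width,
fragments as truncated tubes, overlaps as unioned crossing tubes, nuclei
as smooth ellipses, debris as small disc unions.  Per-cell DC counts are
Poisson with the linear-quadratic mean; the default background is the
conventional 1 DC per 1000 cells (c0 = 0.001).  All randomness flows
through one explicit seeded generator; identical spec and seed reproduce
byte-identical output.

## Problem sizes in the test suite

The suite exercises the pipeline at desk scale: candidate pools of 40
pseudo-images (200 true dicentrics, 400 false positives), dose-recovery
simulations of 100 replicates at 500 cells per dose, 1000-replicate
type-I calibration of the Poisson test, and end-to-end runs of a few
cells per sample on 600×800 canvases.  These sizes were chosen so each
property is measured with meaningful statistics while the full suite
runs in minutes; the defaults in the library itself (1040×1392 canvas,
250-image selection, 500-cell samples) reflect realistic practice.

## Known limitations

* The rule-based MC/DC call is deliberately simple; smooth round debris
  with incidental width minima can classify as DC.  That mirrors the
  false positives the FP filters exist to remove, but means the heuristic
  should not be used as a detector outside this curation context.
* The intercandidate symmetry filter rarely fires on the synthetic FP
  classes (most lack two ranked candidates), so bulk FP removal here is
  carried by the area and width filters; on real SCS data the symmetry
  filter is reported to be the strongest discriminator.
* Weight optimization's residual objective is weakly identified when
  image quality is homogeneous — all weight vectors tie, which the tests
  assert explicitly.
* The Poisson bootstrap p-value has a granularity of 1/2000 at the
  default simulation count; verdicts at α = 0.005 are meaningful, far
  smaller printed p-values are not.
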