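# Methods

`kelpmorph` re-implements, as a tested pipeline, the quantitative analysis of
early *Saccharina latissima* (sugar kelp) embryogenesis from manually
segmented time-lapse microscopy: per-cell and per-blade morphometry, lineage
tracking with division-orientation classification, growth-rate estimation and
group statistics. Because the original segmented image data are not
programmatically available, the package also contains a first-class synthetic
embryo simulator embodying the basal-inhibition / apical-growth-gradient
model of early kelp development. Every stage of the pipeline can therefore be
validated against simulator ground truth.

## The growth and division model

The early embryo is modelled as a monolayer stack of polygonal cells along a
single apico-basal axis. Three rules drive development:

1. **Positional growth gradient.** The fractional elongation rate per day is
   linear in relative axis position: `g(x) = g_b + (g_a − g_b)·x`, with `x=0`
   at the basal pole and `x=1` at the apical pole. A cell elongates each day
   by `1 + g(x_mid)·ε`, where `x_mid` is its span midpoint and `ε` a
   lognormal multiplier with coefficient of variation `noise_growth_cv`
   (`ε = 1` when the CV is 0). Because the gradient integrates over any
   partition of the axis to the same mean, total blade area always grows at
   `(g_b + g_a)/2` per day — removing part of the embryo leaves the
   remainder's area increase rate unchanged. This is the model's expression
   of cell-autonomous growth: the observation behind it is that ablated
   regions are never compensated by faster growth elsewhere, and that the
   growth kinetics of the remainder match intact controls. (A rank-based
   variant, interpolating `g` over living cell indices, was considered and
   rejected: it makes the post-ablation remainder systematically ~15% slower
   than controls, contradicting the observed unchanged kinetics.)

2. **Area-threshold division.** A cell divides when its area reaches
   `division_area_factor` (default 2.0) times its birth area. Divisions are
   processed apical-most first within a day; daughters halve the parent
   (height for transverse, width for longitudinal divisions) and restart the
   area clock, so division is area-conserving and no cell divides twice in
   one day.

3. **Basal inhibition of longitudinal division with finite range.** A
   dividing cell divides longitudinally (new wall parallel to the growth
   axis) if and only if the original basal cell's lineage is dead, or more
   than `inhibition_range_R` living cells lie basal to it. Otherwise it
   divides transversally. The inhibition is binary with a sharp range
   (default R = 6 ranks); the underlying biology suggests a graded signal,
   but no functional form is available, and the minimal binary rule
   reproduces the intact onset.

With the defaults — zygote 35 × 10 µm, `g_a = 0.9/day`, `g_b = 0.45/day`,
area factor 2.0, R = 6 — the intact embryo divides 1→2 on day 2, 2→4 on day
4, 4→8 on day 6, and the apical-most cell of the 8-cell stack performs the
first longitudinal division on day 8 with 8 living cells present. These
defaults are calibration choices that reproduce the observed 8-cell onset;
they are not measured rates. Basal ablation removes the inhibition source,
so the first post-ablation division is longitudinal regardless of stage;
apical ablation leaves the inhibition intact and the basal remainder keeps
dividing transversally until it outgrows the range.

**Stage convention.** The "stage of the first longitudinal division" is the
number of *living* cells immediately before that division; ablation remnants
are excluded. Simultaneous divisions within one day are ordered apical-most
parent first, mirroring the simulator's processing order; this convention
shifts reported stages by ±1–2, so it is applied identically in simulator
ground truth and pipeline output.

**Ablation.** An ablation plan fires at the first daily snapshot whose
living-cell count reaches the planned stage (`≥`, not `=`: growth noise can
desynchronise divisions so the count jumps past the stage within a day). The
targeted end cell becomes an inert remnant: its outline is kept, uniformly
shrunk by `remnant_fraction` (default 0.6) to mimic loss of cell contents,
rendered grey in segmentations, and excluded from living counts, growth and
division forever after.

## Segmentation documents

Series are exchanged as Inkscape-compatible SVG: one group per daily time
point labelled `d00`, `d01`, …; one closed path per cell carrying the cell
id; grey fill (`#808080`, palette configurable) marks ablated remnants;
`class="excluded"` marks cells removed from analysis (the rhizoid-forming
sub-basal cell after basal ablation). Supported path commands are M/L/H/V/C
and their relative forms; cubic Beziers are flattened at a configurable
chord tolerance (default 0.1 µm). Coordinates are multiplied by a
µm-per-drawing-unit calibration on read; vertex winding is normalised
counter-clockwise so downstream geometry is independent of how the editor
saved the outline. Which end of the blade axis is basal is declared in
document metadata (`basal_end`), never inferred from image coordinates.

## Morphometry

Per cell: surface area by the shoelace formula; convex hull
(`scipy.spatial.ConvexHull`, reduced to a collinear-free CCW ring); minimal
bounding rectangle by the edge-aligned candidate search (the minimum-area
enclosing rectangle of a convex polygon has a side collinear with a hull
edge); length-to-width ratio (LWR) = MBR length / width ≥ 1. Ties in MBR
area are broken towards the smaller orientation angle, and orientations are
reported modulo 180°.

Per blade (snapshot): blade area is literally the sum of living cells'
areas. The main axis is the principal axis of the second-order area moments
of the union of living cells (computed from exact polygon moment integrals;
overlapping outlines do not double count in the moments). Blade length and
width are the extents of the living cells projected on the main and
secondary axes. The original analysis cites an external method for the blade
axes that is not recoverable from the text; the moment-based principal axis
is this package's documented substitute — deterministic, rigid-invariant,
and identical to the MBR axis for elongated stacks.

## Lineage tracking

Cells are matched between consecutive snapshots in *mass coordinates*: in
the snapshot's principal-axis frame, a point's axis coordinate becomes the
fraction of cell mass basal to it, and its transverse coordinate is
normalised by blade width. Two mass weightings are complementary:

- **area CDF** — each cell's polygon area spread over its axis span.
  Division conserves area, so daughters tile their parent's slot exactly;
  insensitive to simultaneous divisions, but an ablation remnant's shrunken
  outline underweights its end of the axis.
- **rank CDF** — one unit per cell. Insensitive to differential growth and
  remnant shrinkage; exact when all cells of a snapshot divide in the same
  interval.

A candidate parent–child score is the intersection-over-union of the two
transformed polygons, the better of the two weightings. Because cells never
pass one another along the growth axis, lineage is order-preserving: in
stack order each parent either continues as one child or divides into two
consecutive children. The maximal-score assignment under that constraint is
found by dynamic programming (transitions: skip parent, skip child, match
one, match two consecutive; skipping carries a 0.3 penalty since cells
neither appear nor vanish — remnants stay visible). The IoU floor (default
0.1) only rejects gross outliers; the order constraint does the
disambiguation. A greedy IoU assignment after rigid or similarity alignment
— the obvious first design — was measured to be unworkable here: day-to-day
area growth of up to two-fold leaves true parent–daughter IoU as low as
0.08 while spurious neighbour overlaps reach 0.46.

A parent matched to two children is a division if the children jointly cover
≥ 60% of the parent's slot. The new wall is the chord spanning the longest
shared-boundary run between the daughters (vertices of one within 0.5 µm of
the other's boundary); when one daughter is a shrunken remnant and no longer
touches its sister, the wall falls back to the perpendicular bisector of the
centroid segment. Orientation: the acute angle φ between the wall chord and
the blade main axis classifies the division — φ < 45° longitudinal,
φ ≥ 45° transverse. The tie at exactly 45° goes to transverse because early
embryos divide transversally by default. One-to-many matches beyond two,
unmatched cells and low-coverage pairs are reported as anomalies, never
silently dropped.

On noise-free simulated fixtures of all nine experimental conditions the
tracker reproduces simulator ground truth — parents, daughters, orientation
and stage counts — exactly; at the default observation noise (growth CV 0.1,
vertex jitter 0.2 µm) orientation agreement of recovered events exceeds 95%,
though roughly a fifth of events go undetected, mostly when jitter blurs a
fresh, thin daughter pair.

## Growth statistics

Per-embryo increase rates are ordinary least-squares slopes of measure
against day; multiplicative measures (areas, cell counts) are
natural-log-transformed first. Rate comparisons between an ablated group and
its stage-matched control fit slopes from the ablation day onwards — the
level drop at ablation is not growth and would otherwise contaminate the
slope. Day-6 endpoint comparisons use one-tailed Mann–Whitney U-tests
(treated < control) for size-like measures, rates use two-tailed tests; cell
LWR uses a pooled two-sample Student t-test. The Mann–Whitney p-value is
exact (full permutation distribution) for tie-free samples with
min(n) ≤ 8 and a tie-corrected normal approximation with optional
continuity correction otherwise; both routes are scipy's, cross-checked in
the tests against an independent exhaustive-enumeration oracle. Shape ratios
are summarised by geometric mean with a multiplicative SD factor
(`exp(mean ± sd of ln values)`). Significance is p < α with α = 0.05; no
multiple-testing correction is applied across the pairwise comparisons —
deliberately matching the original analysis, and a known caveat.

## What the simulator does and does not emulate

It emulates: daily snapshots of a monolayer stack; asynchronous transverse
divisions and the basally-inhibited onset of longitudinal ones; apical-bias
growth; ablation remnants drawn grey; replicate-level growth-rate spread
(lognormal multiplier on both rates per embryo); per-cell growth noise; and
hand-segmentation error as Gaussian vertex jitter that preserves polygon
validity. It does not emulate: curved or pear-shaped outlines (cells are
rectangles), rhizoid outgrowth, two-dimensional lamina expansion beyond
width-splitting, cell death other than declared ablation, segmentation
topology errors (missing or merged cells), or image-registration drift
between days. Passing the closure tests therefore shows the pipeline is
correct on clean stack-like geometry with realistic noise levels — not that
it is robust to every pathology of real hand-segmented material.

Statistical oracle simulations draw per-embryo endpoint values lognormal
with log-SD 0.3, consistent with the multiplicative SD factors (~1.2–1.35)
reported for replicate spread in this system.

## Numerical choices and degenerate inputs

- Degenerate polygons (< 3 vertices, zero area, all-collinear point sets,
  zero-width rectangles) raise `ValueError` rather than returning NaN.
- MBR area ties break to the smaller angle; division-orientation ties (45°)
  break to transverse; same-day division order ties (side-by-side parents)
  break by secondary-axis position.
- The simulator is fully deterministic given its configuration when both
  noise terms are zero; all randomness flows from a single integer seed
  (growth noise and vertex jitter use separate streams derived from it).
- Problem sizes in the test-suite simulations (replicates per condition,
  repetition counts of the statistical oracles) are chosen so the whole
  suite completes in a couple of minutes while keeping binomial confidence
  intervals inside the asserted tolerances.

## Known limitations

- The lineage tracker's order-preserving assumption fails if transverse
  divisions occur simultaneously in side-by-side cells (children interleave
  in stack order). This cannot happen within the 9-day window of the
  modelled conditions but would matter for later development.
- Blade "width" never increases in the simulator (longitudinal splits halve
  cell width but nothing widens), so simulated LWR kinetics above the
  8-cell stage are not biologically meaningful.
- The reported medians and geometric means of the original study derive
  from its segmented microscopy data, which are not available; the package
  reproduces the study's *findings* as ordering and invariance properties,
  plus the intact 8-cell onset as a point value, not its raw-data tables.
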