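# Methods

`bundlekit` models flagellum-independent colony migration driven by growing,
folding filaments of pole-to-pole attached cells, and implements the image
statistics used to characterize the tightly aligned multicellular bundles that
produce those filaments. This note documents the model, the estimators, the
synthetic-data generators that stand in for microscopy, and the numerical and
design choices behind them.

## The filament model

A filament is a single chain of rod cells, represented by the ordered sequence
of its pole nodes in a fixed 1 x 1 arena; cell *i* spans nodes *i* and *i+1*.
The chain starts as a horizontal line of *N* cells of length *L0* at the bottom
edge (*y* = 0), with both filament ends pinned (attachment to the colony). Each
of *T* update steps picks one cell uniformly at random and attempts one event:

* **Elongation** (probability 1 − *p_turn*). The cell grows by a rate drawn
  from Uniform(0, *G*) toward a uniformly chosen neighbor: the shared pole is
  pushed outward along the focal cell's axis, and the neighbor's other pole is
  relocated to the intersection of the two circles that preserve the neighbor's
  and the next cell's lengths (of the two intersection points, the one closer
  to the pole's previous position is taken — a continuity tie-break). Growth
  toward a pinned filament end is a rejection.
* **Division** (automatic). After every elongation the focal length is checked
  against the maximum cell size *S*; a longer cell divides into two equally
  long daughters by inserting a node at its midpoint. No node moves, so
  division never changes the filament's shape or arc length.
* **Turning** (probability *p_turn*). A candidate re-orientation is built by
  rotating the pole shared with a uniformly chosen neighbor by an angle
  beta ~ Normal(0, *B*) about that neighbor's far pole, then restoring the
  focal cell's other junction by circle intersection so that every cell length
  is conserved. With alpha_1, alpha_2 the angles the focal cell makes with its
  left and right neighbors (pi = aligned; a missing junction at a pinned end
  contributes zero), the bending energy is

      V = (pi - alpha_1)^2 + (pi - alpha_2)^2 ,

  and a candidate with V_n < V_c is adopted with probability

      P = 1 - exp(-k (V_c - V_n)) ,

  k >= 0 being the bending rigidity. Stiff filaments (large k) convert an
  energy drop into a re-alignment almost surely and therefore stay straighter
  and fold less. Moves that never lower the energy are never adopted, so a
  perfectly straight filament is an absorbing minimum for turning. (From exact
  collinearity the candidate is in fact geometrically infeasible as well: the
  rotation pulls the shared pole away from the restoring anchor, so no
  length-preserving intersection exists. The chain only starts turning once
  elongation has buckled it.)

Any candidate event is rejected outright when it would move a node out of the
unit square, lose a circle intersection (incompatible lengths), or bring two
non-adjacent cell segments closer than the cell width *w* (segments sharing a
chain node are exempt). Because division re-partitions the chain — a daughter
no longer shares a node with its mother's neighbor — an elongation whose
triggered division would violate the clearance rule is rejected up front;
this keeps the no-overlap invariant true after every accepted event rather
than only between divisions.

Migration is read out as the maximum node *y* (the apex of the most advanced
loop defines the colony front). The replicate *r* of any condition runs with
seed = base seed + *r*; all randomness flows from one `numpy` generator per
run, so identical (parameters, seed) give identical trajectories.

### Parameters and defaults

| symbol | meaning | default |
|---|---|---|
| N | initial cell count | 20 |
| T | update steps | 2·10^5 |
| G | maximal elongation rate per step | 0.004 |
| S | maximum cell length | 0.04 |
| B | sd of turning angle (rad) | 0.15 |
| k | bending rigidity | 0.5 |
| w | clearance width for overlap tests | 0.005 |
| p_turn | turn vs elongation mix | 0.5 |
| L0 | initial cell length | 0.02 |

Lengths are in units of the arena side. The three canonical conditions are the
default, a high-rigidity variant (k x10) and a large-cell variant (S and L0
x2). The default k sits on the steep part of the migration-vs-rigidity
response: a 7-point scan of k from 0.5 to 50 (6 replicates each at full T)
shows mean final migration rising from ~0.43 at k = 0.5 and saturating at
~0.51-0.53 for k >= 5. Placing the default at k = 0.5 therefore gives both
variant contrasts a detectable effect at the 20-replicate scale, while
preserving the qualitative behavior (loops form and expand under the default;
stiffer or longer cells fold less and migrate farther). The turning
probability above is written with the exponent's sign chosen so that P lies in
[0, 1] and increases with both k and the energy drop — the stated behavior of
the rigidity parameter; the opposite sign would make P negative exactly when
the move is favorable.

The event mix is an explicit Bernoulli(p_turn) choice between a turning
attempt and an elongation attempt, with division a deterministic consequence
of the post-elongation length check rather than a third random event.

### Numerical notes

* Circle intersections tolerate 1e-12 slack at tangency; coincident centers
  are treated as no intersection (the move is rejected/infeasible).
* Candidate legality uses compiled kernels (numba) with a bounding-box early
  reject; a full O(n^2) invariant audit (`FilamentState.check_invariants`) is
  available and used on a cadence in tests.
* Cell lengths are conserved by turning to ~1e-12 relative per event; tests
  assert 1e-9 over event sequences.
* A full default run (2·10^5 steps, ~1300 final cells) takes a few seconds on
  one CPU.

## Alignment statistics

Input is one centerline (ordered pixel points along the major axis) per
segmented cell; image convention is origin top-left, y down, pixel centers at
integer coordinates. Each centerline of arc length *s* is cut into
ceil(*s*/target) equal-arc segments (default target 10 px); a segment carries
its chord midpoint and chord orientation theta in [0, 180) — orientation is
axial, so theta and theta+180 are the same direction and the difference
between two orientations is folded into [0, 90].

For a focal segment, neighbors are all segments whose midpoint lies within a
radius (default 20 px, Euclidean on midpoints) excluding segments of the focal
cell itself. The summary statistics are:

* **alignment score** per segment: 1 − (mean neighbor difference)/90, in
  [0, 1], NaN for isolated segments. The formula is this package's choice —
  it is monotone in the mean difference and invariant under global rotation,
  translation and axial flips (verified by tests).
* **angle histogram**: focal segments subsampled without replacement at 10%
  (seeded), all their neighbor differences pooled and binned in 9-degree bins
  on [0, 90]; the reported mean is the mean of the pooled differences
  (per-pair pooling, not per-focal-segment averaging — with the neighbor count
  roughly constant across focal segments the two weightings differ little).
* **cell length comparison**: Welch two-sample t on centerline arc lengths.

Two independent axial orientations drawn uniformly give a folded difference
uniform on [0, 90] with mean 45 degrees — the dispersed-population null. For
bundle-like populations with wrapped-normal orientation noise of sd sigma,
the difference of two independent draws is normal with sd sigma*sqrt(2) and
the folded mean is computed by numerical integration
(`synthetic.expected_folded_mean_deg`), approaching 2*sigma/sqrt(pi) for
sigma << 90. Measured bundle means recover this expectation within
Monte-Carlo error (tests sweep sigma in {1, 5, 15} degrees).

## Fluorescence statistics

* **Co-expression ratio.** Two same-shape channels are jointly binned
  (equal-width bins spanning each channel's observed range; default 32 bins —
  counts and frequencies give the same ratio, so counts are used). Expected
  counts come from the product of the observed marginals; by construction the
  expected grid reproduces the observed marginals and total exactly. The
  ratio observed/expected is reported only where observed > 0; empty cells
  are masked — no data cannot be distinguished from depletion there. The
  summary "fraction of ratios in [0.8, 1.25]" weights cells by their observed
  pixel count: outermost cells always hold O(1) pixels whatever the sample
  size, so the unweighted fraction does not converge to 1 under independence
  while the pixel-weighted one does.
* **Transect profiles.** Intensities are sampled by bilinear interpolation at
  1-px steps along each transect; both endpoints must be inside the image.
  Each profile is shifted so its maximum (leftmost on ties) sits at offset 0;
  the per-offset mean is reported wherever >= 1 profile has a sample and the
  sd (ddof = 1) wherever >= 2 overlap. Background normalization subtracts the
  mean of a caller-supplied background pixel sample, without clipping
  (values below background are informative noise). Cell-pixel masks for the
  labeled-minus-control expression difference are inputs; segmentation is out
  of scope.

## Folding statistics

A traced loop polyline is resampled at points placed at arc-length multiples
of a spacing L (linear interpolation between trace points; trailing remainder
< L dropped; closed traces are closed before resampling; default L =
arc length/100 when unspecified). The fold measure at each interior vertex is
the unsigned angle between incoming and outgoing segments (180 = straight;
closed chains wrap, open chains have no end angles). On a circle of radius R
this reproduces the inscribed-chord angle 180 − 360·L/(2 pi R) to better than
0.1 degree for L/R <= 0.1. Strains are compared by pooling vertex angles over
all loops per strain and applying a Mann-Whitney U test (exact null for small
tie-free samples, tie-corrected normal approximation otherwise; the one-sided
alternative "A stochastically smaller" is the folding-prone direction).

## Synthetic data: what it emulates and what it does not

The generators produce every input the analyses consume, with ground truth:

* `gen_cell_field` — bundle mode chains straight 4-point centerlines
  pole-to-pole in parallel rows with wrapped-normal orientation noise
  (defaults: 200 cells, mean length 30 px, sd 4 px, noise sd 5 degrees, row
  spacing 6 px); dispersed mode scatters cells uniformly with uniform axial
  orientations over a field of matching density.
* `gen_dual_channel` — a latent binary state per pixel and channel; with
  probability |exclusivity| the two states are coupled (opposite for negative
  values, equal for positive), otherwise independent; intensities are
  low/high (20/100 AU) plus Gaussian noise (sd 8 AU), clipped at zero.
* `gen_pole_image` — horizontal rod cells chained in rows on a uniform
  background (50 AU) with Gaussian peaks (sd 1.5 px) of amplitude
  `peak_height` (100 AU) at integer-pixel pole junctions, matching
  pole-to-pole and side-to-side transects, and a pure-background strip. The
  cell body adds `body_contrast` (default 0) over background so the noise-free
  centered profile recovers the peak amplitude exactly after background
  subtraction.
* `gen_loops` — random-walk traces of 100 steps of 10 px; folds are placed at
  exactly round(fold_rate/100 x n_vertices) randomly chosen vertices per loop
  with angles Normal(fold_angle_mean, 8 degrees) and random turn direction;
  other vertices jitter the heading by Normal(0, 2 degrees). The default fold
  frequency is 40 per 100 segments, the heavily folded regime: a rank test
  comparing two strains that differ only in fold-angle mean has
  P(A < B) = 0.5 + f^2/2 at fold fraction f, so sparse folding (f << 0.3)
  would make a 30-degree separation undetectable at the ~500-segment scale
  regardless of implementation. The fold count is fixed per loop rather than
  Bernoulli-drawn so that the stated frequency is exact and between-group
  count noise does not dominate the rank statistic.

Additive Gaussian noise (clipped at 0) is used for images throughout; no
Poisson/shot-noise model, no optical blur, no bleaching, no segmentation
errors, no visual micrograph texture. Passing tests therefore demonstrate the
estimators' correctness and statistical calibration under clean, known
structure — not robustness to real microscopy artifacts such as uneven
illumination, cell overlap, or tracking failures.

## Problem sizes used by tests and the acceptance script

Simulations run at the full default T = 2·10^5. The three-condition migration
experiment uses 20 replicates per condition in the test suite (one-sided
Welch test at alpha = 0.05) and 10 replicates — the headline figure's n — in
`scripts/acceptance.py`. Co-expression checks use 10^6 pixels; alignment
checks use fields of 80-250 cells with 10-20 Monte-Carlo replicates; folding
checks use 5 loops x 100 segments per strain (~500 pooled vertex angles, the
scale of the original tracing).

## Known limitations

* The model is phenomenological: dimensionless units, no substrate friction or
  hydrodynamics, no side-to-side filament bundling, and parameters are not
  calibrated to biophysical measurements — only orderings and qualitative
  shapes are meaningful.
* Migration saturates near the arena ceiling (y = 1), compressing contrasts
  between strongly migrating conditions.
* The alignment score formula and the neighborhood metric are reasonable but
  not unique choices; absolute score values are not comparable across radii.
* Equal-arc resampling gives chords slightly shorter than the spacing on
  curved traces; vertex angles are insensitive to this at the spacings used.
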