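# Methods

## Coordinate and sign conventions

Images are treated as viewed from the top (the air interface), with the
array displayed origin-upper-left. The polar angle `phi` is measured
from the +x image axis and **increases clockwise as displayed**
(`phi = atan2(row_offset, col_offset)`, with the row axis pointing
down). A boundary that bends clockwise therefore has positive
`dphi/d ln r`, and the chiral angle

    theta = arctan(dphi / d ln r) * 180 / pi        [degrees]

is positive for clockwise colony rotation. `ln(r / r_i)` is the natural
abscissa because an equiangular spiral is exactly linear in it; at the
angles relevant here (|theta| ≲ 10°) `arctan(slope)` and
`slope * 180/pi` differ by < 0.1°, and the package standardises on
`arctan`.

## Synthetic colonies

Sector boundaries are generated directly at the curve level (no
agent-based growth): boundary k launches at `phi_0 = 2*pi*k/n` on the
homeland rim `r_i` and follows

    phi(r) = phi_0 + tan(theta_true) * ln(r/r_i) + W(ln(r/r_i)),

with `W` a zero-mean Brownian path of variance `wiggle_D` per unit
`ln r`. Brownian wander in the same variable as the deterministic drift
keeps recovery tests analytically tractable (endpoint slopes average to
`tan(theta_true)` with computable error); real sector boundaries
wander super-diffusively, which is noted but not modelled. `wiggle_D`
is a free test parameter, not a fitted biological quantity; the default
0.005 rad²/ln r gives boundary endpoints an angular spread
(~0.11 rad over a 12-fold radial expansion) comparable in magnitude to
the deterministic rotation, i.e. boundaries that look as stochastic as
they do in real colonies while leaving the drift recoverable.

Rendering partitions the annulus `r_i <= r <= r_max` into sectors of
alternating channel identity; each pixel is assigned to the boundary
immediately behind it in angle at the pixel's radius. Fills are hard
(aliased); an optional Gaussian blur emulates optics. The homeland disk
is rendered with both channels on — the mixed central sector that real
centre-fitting uses — and the background is zero. Independent Brownian
boundaries can meet and re-cross ("braid"); the renderer then flips the
channel of the strip between them at each re-crossing. This is a
deliberate consequence of keeping the stated generative model; the
extraction stage is responsible for rejecting the resulting
non-boundary features (below).

Default colony geometry (20 boundaries, r_i = 250 um, r_max = 3000 um,
5 um pixels, 1250 px images) matches a late-stage colony imaged at low
magnification and is the condition under which the headline recovery is
validated.

## Boundary extraction

* **Difference image.** Channels are normalised to their own maxima and
  subtracted; the sign flips across every sector boundary.
* **Edges.** Laplacian-of-Gaussian (sigma 2 px) zero crossings, kept
  when the response jump across the crossing exceeds 0.75× the mean
  absolute response (both exposed in the API, since real images need
  per-image adjustment).
* **Centre.** Algebraic (Kasa) least-squares circle, either through a
  user-supplied rim-point list (the faithful workflow) or through the
  rim of the Otsu-thresholded summed-channel silhouette (automated
  convenience used for synthetic images).
* **Polar transform and chaining.** Edge-pixel centres map to (r, phi);
  traces grow greedily to the nearest unassigned point within 3 px
  (ties to the lowest index, then the chain is reversed and grown from
  its other end), and phi is unwrapped along each chain.
* **Cleaning.** Points with `r < 0.25 R` (sectors not yet resolved) and
  `r > 0.98 R` (the colony rim, an intensity edge but not a sector
  boundary) are removed, with chains split at the gaps. Chains are also
  split at radial turning points (5 px hysteresis): an out-and-back
  chain has collected the two sides of a pinched-off sector, which are
  two distinct boundaries. Traces whose radial span is less than 0.2×
  their path length are dropped: sector boundaries are near-radial
  (within ~78° of radial at this threshold), whereas rim fragments and
  the channel-flip arcs left by braiding boundaries run
  circumferentially. Traces shorter than 20 points are dropped;
  survivors are smoothed with an 11-point centred moving average of phi
  (symmetrically shrinking at the ends, so linear profiles — and hence
  slopes — are preserved exactly). Scripted curation hints
  (split-at-index / drop per trace) replace interactive cleanup so
  pipelines stay reproducible.

On noiseless synthetic colonies the extracted traces deviate from the
generating spirals by under 2 px RMS, and channel swap or 90° rotation
of the input leaves the recovered chirality unchanged.

## Chiral-angle estimator

Traces from all colonies of a condition are pooled. A radial grid of
50 log-spaced bins spans the 5th–95th percentile radii of the pooled
points. For each trace and bin, the local slope `dphi/d ln r` is fitted
by OLS on the trace's points in that bin; a bin contributes only if the
trace has ≥ 2 points spanning at least half the bin's `ln r` width — a
slope fitted over a vanishing radial baseline is unbounded, and without
the span rule single corrupted fragments (from braiding artifacts)
inflate the estimator variance roughly twofold at zero chirality while
contributing nothing to signal.

The bootstrap draws N traces with replacement (N = pooled count),
averages per-bin slopes over the draw, and integrates the averaged
slope over `ln r` (trapezoid between bin centres, exact for constant
slope) from the first bin centre with `phi(r_i) = 0`. Over 200
iterations (seeded, bit-reproducible) the mean integrated curve is the
**mean rotation curve** and the per-bin sd (ddof = 1) its bootstrap
spread; bins uncovered in some iteration carry slope 0 and a coverage
flag (an interpolation mode is deliberately not the default, to keep
the integral well defined). `theta` is `arctan` of the OLS slope of the
mean curve over a radial window, by default [0.4, 0.9] of the top grid
edge — the window is always recorded in the result and should be set
from the known colony radius when available. The bootstrap spread of
`theta` is the sd of the same window fit across the 200 curves;
across-colony mean and sd are reported separately (conditions with
fewer than 5 colonies are flagged), and the two spreads are never
combined.

Validated properties: exact recovery (< 0.05°) on noiseless generative
traces across ±10°; mirror antisymmetry of the full pipeline within
0.2°; ~92% of achiral colonies within 2 bootstrap sd of zero; mean
recovery within 1° at the 6.4° benchmark over 10 colonies.

## Twist quantification

Inputs are per-frame (length, integrated fluorescence) tables —
contour segmentation is upstream and external. Curves are divided by
the prebleach level and re-zeroed to the first post-bleach frame;
`lambda` is the OLS slope of normalised F against elongation restricted
to the first 3 um (default, configurable), which provably ignores later
points where photobleaching noise accumulates. `lambda` is defined
operationally as normalised fluorescence per um of elongation; no
reference value is asserted for it. Handedness is called from the
quadrant asymmetry of a cropped recovery image after levelling the cell
axis: score = (UL + LR − LL − UR)/total about the intensity centroid,
with |score| < 0.1 (default) reported as ambiguous; recovery in the
upper-left/lower-right quadrants is the left-handed pattern. The
numeric rule replaces a by-eye classification, so the score and
threshold accompany every call.

## Filamentation and growth statistics

Length summaries report the ECDF, the mean, and the fraction of cells
with length **strictly greater** than 5 um. Fields of view are
stratified by their cell count (a proxy for sampling position relative
to the colony edge; default strata are quartiles of the per-field
counts) and cross-condition comparisons should use matching strata.
Distribution comparisons report both two-sample KS and Mann-Whitney
from standard implementations; the suite checks their null calibration
(MW p-values uniform; the asymptotic KS p-values are detectably
non-uniform at n = 200, so only its false-positive rate is checked).
The synthetic length model is a Normal body mode plus, for a programmed
fraction of cells, a lognormal excess (mean = `filament_scale`, ln-sd
0.4); the lognormal keeps essentially all filamentous cells above the
5 um threshold at realistic scales, so the programmed fraction is the
recoverable quantity, and the exact mixture exceedance probability is
available by quadrature as an oracle.

Maximal growth rate is the maximum over 11-point sliding windows of the
OLS slope of `ln(OD)` against time; input times are minutes, rates are
reported per hour. Non-positive OD readings are excluded with a warning
before windowing; no blank subtraction is applied by default. On an
exact exponential sampled at 7.5-min cadence the window regression is
exact; on a logistic curve the windowed estimate sits ~1% below the
instantaneous early-phase slope because it averages over the 75-min
window — inherent to the sliding-window definition, not an error.

## Problem sizes and numerical choices

The validation suite uses 640 px colonies (12 sectors, r_max 1500 um)
for fast property tests and the full 1250 px, 20-sector geometry for
the recovery and null-calibration studies (10 and 50 colonies
respectively); these sizes give Monte-Carlo errors comfortably inside
the asserted tolerances. All randomness flows through
`numpy.random.default_rng` seeds; bootstrap outputs are byte-identical
under a fixed seed. Degenerate inputs (collinear centre points, empty
trace sets, windows off the grid, < 3 points in a twist fit,
non-positive prebleach or OD values) raise or warn explicitly rather
than returning silent defaults.

## Known limitations

* Boundary wander is Brownian in `ln r`; real boundaries are
  super-diffusive, so absolute variances here are not biological.
* Independent boundaries can braid instead of coalescing on contact as
  real demixing boundaries do; the extraction filters reject the
  resulting artifacts, but heavily braided colonies carry more
  estimator noise than a coalescing model would produce.
* The renderer has no optics model beyond optional Gaussian blur, no
  illumination gradients, and no camera noise; extraction defaults are
  tuned for such clean images and real data will need the exposed
  sigma/threshold/curation controls.
* Handedness classification assumes a single cropped cell with a known
  axis; it does not segment.
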