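"""Sector-boundary extraction from two-channel colony images.

An expanding mixed colony of two differently labelled but otherwise
identical strains demixes into single-colour sectors; the frozen
boundaries between sectors record the growth history of the colony.
This module turns a registered YFP/CFP image pair into cleaned boundary
traces in polar coordinates around the fitted colony centre:

1. difference image of the normalised channels,
2. Laplacian-of-Gaussian zero-crossing edge detection,
3. least-squares circle fit of the colony centre (from supplied rim
   points or automatically from the colony outline),
4. polar transform of the edge pixels,
5. nearest-neighbour chaining of edge pixels into traces,
6. radius filtering, length filtering, scripted curation, smoothing.

Angles follow the "viewed from the top" convention: the polar angle phi
is measured from the +x image axis and increases clockwise as the image
is displayed (origin in the upper-left corner), so that a boundary that
bends clockwise when the plate is viewed from the air interface has
d(phi)/d(ln r) > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage as ndi
from scipy.spatial import cKDTree


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColonyImagePair:
    """Registered YFP and CFP rasters of one colony.

    Parameters
    ----------
    yfp, cfp : ndarray
        2-D intensity rasters of identical shape, finite and >= 0.
    pixel_size : float or None
        Physical pixel size in um/px. When set, extracted trace radii are
        reported in um; otherwise in pixels.
    """

    yfp: np.ndarray
    cfp: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self):
        yfp = np.asarray(self.yfp)
        cfp = np.asarray(self.cfp)
        if yfp.ndim != 2 or cfp.ndim != 2:
            raise ValueError("channel rasters must be 2-D")
        if yfp.shape != cfp.shape:
            raise ValueError(
                f"channel shapes differ: {yfp.shape} vs {cfp.shape}"
            )
        if not (np.all(np.isfinite(yfp)) and np.all(np.isfinite(cfp))):
            raise ValueError("intensities must be finite")
        if yfp.min() < 0 or cfp.min() < 0:
            raise ValueError("intensities must be >= 0")
        object.__setattr__(self, "yfp", yfp)
        object.__setattr__(self, "cfp", cfp)

    @property
    def shape(self) -> tuple[int, int]:
        return self.yfp.shape

    def swapped(self) -> "ColonyImagePair":
        return ColonyImagePair(self.cfp, self.yfp, self.pixel_size)

    def mirrored(self) -> "ColonyImagePair":
        """Left-right mirror of both channels (chirality sign flip)."""
        return ColonyImagePair(
            np.fliplr(self.yfp), np.fliplr(self.cfp), self.pixel_size
        )


@dataclass(frozen=True)
class ColonyGeometry:
    """Fitted colony centre and radius, in pixel coordinates."""

    cx: float
    cy: float
    R: float
    source: str = "rim-of-colony"  # or "central-mixed-sector"

    def __post_init__(self):
        if not self.R > 0:
            raise ValueError("colony radius must be positive")


@dataclass
class PolarPoints:
    """Edge pixels in both Cartesian (pixel) and polar coordinates."""

    x: np.ndarray
    y: np.ndarray
    r: np.ndarray
    phi: np.ndarray

    def __len__(self) -> int:
        return len(self.r)


@dataclass
class BoundaryTrace:
    """One ordered sector-boundary trace in polar coordinates.

    ``phi`` is unwrapped along the trace (no 2*pi jumps between
    neighbouring points); ``r`` is in pixels or um depending on origin.
    """

    r: np.ndarray
    phi: np.ndarray
    colony_id: str = ""
    trace_id: int = 0

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.r.shape != self.phi.shape:
            raise ValueError("r and phi must have equal length")

    def __len__(self) -> int:
        return len(self.r)

    def scaled(self, factor: float) -> "BoundaryTrace":
        """Return a copy with radii multiplied by ``factor`` (px -> um)."""
        return BoundaryTrace(self.r * factor, self.phi.copy(),
                             self.colony_id, self.trace_id)


@dataclass
class TraceSet:
    """Cleaned traces of one colony plus the geometry they refer to."""

    traces: list[BoundaryTrace]
    geometry: ColonyGeometry | None = None
    r_min_used: float = 0.0

    def __len__(self) -> int:
        return len(self.traces)


@dataclass(frozen=True)
class CurationHint:
    """Scripted stand-in for manual trace curation.

    action is ``"split"`` (at ``index``, trace becomes [:index] and
    [index:]) or ``"drop"``.
    """

    colony_id: str
    trace_id: int
    action: str
    index: int | None = None


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def difference_image(pair: ColonyImagePair) -> np.ndarray:
    """Signed YFP - CFP image after per-channel peak normalisation.

    Each channel is divided by its maximum so the two label intensities
    live on a common scale; the sign of the result flips across every
    sector boundary.
    """
    yfp = pair.yfp.astype(float)
    cfp = pair.cfp.astype(float)
    ymax = yfp.max()
    cmax = cfp.max()
    if ymax > 0:
        yfp = yfp / ymax
    if cmax > 0:
        cfp = cfp / cmax
    return yfp - cfp


def detect_edges(
    diff: np.ndarray,
    sigma: float = 2.0,
    threshold: float | None = None,
    threshold_factor: float = 0.75,
) -> np.ndarray:
    """Laplacian-of-Gaussian zero-crossing edge mask.

    The LoG response is computed at scale ``sigma`` (px); a pixel is
    marked when the response changes sign between it and a 4-neighbour
    and the jump across the crossing exceeds ``threshold``. When
    ``threshold`` is None it defaults to ``threshold_factor`` times the
    mean absolute LoG response of the image (the customary automatic
    threshold for this detector). The pixel on the weaker side of each
    crossing is marked, giving a one-pixel-wide contour.
    """
    diff = np.asarray(diff, dtype=float)
    if not np.all(np.isfinite(diff)):
        raise ValueError("difference image must be finite")
    log_resp = ndi.gaussian_laplace(diff, sigma)
    if threshold is None:
        threshold = threshold_factor * np.mean(np.abs(log_resp))
    mask = np.zeros(diff.shape, dtype=bool)
    if threshold == 0 and not np.any(log_resp):
        return mask  # constant input: no edges
    for axis in (0, 1):
        a = log_resp[:-1, :] if axis == 0 else log_resp[:, :-1]
        b = log_resp[1:, :] if axis == 0 else log_resp[:, 1:]
        crossing = (a * b < 0) & (np.abs(a - b) > threshold)
        first = crossing & (np.abs(a) <= np.abs(b))
        second = crossing & ~first
        if axis == 0:
            mask[:-1, :] |= first
            mask[1:, :] |= second
        else:
            mask[:, :-1] |= first
            mask[:, 1:] |= second
    return mask


def fit_center(points: np.ndarray, source: str = "rim-of-colony") -> ColonyGeometry:
    """Algebraic least-squares circle through (x, y) points.

    Minimises the algebraic residual of x^2 + y^2 + D*x + E*y + F = 0
    (the Kasa fit), which for low-noise rim points coincides with the
    geometric least-squares circle. Requires >= 3 non-collinear points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (x, y) points to fit a circle")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("points are collinear; circle fit is degenerate")
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx**2 + cy**2
    if r2 <= 0:
        raise ValueError("degenerate circle fit (non-positive radius)")
    return ColonyGeometry(cx=cx, cy=cy, R=float(np.sqrt(r2)), source=source)


def estimate_geometry(pair: ColonyImagePair, n_rim_points: int = 200) -> ColonyGeometry:
    """Automatic colony geometry from the summed-channel silhouette.

    Thresholds yfp + cfp (Otsu), keeps the largest connected component,
    extracts its outline and fits the least-squares circle. Convenience
    fallback for synthetic or well-behaved images; for real images the
    faithful route is a manually picked rim-point list via
    :func:`fit_center`.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import find_contours

    total = pair.yfp.astype(float) + pair.cfp.astype(float)
    if total.max() <= 0:
        raise ValueError("empty image: cannot locate colony")
    thr = threshold_otsu(total)
    mask = total > thr
    labels, n = ndi.label(mask)
    if n == 0:
        raise ValueError("no foreground component found")
    largest = np.argmax(ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))) + 1
    comp = labels == largest
    contours = find_contours(comp.astype(float), 0.5)
    rim = max(contours, key=len)  # (row, col) pairs
    if len(rim) > n_rim_points:
        rim = rim[np.linspace(0, len(rim) - 1, n_rim_points).astype(int)]
    xy = np.column_stack([rim[:, 1], rim[:, 0]])
    return fit_center(xy, source="rim-of-colony")


def to_polar(mask: np.ndarray, geometry: ColonyGeometry) -> PolarPoints:
    """Map edge-mask pixels to polar coordinates around the colony centre.

    Pixel centres (0-based indices) are used. phi = atan2(dy, dx) with
    dy the row offset, which increases clockwise in the displayed image
    (y axis pointing down), matching the viewed-from-the-top convention.
    A pixel at (cx + 10, cy) maps to (r=10, phi=0).
    """
    ys, xs = np.nonzero(np.asarray(mask))
    dx = xs.astype(float) - geometry.cx
    dy = ys.astype(float) - geometry.cy
    return PolarPoints(
        x=xs.astype(float),
        y=ys.astype(float),
        r=np.hypot(dx, dy),
        phi=np.arctan2(dy, dx),
    )


def assemble_traces(
    points: PolarPoints,
    max_link: float = 3.0,
    colony_id: str = "",
) -> list[BoundaryTrace]:
    """Chain edge points into traces by greedy nearest-neighbour linking.

    Starting from the lowest-index unassigned point, a trace repeatedly
    extends to the nearest unassigned point within ``max_link`` pixels
    (Euclidean distance in image space; ties broken by lowest point
    index). When the growing end is exhausted the trace is reversed and
    extended from its other end. Every point ends up in exactly one
    trace; isolated points become singleton traces (removed later by the
    length filter). phi is unwrapped along each chain.
    """
    n = len(points)
    if n == 0:
        return []
    xy = np.column_stack([points.x, points.y])
    tree = cKDTree(xy)
    assigned = np.zeros(n, dtype=bool)
    traces: list[BoundaryTrace] = []

    def nearest_unassigned(i: int) -> int | None:
        cands = tree.query_ball_point(xy[i], max_link)
        best = None
        for j in cands:
            if assigned[j] or j == i:
                continue
            d = float(np.hypot(*(xy[j] - xy[i])))
            key = (d, j)
            if best is None or key < best[0]:
                best = (key, j)
        return None if best is None else best[1]

    trace_id = 0
    for seed in range(n):
        if assigned[seed]:
            continue
        chain = [seed]
        assigned[seed] = True
        for _pass in range(2):
            while True:
                nxt = nearest_unassigned(chain[-1])
                if nxt is None:
                    break
                chain.append(nxt)
                assigned[nxt] = True
            chain.reverse()  # grow from the other end on the second pass
        idx = np.array(chain)
        phi = np.unwrap(points.phi[idx])
        traces.append(
            BoundaryTrace(points.r[idx], phi, colony_id=colony_id,
                          trace_id=trace_id)
        )
        trace_id += 1
    return traces


def _reversal_cut_indices(r: np.ndarray, tol: float) -> list[int]:
    """Indices of radial turning points along a chain (zigzag detection).

    A genuine sector boundary runs monotonically outward in r (up to
    pixel jitter), whereas a chain that picked up both sides of a
    pinched-off sector runs out and back. Turning points are detected
    with hysteresis ``tol``: the direction flips only after r retreats
    by more than ``tol`` from the running extremum.
    """
    cuts: list[int] = []
    direction = 0
    ext_val = r[0]
    ext_idx = 0
    for i in range(1, len(r)):
        v = r[i]
        if direction == 0:
            if v - ext_val > tol:
                direction = 1
                ext_val, ext_idx = v, i
            elif ext_val - v > tol:
                direction = -1
                ext_val, ext_idx = v, i
        elif direction == 1:
            if v > ext_val:
                ext_val, ext_idx = v, i
            elif ext_val - v > tol:
                cuts.append(ext_idx)
                direction = -1
                ext_val, ext_idx = v, i
        else:
            if v < ext_val:
                ext_val, ext_idx = v, i
            elif v - ext_val > tol:
                cuts.append(ext_idx)
                direction = 1
                ext_val, ext_idx = v, i
    return cuts


def _contiguous_runs(keep: np.ndarray) -> list[slice]:
    """Slices of maximal runs of True in a boolean array."""
    runs = []
    start = None
    for i, k in enumerate(keep):
        if k and start is None:
            start = i
        elif not k and start is not None:
            runs.append(slice(start, i))
            start = None
    if start is not None:
        runs.append(slice(start, len(keep)))
    return runs


def clean_traces(
    traces: list[BoundaryTrace],
    r_min: float,
    min_points: int = 20,
    r_max: float | None = None,
    hints: list[CurationHint] | None = None,
    geometry: ColonyGeometry | None = None,
    turn_tolerance: float | None = 5.0,
    min_radial_aspect: float | None = 0.2,
) -> TraceSet:
    """Radius-filter, curate, length-filter and re-unwrap traces.

    Points with r < ``r_min`` (too close to the centre, where sectors
    have not yet resolved) and, when ``r_max`` is given, points with
    r > ``r_max`` (the colony rim itself, whose outline is an intensity
    edge but not a sector boundary) are removed. Removal can cut a chain
    in two; each contiguous remnant becomes its own trace. ``hints``
    apply scripted splits/drops by (colony_id, trace_id) before the
    radius filter, replacing the manual curation step of interactive
    workflows with a reproducible record. Chains are additionally split
    at radial turning points (hysteresis ``turn_tolerance``, same units
    as r; None disables): a chain that runs outward and back has picked
    up the two sides of a pinched-off sector and each side is its own
    boundary. Traces whose radial span is less than ``min_radial_aspect``
    times their along-trace path length are dropped: sector boundaries
    are near-radial curves, whereas circumferential features (rim
    fragments, channel-flip arcs left where boundaries meet and
    re-separate) run in angle at nearly constant radius and are not
    boundaries. Traces shorter than ``min_points`` are dropped;
    survivors are renumbered and their phi re-unwrapped.
    """
    hints = hints or []
    worked: list[BoundaryTrace] = []
    for tr in traces:
        pieces = [tr]
        for h in hints:
            if h.colony_id == tr.colony_id and h.trace_id == tr.trace_id:
                if h.action == "drop":
                    pieces = []
                elif h.action == "split":
                    if h.index is None:
                        raise ValueError("split hint needs an index")
                    pieces = [
                        BoundaryTrace(tr.r[: h.index], tr.phi[: h.index],
                                      tr.colony_id, tr.trace_id),
                        BoundaryTrace(tr.r[h.index:], tr.phi[h.index:],
                                      tr.colony_id, tr.trace_id),
                    ]
                else:
                    raise ValueError(f"unknown curation action {h.action!r}")
        worked.extend(pieces)

    if turn_tolerance is not None:
        split_out: list[BoundaryTrace] = []
        for tr in worked:
            if len(tr) < 2:
                split_out.append(tr)
                continue
            cuts = _reversal_cut_indices(tr.r, turn_tolerance)
            lo = 0
            for cut in cuts + [len(tr) - 1]:
                split_out.append(
                    BoundaryTrace(tr.r[lo:cut + 1], tr.phi[lo:cut + 1],
                                  tr.colony_id, tr.trace_id)
                )
                lo = cut + 1
        worked = split_out

    cleaned: list[BoundaryTrace] = []
    for tr in worked:
        keep = tr.r >= r_min
        if r_max is not None:
            keep &= tr.r <= r_max
        for run in _contiguous_runs(keep):
            if run.stop - run.start < max(min_points, 2):
                continue
            r_run = tr.r[run]
            phi_run = np.unwrap(tr.phi[run])
            if min_radial_aspect is not None:
                ds = np.hypot(np.diff(r_run),
                              0.5 * (r_run[1:] + r_run[:-1]) * np.diff(phi_run))
                path = ds.sum()
                if path > 0 and np.ptp(r_run) / path < min_radial_aspect:
                    continue
            cleaned.append(
                BoundaryTrace(r_run, phi_run, tr.colony_id, len(cleaned))
            )
    if not cleaned:
        warnings.warn("no traces survive cleaning; trace set is empty")
    return TraceSet(traces=cleaned, geometry=geometry, r_min_used=r_min)


def smooth_trace(trace: BoundaryTrace, window: int = 11) -> BoundaryTrace:
    """Centred moving average of phi along the trace; r untouched.

    Endpoints use symmetrically shrinking windows, so a linear phi
    profile (in the trace's own ordering) is reproduced exactly
    everywhere, including at the ends.
    """
    if window < 1:
        raise ValueError("smoothing window must be >= 1")
    n = len(trace)
    if n < window:
        raise ValueError(f"trace of {n} points shorter than window {window}")
    h = (window - 1) // 2
    idx = np.arange(n)
    half = np.minimum(np.minimum(idx, n - 1 - idx), h)
    cs = np.concatenate([[0.0], np.cumsum(trace.phi)])
    lo = idx - half
    hi = idx + half + 1
    phi_s = (cs[hi] - cs[lo]) / (hi - lo)
    return BoundaryTrace(trace.r.copy(), phi_s, trace.colony_id, trace.trace_id)


def extract_traces(
    pair: ColonyImagePair,
    geometry: ColonyGeometry | None = None,
    sigma: float = 2.0,
    edge_threshold: float | None = None,
    threshold_factor: float = 0.75,
    max_link: float = 3.0,
    r_min_frac: float = 0.25,
    r_max_frac: float = 0.98,
    min_points: int = 20,
    smooth_window: int = 11,
    hints: list[CurationHint] | None = None,
    turn_tolerance: float | None = 5.0,
    min_radial_aspect: float | None = 0.2,
    colony_id: str = "",
) -> TraceSet:
    """Full boundary-extraction pipeline for one colony image pair.

    Runs difference image -> LoG edges -> (auto) geometry -> polar
    transform -> nearest-neighbour chaining -> radius/length filters and
    scripted curation -> smoothing. Radii are converted to um when the
    pair carries a pixel size.
    """
    diff = difference_image(pair)
    mask = detect_edges(diff, sigma=sigma, threshold=edge_threshold,
                        threshold_factor=threshold_factor)
    if geometry is None:
        geometry = estimate_geometry(pair)
    pts = to_polar(mask, geometry)
    raw = assemble_traces(pts, max_link=max_link, colony_id=colony_id)
    ts = clean_traces(
        raw,
        r_min=r_min_frac * geometry.R,
        r_max=r_max_frac * geometry.R,
        min_points=min_points,
        hints=hints,
        geometry=geometry,
        turn_tolerance=turn_tolerance,
        min_radial_aspect=min_radial_aspect,
    )
    smoothed = [
        smooth_trace(tr, smooth_window) if len(tr) >= smooth_window else tr
        for tr in ts.traces
    ]
    r_min_used = ts.r_min_used
    if pair.pixel_size is not None:
        smoothed = [tr.scaled(pair.pixel_size) for tr in smoothed]
        r_min_used *= pair.pixel_size
    return TraceSet(traces=smoothed, geometry=geometry, r_min_used=r_min_used)
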