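"""Chiral-angle estimation from pooled sector-boundary traces.

A sector boundary of an expanding colony that maintains a constant
angle theta to the radial direction is a logarithmic (equiangular)
spiral, phi(r) = phi0 + tan(theta) * ln(r / r_i). The chiral angle of a
condition is therefore estimated as the slope of the mean polar angle
phi against ln(r):

1. pool all traces from all colonies of the condition,
2. per trace and per radial bin, fit the local slope d(phi)/d(ln r),
3. bootstrap over traces: draw traces with replacement, average the
   per-bin slopes, integrate the averaged slope over ln(r) from the
   initial radius (phi(r_i) = 0); repeat n_boot times,
4. the mean of the integrated curves is the mean rotation curve phi(r),
   their per-bin standard deviation the bootstrap spread,
5. theta = arctan(slope of phi_mean vs ln r) over a radial fit window,
   in degrees, positive for clockwise rotation viewed from the top.

`ChiralityModel` / `ChiralityResults` wrap steps 2-5 in a fit interface;
the underlying functions are exposed for pipeline use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .boundary import BoundaryTrace, TraceSet

__all__ = [
    "RadialGrid",
    "MeanRotationCurve",
    "ChiralAngleResult",
    "ConditionSummary",
    "trace_slopes_on_grid",
    "bootstrap_mean_curve",
    "chiral_angle",
    "aggregate_condition",
    "ChiralityModel",
    "ChiralityResults",
]


# ---------------------------------------------------------------------------
# Radial grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RadialGrid:
    """Log-spaced radial bins on which per-trace slopes are sampled."""

    edges: np.ndarray  # length n_bins + 1, strictly increasing, > 0

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=float)
        if edges.ndim != 1 or len(edges) < 6:
            raise ValueError("need at least 5 bins (6 edges)")
        if edges[0] <= 0 or np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be positive and strictly increasing")
        object.__setattr__(self, "edges", edges)

    @classmethod
    def from_range(cls, r_lo: float, r_hi: float, n_bins: int = 50) -> "RadialGrid":
        if not 0 < r_lo < r_hi:
            raise ValueError("require 0 < r_lo < r_hi")
        return cls(np.geomspace(r_lo, r_hi, n_bins + 1))

    @classmethod
    def from_traces(
        cls,
        traces: list[BoundaryTrace],
        n_bins: int = 50,
        lo_pct: float = 5.0,
        hi_pct: float = 95.0,
    ) -> "RadialGrid":
        """Grid between percentile radii of the pooled trace points."""
        r_all = np.concatenate([tr.r for tr in traces])
        r_lo, r_hi = np.percentile(r_all, [lo_pct, hi_pct])
        return cls.from_range(float(r_lo), float(r_hi), n_bins)

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def centers(self) -> np.ndarray:
        """Geometric bin centres (log midpoints)."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    @property
    def r_i(self) -> float:
        """Initial radius of the integrated rotation curve."""
        return float(self.centers[0])


@dataclass
class MeanRotationCurve:
    """Bootstrap mean polar angle phi(r) with per-bin spread.

    phi_mean starts at 0 in the first bin; phi_sd is the standard
    deviation over the n_boot integrated bootstrap curves.
    """

    grid: RadialGrid
    phi_mean: np.ndarray
    phi_sd: np.ndarray
    n_boot: int
    seed: int | None = None
    coverage_warn: np.ndarray | None = None  # bins ever lacking slope samples
    samples: np.ndarray | None = None  # (n_boot, n_bins) integrated curves

    def __post_init__(self):
        if len(self.phi_mean) != self.grid.n_bins:
            raise ValueError("phi_mean length must equal the bin count")
        if np.any(self.phi_sd < 0):
            raise ValueError("phi_sd must be non-negative")


@dataclass(frozen=True)
class ChiralAngleResult:
    """Signed chiral angle (degrees, clockwise-from-top positive)."""

    theta_deg: float
    theta_sd_deg: float  # NaN when no bootstrap spread is available
    fit_window: tuple[float, float]
    slope: float  # d(phi)/d(ln r) used for theta
    n_traces: int = 0
    n_colonies: int = 0


@dataclass(frozen=True)
class ConditionSummary:
    """Across-colony mean and spread of the chiral angle."""

    theta_mean_deg: float
    theta_sd_deg: float  # NaN for a single colony
    n_colonies: int
    few_colonies: bool  # True when fewer than 5 colonies contribute


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def _as_trace_list(traces) -> list[BoundaryTrace]:
    if isinstance(traces, TraceSet):
        return list(traces.traces)
    if isinstance(traces, (list, tuple)):
        out: list[BoundaryTrace] = []
        for item in traces:
            if isinstance(item, TraceSet):
                out.extend(item.traces)
            else:
                out.append(item)
        return out
    raise TypeError("expected a TraceSet, list of traces, or list of TraceSets")


def trace_slopes_on_grid(traces, grid: RadialGrid,
                         min_span_frac: float = 0.5) -> np.ndarray:
    """Per-trace, per-bin local slopes d(phi)/d(ln r).

    For each trace and each grid bin it overlaps with at least two
    points, the slope is the ordinary least-squares fit of phi against
    ln(r) on the points inside the bin. The points must span at least
    ``min_span_frac`` of the bin's ln(r) width: a local slope fitted
    over a vanishing radial baseline is unstable (a near-circumferential
    segment clipped by a bin edge can produce arbitrarily large values),
    so such fragments contribute nothing to that bin. Bins a trace does
    not cover hold NaN. Traces covering no bin are skipped with a
    warning.
    """
    trace_list = _as_trace_list(traces)
    if not trace_list:
        raise ValueError("no traces supplied")
    ln_width = np.diff(np.log(grid.edges))
    S = np.full((len(trace_list), grid.n_bins), np.nan)
    for i, tr in enumerate(trace_list):
        if len(tr) < 2:
            warnings.warn(f"trace {tr.trace_id} has < 2 points; skipped")
            continue
        which = np.digitize(tr.r, grid.edges) - 1
        any_bin = False
        for j in range(grid.n_bins):
            sel = which == j
            if sel.sum() < 2:
                continue
            lnr = np.log(tr.r[sel])
            if np.ptp(lnr) < min_span_frac * ln_width[j]:
                continue
            S[i, j] = np.polyfit(lnr, tr.phi[sel], 1)[0]
            any_bin = True
        if not any_bin:
            warnings.warn(
                f"trace {tr.colony_id}/{tr.trace_id} covers no bin with >= 2 "
                "points; it contributes nothing"
            )
    return S


def _integrate_slopes(s_bar: np.ndarray, ln_centers: np.ndarray) -> np.ndarray:
    """Cumulative trapezoid of the per-bin slopes over ln(r), phi[0] = 0."""
    incr = 0.5 * (s_bar[1:] + s_bar[:-1]) * np.diff(ln_centers)
    return np.concatenate([[0.0], np.cumsum(incr)])


def bootstrap_mean_curve(
    traces,
    grid: RadialGrid,
    n_boot: int = 200,
    seed: int | None = None,
    keep_samples: bool = True,
) -> MeanRotationCurve:
    """Bootstrap-over-traces mean rotation curve.

    Each iteration draws N traces with replacement (N = number of
    pooled traces), averages their per-bin slopes, and integrates the
    averaged slope over ln(r) from the first bin centre with
    phi(r_i) = 0. The final curve is the mean of the n_boot integrated
    curves; phi_sd is their per-bin standard deviation (ddof=1). A bin
    with no slope sample in some iteration contributes zero slope and is
    flagged in ``coverage_warn``.
    """
    S = trace_slopes_on_grid(traces, grid)
    usable = ~np.all(np.isnan(S), axis=1)
    S = S[usable]
    n = S.shape[0]
    if n == 0:
        raise ValueError("no usable traces for the bootstrap")
    rng = np.random.default_rng(seed)
    ln_c = np.log(grid.centers)
    curves = np.empty((n_boot, grid.n_bins))
    coverage_warn = np.zeros(grid.n_bins, dtype=bool)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            s_bar = np.nanmean(S[idx], axis=0)
        empty = np.isnan(s_bar)
        if np.any(empty):
            coverage_warn |= empty
            s_bar = np.where(empty, 0.0, s_bar)
        curves[b] = _integrate_slopes(s_bar, ln_c)
    if np.any(coverage_warn):
        warnings.warn(
            f"{int(coverage_warn.sum())} bins lacked slope samples in some "
            "bootstrap iteration; their slope was taken as 0"
        )
    phi_mean = curves.mean(axis=0)
    phi_sd = curves.std(axis=0, ddof=1) if n_boot > 1 else np.zeros(grid.n_bins)
    return MeanRotationCurve(
        grid=grid,
        phi_mean=phi_mean,
        phi_sd=phi_sd,
        n_boot=n_boot,
        seed=seed,
        coverage_warn=coverage_warn,
        samples=curves if keep_samples else None,
    )


def _window_slope(phi: np.ndarray, ln_c: np.ndarray, sel: np.ndarray) -> float:
    return float(np.polyfit(ln_c[sel], phi[sel], 1)[0])


def chiral_angle(
    curve: MeanRotationCurve,
    fit_window: tuple[float, float] | None = None,
    n_traces: int = 0,
    n_colonies: int = 0,
) -> ChiralAngleResult:
    """Chiral angle from the mean rotation curve over a radial window.

    theta = arctan(slope) * 180 / pi where slope is the OLS fit of
    phi_mean against ln(r) over bins whose centres fall in
    ``fit_window`` (default [0.4, 0.9] of the top grid edge). The
    bootstrap spread of theta is the standard deviation of the same
    window fit over the stored bootstrap curves, when available.
    """
    grid = curve.grid
    if fit_window is None:
        r_top = grid.edges[-1]
        fit_window = (0.4 * r_top, 0.9 * r_top)
    r_lo, r_hi = fit_window
    if r_lo >= r_hi:
        raise ValueError("fit window must satisfy r_lo < r_hi")
    sel = (grid.centers >= r_lo) & (grid.centers <= r_hi)
    if sel.sum() < 3:
        raise ValueError(
            f"fit window {fit_window} covers {int(sel.sum())} grid bins; "
            "need at least 3"
        )
    ln_c = np.log(grid.centers)
    slope = _window_slope(curve.phi_mean, ln_c, sel)
    theta = float(np.degrees(np.arctan(slope)))
    if curve.samples is not None and curve.n_boot > 1:
        thetas = np.degrees(
            np.arctan([_window_slope(s, ln_c, sel) for s in curve.samples])
        )
        theta_sd = float(np.std(thetas, ddof=1))
    else:
        theta_sd = float("nan")
    return ChiralAngleResult(
        theta_deg=theta,
        theta_sd_deg=theta_sd,
        fit_window=(float(r_lo), float(r_hi)),
        slope=slope,
        n_traces=n_traces,
        n_colonies=n_colonies,
    )


def aggregate_condition(results: list[ChiralAngleResult]) -> ConditionSummary:
    """Across-colony mean and standard deviation of the chiral angle.

    Mirrors the usual reporting for colony experiments: each colony
    contributes one angle; conditions with fewer than 5 colonies are
    flagged. A single colony yields an undefined (NaN) spread.
    """
    if not results:
        raise ValueError("no colony results to aggregate")
    thetas = np.array([res.theta_deg for res in results])
    n = len(thetas)
    sd = float(np.std(thetas, ddof=1)) if n > 1 else float("nan")
    return ConditionSummary(
        theta_mean_deg=float(thetas.mean()),
        theta_sd_deg=sd,
        n_colonies=n,
        few_colonies=n < 5,
    )


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class ChiralityModel:
    """Chiral-angle model over pooled sector-boundary traces.

    Parameters
    ----------
    traces : TraceSet, list of TraceSet, or list of BoundaryTrace
        All traces from all colonies of one experimental condition;
        multiple TraceSets are pooled.
    grid : RadialGrid, optional
        Radial binning; by default 50 log-spaced bins between the 5th
        and 95th percentile radii of the pooled points.
    n_bins : int
        Bin count for the default grid.
    """

    def __init__(self, traces, grid: RadialGrid | None = None, n_bins: int = 50):
        self.trace_list = _as_trace_list(traces)
        if not self.trace_list:
            raise ValueError("cannot build a model from an empty trace set")
        self.grid = grid if grid is not None else RadialGrid.from_traces(
            self.trace_list, n_bins=n_bins
        )
        self.colony_ids = sorted({tr.colony_id for tr in self.trace_list})

    def fit(
        self,
        n_boot: int = 200,
        seed: int | None = None,
        window: tuple[float, float] | None = None,
    ) -> "ChiralityResults":
        """Bootstrap the mean rotation curve and fit the chiral angle."""
        curve = bootstrap_mean_curve(
            self.trace_list, self.grid, n_boot=n_boot, seed=seed
        )
        result = chiral_angle(
            curve,
            fit_window=window,
            n_traces=len(self.trace_list),
            n_colonies=len(self.colony_ids),
        )
        return ChiralityResults(self, curve, result)


class ChiralityResults:
    """Fitted chiral angle plus the bootstrap mean rotation curve."""

    def __init__(self, model: ChiralityModel, curve: MeanRotationCurve,
                 result: ChiralAngleResult):
        self.model = model
        self.curve = curve
        self.result = result

    @property
    def theta_deg(self) -> float:
        return self.result.theta_deg

    @property
    def theta_sd_deg(self) -> float:
        return self.result.theta_sd_deg

    @property
    def slope(self) -> float:
        return self.result.slope

    def summary(self) -> str:
        res = self.result
        lines = [
            "Chiral-angle fit (bootstrap over pooled traces)",
            "=" * 48,
            f"traces pooled          {res.n_traces:>10d}",
            f"colonies               {res.n_colonies:>10d}",
            f"radial bins            {self.curve.grid.n_bins:>10d}",
            f"bootstrap iterations   {self.curve.n_boot:>10d}",
            f"fit window             [{res.fit_window[0]:.1f}, "
            f"{res.fit_window[1]:.1f}]",
            f"slope dphi/dln(r)      {res.slope:>10.5f}",
            f"chiral angle theta     {res.theta_deg:>10.3f} deg",
            f"bootstrap sd           {res.theta_sd_deg:>10.3f} deg",
            "sign: positive = clockwise viewed from the top",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Mean rotation curve with bootstrap band and window fit line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = self.curve.grid
        r = grid.centers
        ax.plot(r, np.degrees(self.curve.phi_mean), "k-", lw=2,
                label="mean rotation")
        ax.fill_between(
            r,
            np.degrees(self.curve.phi_mean - self.curve.phi_sd),
            np.degrees(self.curve.phi_mean + self.curve.phi_sd),
            color="0.8",
        )
        r_lo, r_hi = self.result.fit_window
        sel = (r >= r_lo) & (r <= r_hi)
        ln_c = np.log(r)
        coef = np.polyfit(ln_c[sel], self.curve.phi_mean[sel], 1)
        ax.plot(r[sel], np.degrees(np.polyval(coef, ln_c[sel])), "r-",
                label=f"theta = {self.theta_deg:.2f} deg")
        ax.axvspan(r_lo, r_hi, color="gold", alpha=0.15)
        ax.set_xscale("log")
        ax.set_xlabel("radius")
        ax.set_ylabel("mean polar angle (deg)")
        ax.legend()
        return ax
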