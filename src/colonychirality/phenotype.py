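"""Filamentation and growth statistics.

Cell-length distribution summaries from colony-edge samples — with the
filamentation criterion "length > 5 um" and stratification by imaging
density — and the maximal growth rate of OD600 curves via sliding-window
regression of ln(OD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LengthDistSummary",
    "TwoSampleReport",
    "GrowthRateFit",
    "summarize_lengths",
    "stratify_by_density",
    "compare_distributions",
    "max_growth_rate",
]

FILAMENT_THRESHOLD_UM = 5.0


@dataclass(frozen=True)
class LengthDistSummary:
    """Summary of one cell-length sample."""

    n: int
    frac_gt_threshold: float
    threshold: float
    mean_length: float
    ecdf_x: np.ndarray  # sorted lengths
    ecdf_y: np.ndarray  # cumulative fractions, ends at 1


@dataclass(frozen=True)
class TwoSampleReport:
    """Kolmogorov-Smirnov and Mann-Whitney comparison of two samples."""

    ks_stat: float
    ks_p: float
    mw_stat: float
    mw_p: float


@dataclass(frozen=True)
class GrowthRateFit:
    """Maximal specific growth rate from one OD600 curve."""

    rate_per_hour: float
    window: int
    t_at_max_min: float  # centre time of the maximising window
    n_windows: int


def summarize_lengths(lengths, threshold: float = FILAMENT_THRESHOLD_UM) -> LengthDistSummary:
    """ECDF, mean, and fraction of lengths strictly above ``threshold``.

    The filamentous fraction uses a strict inequality (length > 5 um by
    default).
    """
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty length sample")
    x = np.sort(arr)
    y = np.arange(1, len(x) + 1) / len(x)
    return LengthDistSummary(
        n=len(x),
        frac_gt_threshold=float(np.mean(arr > threshold)),
        threshold=float(threshold),
        mean_length=float(arr.mean()),
        ecdf_x=x,
        ecdf_y=y,
    )


def stratify_by_density(
    records: pd.DataFrame,
    bin_edges=None,
    threshold: float = FILAMENT_THRESHOLD_UM,
    length_col: str = "length_um",
    field_col: str = "field_id",
) -> pd.DataFrame:
    """Per-density-stratum length summaries.

    Cells sampled from a colony edge are imaged in fields of view; the
    number of cells in a field proxies how close to the colony centre
    the field was sampled, and length statistics shift with that
    density. Fields are assigned to strata by their cell count
    (``bin_edges``; default: quartile edges of the per-field counts)
    and summaries are computed per stratum so that comparisons across
    conditions can be restricted to matching strata. Empty strata are
    omitted with a note.
    """
    if records.empty:
        raise ValueError("no records to stratify")
    counts = records.groupby(field_col).size()
    if bin_edges is None:
        qs = np.quantile(counts.values, [0.0, 0.25, 0.5, 0.75])
        bin_edges = np.concatenate([np.unique(qs), [np.inf]])
    bin_edges = np.asarray(bin_edges, dtype=float)
    rows = []
    for k in range(len(bin_edges) - 1):
        lo, hi = bin_edges[k], bin_edges[k + 1]
        fields = counts.index[(counts.values >= lo) & (counts.values < hi)]
        if len(fields) == 0:
            warnings.warn(
                f"density stratum [{lo:g}, {hi:g}) contains no field; omitted"
            )
            continue
        sub = records[records[field_col].isin(fields)]
        summ = summarize_lengths(sub[length_col].values, threshold)
        rows.append({
            "stratum_lo": lo,
            "stratum_hi": hi,
            "n_fields": len(fields),
            "n_cells": summ.n,
            "frac_gt_threshold": summ.frac_gt_threshold,
            "mean_length": summ.mean_length,
        })
    return pd.DataFrame(rows)


def compare_distributions(a, b) -> TwoSampleReport:
    """Two-sample KS and Mann-Whitney tests on length samples.

    Both tests are reported side by side, as is customary for
    length-distribution comparisons; standard implementations are used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ks = stats.ks_2samp(a, b)
    mw = stats.mannwhitneyu(a, b, alternative="two-sided")
    return TwoSampleReport(
        ks_stat=float(ks.statistic),
        ks_p=float(ks.pvalue),
        mw_stat=float(mw.statistic),
        mw_p=float(mw.pvalue),
    )


def max_growth_rate(times_min, od, window: int = 11) -> GrowthRateFit:
    """Maximal slope of ln(OD) over sliding windows of ``window`` points.

    Times are in minutes; the rate is reported per hour. Non-positive
    OD values are excluded with a warning before windowing; at least
    ``window`` valid points are required. The slope of each contiguous
    window comes from ordinary least squares of ln(OD) against time.
    """
    t = np.asarray(times_min, dtype=float)
    od = np.asarray(od, dtype=float)
    if t.shape != od.shape:
        raise ValueError("times and od must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    valid = od > 0
    if not np.all(valid):
        warnings.warn(
            f"excluding {int((~valid).sum())} non-positive OD values"
        )
        t, od = t[valid], od[valid]
    if len(t) < window:
        raise ValueError(
            f"only {len(t)} valid points; need at least {window}"
        )
    ln_od = np.log(od)
    best = -np.inf
    best_t = float("nan")
    n_win = len(t) - window + 1
    for i in range(n_win):
        sl = slice(i, i + window)
        slope = np.polyfit(t[sl], ln_od[sl], 1)[0]
        if slope > best:
            best = slope
            best_t = float(t[sl].mean())
    return GrowthRateFit(
        rate_per_hour=float(best * 60.0),
        window=window,
        t_at_max_min=best_t,
        n_windows=n_win,
    )
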