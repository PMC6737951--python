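"""Histogram phenotyping and the statistical battery.

Regional voxel-intensity histograms (20 equal-width bins with second-order
Savitzky-Golay smoothing over a 5-bin window), Mann-Whitney U tests for
ordinal histopathology scores, Student t-tests for parametric map values,
and pooled Pearson correlation of per-segment map means against per-segment
histology scores across animals and experiments.

The Mann-Whitney p-value is exact for small problems (full permutation
enumeration over midrank sums, valid under ties) and for tie-free problems
up to ``n1*n2 <= 400`` (dynamic-programming null distribution of U);
otherwise the normal approximation with tie correction and continuity
correction is used. Pooled Pearson treats every
(segment, animal) pair as one observation — within-animal dependence of
segments is acknowledged and deliberately not corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.signal import savgol_filter

from .relaxometry import ParameterMap
from .segmentation import SegmentLabelMap

__all__ = [
    "HistogramSummary",
    "GroupComparison",
    "CorrelationResult",
    "roi_histogram",
    "smooth_histogram",
    "mann_whitney",
    "t_test",
    "correlate_segments",
]


@dataclass
class HistogramSummary:
    """A 20-bin region histogram with smoothing and location statistics."""

    bin_edges: np.ndarray   # n_bins + 1, ms
    counts: np.ndarray      # n_bins, integers
    smoothed: np.ndarray    # n_bins, reals
    mean: float
    median: float
    skewness: float

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())


@dataclass
class GroupComparison:
    test: str          # "mannwhitney" | "t_paired" | "t_unpaired"
    statistic: float
    p: float
    n1: int
    n2: int
    tails: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    x_label: str
    y_label: str

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")


def roi_histogram(
    pmap: ParameterMap,
    labelmap: SegmentLabelMap,
    segment_ids: list[int],
    n_bins: int = 20,
) -> HistogramSummary:
    """Voxel-intensity histogram of a map over the named segments.

    Bins are equal-width over [min, max] of the pooled valid pixels;
    constant regions get a single unit-width bin centred on the value.
    """
    sel = np.isin(labelmap.labels, segment_ids) & pmap.valid_mask
    vals = pmap.values[sel]
    if vals.size == 0:
        raise ValueError("no valid pixels in the requested segments")
    if vals.size < n_bins:
        warnings.warn(f"only {vals.size} pixels for a {n_bins}-bin histogram")
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    return HistogramSummary(
        bin_edges=edges,
        counts=counts,
        smoothed=smooth_histogram(counts),
        mean=float(vals.mean()),
        median=float(np.median(vals)),
        skewness=float(sps.skew(vals)) if np.ptp(vals) > 0 else 0.0,
    )


def smooth_histogram(counts: np.ndarray) -> np.ndarray:
    """Savitzky-Golay smoothing: two bins each side, second-order polynomial.

    Reproduces polynomials up to order 2 exactly; edge bins are handled by a
    polynomial fit on the truncated window.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 5:
        raise ValueError("need at least 5 bins for window-5 smoothing")
    return savgol_filter(counts, window_length=5, polyorder=2, mode="interp")


def _u_null_pmf(n1: int, n2: int) -> np.ndarray:
    """Exact null distribution of U by dynamic programming over rank subsets."""
    n = n1 + n2
    max_sum = n1 * n  # loose upper bound on the rank sum
    g = np.zeros((n1 + 1, max_sum + 1))
    g[0, 0] = 1.0
    for rank in range(1, n + 1):
        for j in range(min(rank, n1), 0, -1):
            g[j, rank:] += g[j - 1, :-rank]
    s_min = n1 * (n1 + 1) // 2
    pmf = g[n1, s_min:s_min + n1 * n2 + 1]
    return pmf / comb(n, n1)


def mann_whitney(scores_a, scores_b, tails: int = 2) -> GroupComparison:
    """Mann-Whitney U with midrank ties; exact p when feasible.

    Reports U for the first group (``U1``); swapping the groups maps
    ``U -> n1*n2 - U`` with an unchanged p-value. The two-sided p is
    ``min(1, 2*min(P(U<=u), P(U>=u)))`` under the exact null; one-tailed
    requests return the smaller tail.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)

    has_ties = np.unique(pooled).size < pooled.size
    if comb(n1 + n2, n1) <= 20_000:
        # small problems: permutation enumeration over midrank sums is exact
        # even under ties (and covers tied ordinal scores)
        from itertools import combinations
        base = n1 * (n1 + 1) / 2
        us = np.array([ranks[list(c)].sum() - base
                       for c in combinations(range(n1 + n2), n1)])
        cdf = float((us <= u1 + 1e-9).mean())
        sf = float((us >= u1 - 1e-9).mean())
        p = min(cdf, sf) if tails == 1 else min(1.0, 2.0 * min(cdf, sf))
    elif not has_ties and n1 * n2 <= 400:
        pmf = _u_null_pmf(n1, n2)
        u_int = int(round(u1))
        cdf = float(pmf[:u_int + 1].sum())
        sf = float(pmf[u_int:].sum())
        p = min(cdf, sf) if tails == 1 else min(1.0, 2.0 * min(cdf, sf))
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts ** 3 - tie_counts).sum())) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u1 - mu) - 0.5) / np.sqrt(var)  # continuity-corrected
            z = max(z, 0.0)
            p = float(sps.norm.sf(z))
            if tails == 2:
                p = min(1.0, 2.0 * p)
    return GroupComparison(test="mannwhitney", statistic=u1, p=p, n1=n1, n2=n2, tails=tails)


def t_test(values_a, values_b, paired: bool = False, tails: int = 2,
           welch: bool = False) -> GroupComparison:
    """Paired or unpaired Student t-test (Welch variant by flag).

    Degenerate zero-variance comparisons with equal means follow the
    convention t=0, p=1. One-tailed requests halve the two-sided p.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal-length groups")
        if a.size < 2:
            raise ValueError("need n >= 2")
        res = sps.ttest_rel(a, b)
        name = "t_paired"
    else:
        if min(a.size, b.size) < 2:
            raise ValueError("need n >= 2 in each group")
        res = sps.ttest_ind(a, b, equal_var=not welch)
        name = "t_unpaired"
    t_stat, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t_stat):
        if np.isclose(a.mean(), b.mean()):
            t_stat, p = 0.0, 1.0
        else:
            raise ValueError("zero variance with unequal means: t undefined")
    if tails == 1:
        p = p / 2.0
    return GroupComparison(test=name, statistic=t_stat, p=p,
                           n1=a.size, n2=b.size, tails=tails)


def correlate_segments(
    seg_tables: list[pd.DataFrame],
    score_sets: list,
    map_modality: str,
    score_name: str,
) -> CorrelationResult:
    """Pooled Pearson correlation of segment map means against scores.

    One (mean value, ordinal score) pair per segment per animal, pooled
    across all animals/experiments; segments with no valid pixels are
    dropped. Ordinal scores enter as integers 0-3.
    """
    if len(seg_tables) != len(score_sets):
        raise ValueError("one score set per segment table required")
    xs, ys = [], []
    for table, scores in zip(seg_tables, score_sets):
        score_df = scores.scores if hasattr(scores, "scores") else scores
        merged = table.merge(score_df[["segment_id", score_name]], on="segment_id")
        merged = merged[(merged["n_pixels"] > 0) & merged["mean"].notna()]
        xs.append(merged["mean"].to_numpy(dtype=float))
        ys.append(merged[score_name].to_numpy(dtype=float))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size < 3:
        raise ValueError("need at least 3 pooled segment observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate correlation: zero variance in an input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=int(x.size),
                             x_label=map_modality, y_label=score_name)
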