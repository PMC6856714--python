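"""Local interaction density in sliding windows, summarised by occupancy
quantiles with bootstrap confidence intervals.

The density of an on-diagonal square window is the mean obs/exp over its
eligible pixels -- pairs (i, j) with i <= j and |i - j| >= 2, i.e. the first
two diagonals are excluded (at 5 kb bins and 25 kb windows that leaves
exactly 6 pixels).  A window is dropped when the missing (NaN) fraction of
its eligible pixels reaches ``max_missing_frac``; at the defaults a single
masked bin removes the window.

Windows are then joined to a ChIP-style coverage track, grouped by coverage
quantiles, and each group's mean density is reported with a percentile-
bootstrap 95% CI.  For a paired-condition comparison the group assignment
from one condition's coverage (e.g. serum occupancy) is applied to both
conditions' density tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expected import ExpectedProfile
from .matrixio import BalancedContactMatrix, track_to_windows

__all__ = [
    "eligible_pixel_count",
    "local_interaction_density",
    "window_coverage",
    "quantile_edges",
    "assign_quantile_groups",
    "bin_by_quantiles",
]


def eligible_pixel_count(w: int) -> int:
    """Number of pixel pairs (i <= j, j - i >= 2) in a w-bin window."""
    return (w - 2) * (w - 1) // 2


def local_interaction_density(
    matrix: BalancedContactMatrix,
    expected: ExpectedProfile,
    window_bp: int = 25_000,
    step_bp: int | None = None,
    max_missing_frac: float = 0.2,
) -> pd.DataFrame:
    """Mean obs/exp per on-diagonal window, excluding the first two diagonals.

    Returns a table (chrom, start, end, density, n_valid, n_eligible) of the
    retained windows.  ``step_bp`` defaults to ``window_bp`` (tiling windows,
    so no pixel enters the bootstrap twice); a one-bin stride is available.
    """
    res = matrix.bins.resolution
    if window_bp % res != 0:
        raise ValueError("window size must be a multiple of the resolution")
    w = window_bp // res
    if w < 3:
        raise ValueError(f"window of {w} bins has no eligible pixels (need >= 3)")
    step_bp = window_bp if step_bp is None else step_bp
    if step_bp % res != 0 or step_bp <= 0:
        raise ValueError("step must be a positive multiple of the resolution")
    step = step_bp // res

    ii, jj = np.triu_indices(w, k=2)
    n_eligible = len(ii)
    rows = []
    for chrom in matrix.chroms:
        n = matrix.bins.n_bins(chrom)
        if n < w:
            continue
        dense = matrix.balanced_dense(chrom)
        exp = expected.expected(chrom)
        exp_pix = exp[jj - ii]  # same offsets in every window
        exp_ok = np.isfinite(exp_pix) & (exp_pix > 0)
        for s in range(0, n - w + 1, step):
            obs_pix = dense[s + ii, s + jj]
            valid = np.isfinite(obs_pix) & exp_ok
            n_missing = n_eligible - int(valid.sum())
            if n_missing >= max_missing_frac * n_eligible:
                continue
            density = float(np.mean(obs_pix[valid] / exp_pix[valid]))
            rows.append((chrom, s * res, (s + w) * res, density, int(valid.sum()), n_eligible))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "density", "n_valid", "n_eligible"]
    )


def window_coverage(table: pd.DataFrame, track: pd.DataFrame, how: str = "sum") -> np.ndarray:
    """Coverage value per density window (overlap-weighted sum or mean)."""
    out = np.empty(len(table))
    for chrom, sub in table.groupby("chrom", sort=False):
        vals = track_to_windows(
            track, chrom, sub["start"].to_numpy(), sub["end"].to_numpy(), how=how
        )
        out[sub.index.to_numpy()] = vals
    return out


def quantile_edges(values: np.ndarray, n_groups: int) -> np.ndarray:
    """Empirical quantile boundaries (n_groups + 1 edges, possibly tied)."""
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    return np.quantile(np.asarray(values, dtype=float), np.linspace(0, 1, n_groups + 1))


def assign_quantile_groups(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Group label per value from precomputed edges (ties collapse upward,
    leaving lower groups empty -- they are reported with n = 0)."""
    return np.searchsorted(edges[1:-1], np.asarray(values, dtype=float), side="right")


def bin_by_quantiles(
    table: pd.DataFrame,
    coverage: np.ndarray | pd.DataFrame,
    n_groups: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
    edges: np.ndarray | None = None,
    how: str = "sum",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Group windows by coverage quantiles; summarise density per group.

    ``coverage`` is either a per-window array or a coverage-track DataFrame
    (reduced with ``how``).  Pass ``edges`` from another condition's call to
    bin this table by that condition's occupancy (cross-condition mode).
    Returns (summary table, edges); the summary has one row per group with
    the group mean, percentile-bootstrap 95% CI and window count (empty
    groups are reported with n = 0).
    """
    if isinstance(coverage, pd.DataFrame):
        coverage = window_coverage(table, coverage, how=how)
    coverage = np.asarray(coverage, dtype=float)
    if len(coverage) != len(table):
        raise ValueError("coverage length does not match the window table")
    if edges is None:
        edges = quantile_edges(coverage, n_groups)
    n_groups = len(edges) - 1
    labels = assign_quantile_groups(coverage, edges)
    density = table["density"].to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        sel = density[labels == g]
        if len(sel) == 0:
            rows.append((g, edges[g], edges[g + 1], 0, np.nan, np.nan, np.nan))
            continue
        mean = float(sel.mean())
        boots = rng.choice(sel, size=(n_boot, len(sel)), replace=True).mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append((g, edges[g], edges[g + 1], len(sel), mean, float(lo), float(hi)))
    summary = pd.DataFrame(
        rows, columns=["group", "cov_lo", "cov_hi", "n", "mean", "ci_lo", "ci_hi"]
    )
    return summary, edges
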