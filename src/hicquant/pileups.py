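"""Averaged observed/expected interaction maps ("pileups").

A pileup accumulates, over many feature-centred square windows, the dense
balanced observed values and the distance-decay expected values, then
divides the summed observed by the summed expected (sum-then-divide, *not*
the mean of per-window ratios).  The centre-pixel value of the result is the
headline enrichment scalar.

Three variants: on-diagonal pairs between two region sets (e.g. CGI-CGI
interactions), loop-anchor pileups, and local rescaled pileups in which
variable-length on-diagonal windows are resized to a fixed grid before
averaging (mean of per-region resized obs/exp windows).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expected import ExpectedProfile, obs_exp_window
from .matrixio import BalancedContactMatrix, point_to_bin

__all__ = [
    "EmptyPileupError",
    "PileupConfig",
    "Pileup",
    "RescaledPileup",
    "pileup_pairs",
    "pileup_loops",
    "rescaled_pileup",
    "box_resample",
]


class EmptyPileupError(RuntimeError):
    """No eligible windows were accumulated."""


@dataclass
class PileupConfig:
    """Geometry and eligibility rules for fixed-size pileups.

    The window side is ``2 * flank / resolution + 1`` pixels (always odd);
    at the defaults (100 kb flank, 5 kb bins) that is a 41 x 41 pixel
    window spanning 205 kb.  ``min_separation`` defaults to
    ``2 * flank + resolution`` so windows never touch the main diagonal,
    which would otherwise let the steep decay gradient dominate the average.
    """

    flank_bp: int = 100_000
    resolution: int = 5000
    min_separation: int | None = None
    max_separation: int | None = None
    symmetrize: bool | None = None  # None = auto (on when A is B)

    def __post_init__(self):
        if self.flank_bp % self.resolution != 0:
            raise ValueError("flank must be a multiple of the resolution")
        if self.min_separation is None:
            self.min_separation = 2 * self.flank_bp + self.resolution

    @property
    def flank_bins(self) -> int:
        return self.flank_bp // self.resolution

    @property
    def side(self) -> int:
        return 2 * self.flank_bins + 1


@dataclass
class Pileup:
    """Accumulated observed-sum / expected-sum windows."""

    obs_sum: np.ndarray
    exp_sum: np.ndarray
    valid_count: np.ndarray
    n: int
    n_skipped: int
    config: PileupConfig

    @property
    def enrichment(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.exp_sum > 0, self.obs_sum / self.exp_sum, np.nan)

    @property
    def center_enrichment(self) -> float:
        c = self.config.flank_bins
        return float(self.enrichment[c, c])


def _snap_midpoints(regions: pd.DataFrame, resolution: int) -> pd.DataFrame:
    mids = (regions["start"].to_numpy() + regions["end"].to_numpy()) / 2
    bins = np.fromiter(
        (point_to_bin(m, resolution) for m in mids), dtype=np.int64, count=len(mids)
    )
    return pd.DataFrame({"chrom": regions["chrom"].to_numpy(), "bin": bins})


def _eligible_pairs(
    snapA: pd.DataFrame,
    snapB: pd.DataFrame,
    same_set: bool,
    cfg: PileupConfig,
    n_bins: dict[str, int],
) -> list[tuple[str, int, int]]:
    """Cis (A-anchor, B-anchor) bin pairs within the separation band.

    For two distinct sets each cross pair is taken once in each orientation
    it occurs (rows on the A anchor), so pileup(A, B) is the exact transpose
    of pileup(B, A).  When A and B are the same set, each unordered pair is
    taken once, oriented a < b.
    """
    pairs = []
    min_sep = cfg.min_separation
    max_sep = cfg.max_separation
    res = cfg.resolution
    for chrom, subA in snapA.groupby("chrom", sort=False):
        if chrom not in n_bins:
            continue
        subB = snapB[snapB["chrom"] == chrom]
        for a in subA["bin"].to_numpy():
            for b in subB["bin"].to_numpy():
                if same_set and a >= b:
                    continue
                if a == b:
                    continue
                sep = abs(b - a) * res
                if sep < min_sep or (max_sep is not None and sep > max_sep):
                    continue
                pairs.append((chrom, int(a), int(b)))
    return pairs


def _accumulate(
    matrix: BalancedContactMatrix,
    pairs: list[tuple[str, int, int]],
    expected: ExpectedProfile,
    cfg: PileupConfig,
) -> Pileup:
    f = cfg.flank_bins
    side = cfg.side
    obs_sum = np.zeros((side, side))
    exp_sum = np.zeros((side, side))
    count = np.zeros((side, side), dtype=np.int64)
    n = 0
    n_skipped = 0
    for chrom, a, b in pairs:
        nb = matrix.bins.n_bins(chrom)
        if min(a, b) - f < 0 or max(a, b) + f >= nb:
            n_skipped += 1  # window would cross a chromosome edge
            continue
        obs, exp, valid = obs_exp_window(
            matrix, chrom, (a - f, a + f + 1), (b - f, b + f + 1), expected
        )
        obs_sum[valid] += obs[valid]
        exp_sum[valid] += exp[valid]
        count[valid] += 1
        n += 1
    if n == 0:
        raise EmptyPileupError(
            f"no eligible windows accumulated ({len(pairs)} candidate pairs, "
            f"{n_skipped} skipped at chromosome edges)"
        )
    return Pileup(obs_sum, exp_sum, count, n, n_skipped, cfg)


def _maybe_symmetrize(pile: Pileup, symmetrize: bool) -> Pileup:
    if symmetrize:
        pile.obs_sum = (pile.obs_sum + pile.obs_sum.T) / 2
        pile.exp_sum = (pile.exp_sum + pile.exp_sum.T) / 2
        pile.valid_count = (pile.valid_count + pile.valid_count.T) // 2
    return pile


def pileup_pairs(
    matrix: BalancedContactMatrix,
    regionsA: pd.DataFrame,
    regionsB: pd.DataFrame,
    expected: ExpectedProfile,
    config: PileupConfig | None = None,
) -> Pileup:
    """Pileup over all cis pairs between two region sets.

    Regions are snapped to bins by interval midpoint.  Windows crossing a
    chromosome edge are skipped entirely (never NaN-padded) and counted, so
    every pixel averages the same number of windows.
    """
    cfg = config if config is not None else PileupConfig()
    same = regionsA is regionsB or (
        len(regionsA) == len(regionsB)
        and regionsA[["chrom", "start", "end"]].reset_index(drop=True).equals(
            regionsB[["chrom", "start", "end"]].reset_index(drop=True)
        )
    )
    snapA = _snap_midpoints(regionsA, cfg.resolution)
    snapB = snapA if same else _snap_midpoints(regionsB, cfg.resolution)
    n_bins = {c: matrix.bins.n_bins(c) for c in matrix.chroms}
    pairs = _eligible_pairs(snapA, snapB, same, cfg, n_bins)
    pairs.sort()  # independent of region input order
    pile = _accumulate(matrix, pairs, expected, cfg)
    symmetrize = cfg.symmetrize if cfg.symmetrize is not None else same
    return _maybe_symmetrize(pile, symmetrize)


def pileup_loops(
    matrix: BalancedContactMatrix,
    loops: pd.DataFrame,
    expected: ExpectedProfile,
    config: PileupConfig | None = None,
) -> Pileup:
    """Pileup at loop calls: anchor midpoints are the two window centres."""
    cfg = config if config is not None else PileupConfig()
    res = cfg.resolution
    pairs = []
    for _, row in loops.iterrows():
        a = point_to_bin((row["start1"] + row["end1"]) / 2, res)
        b = point_to_bin((row["start2"] + row["end2"]) / 2, res)
        if row["chrom1"] != row["chrom2"]:
            continue
        if a == b:
            continue
        a, b = min(a, b), max(a, b)
        sep = (b - a) * res
        if sep < cfg.min_separation or (
            cfg.max_separation is not None and sep > cfg.max_separation
        ):
            continue
        pairs.append((str(row["chrom1"]), a, b))
    pairs.sort()
    pile = _accumulate(matrix, pairs, expected, cfg)
    symmetrize = cfg.symmetrize if cfg.symmetrize is not None else False
    return _maybe_symmetrize(pile, symmetrize)


# ---------------------------------------------------------------------------
# Rescaled pileups over variable-length regions
# ---------------------------------------------------------------------------

def box_resample(a: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Area-weighted (box) resampling that ignores NaN.

    Each output pixel is the overlap-weighted mean of the finite input
    pixels it covers; all-NaN footprints yield NaN.
    """

    def weights(n_in: int, n_out: int) -> np.ndarray:
        edges = np.linspace(0, n_in, n_out + 1)
        W = np.zeros((n_out, n_in))
        for o in range(n_out):
            lo, hi = edges[o], edges[o + 1]
            k0, k1 = int(math.floor(lo)), int(math.ceil(hi))
            for k in range(k0, min(k1, n_in)):
                W[o, k] = min(hi, k + 1) - max(lo, k)
        return W

    Wr = weights(a.shape[0], out_shape[0])
    Wc = weights(a.shape[1], out_shape[1])
    finite = np.isfinite(a)
    num = Wr @ np.where(finite, a, 0.0) @ Wc.T
    den = Wr @ finite.astype(float) @ Wc.T
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)


@dataclass
class RescaledPileup:
    """Pixelwise mean of per-region resized obs/exp windows."""

    grid_sum: np.ndarray
    grid_count: np.ndarray
    n: int
    n_skipped: int
    grid_side: int
    flank_factor: float

    @property
    def grid(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.grid_count > 0, self.grid_sum / np.maximum(self.grid_count, 1), np.nan)

    def central_block(self) -> tuple[int, int]:
        """Half-open grid index range covered by the rescaled region itself."""
        g, ff = self.grid_side, self.flank_factor
        lo = int(round(g * ff / (1 + 2 * ff)))
        hi = int(round(g * (1 + ff) / (1 + 2 * ff)))
        return lo, hi

    @property
    def central_block_mean(self) -> float:
        lo, hi = self.central_block()
        return float(np.nanmean(self.grid[lo:hi, lo:hi]))


def rescaled_pileup(
    matrix: BalancedContactMatrix,
    regions: pd.DataFrame,
    expected: ExpectedProfile,
    grid_side: int = 33,
    flank_factor: float = 1.0,
    min_length_bp: int = 10_000,
) -> RescaledPileup:
    """Average obs/exp over variable-length on-diagonal regions.

    Each region of length L is expanded to the square window
    ``[start - flank_factor * L, end + flank_factor * L)^2`` (in bins), its
    obs/exp computed at base resolution, box-resampled (NaN-ignoring) to a
    fixed ``grid_side`` grid, and averaged pixelwise across regions.
    Regions shorter than ``min_length_bp`` or whose window leaves the
    chromosome are skipped and counted.
    """
    if grid_side % 2 == 0:
        raise ValueError("grid_side must be odd")
    res = matrix.bins.resolution
    grid_sum = np.zeros((grid_side, grid_side))
    grid_count = np.zeros((grid_side, grid_side), dtype=np.int64)
    n = 0
    n_skipped = 0
    for _, row in regions.iterrows():
        chrom = str(row["chrom"])
        start, end = int(row["start"]), int(row["end"])
        if end - start < min_length_bp:
            n_skipped += 1
            continue
        nb = matrix.bins.n_bins(chrom)
        b0 = start // res
        b1 = -(-end // res)
        L = b1 - b0
        fb = int(round(flank_factor * L))
        w0, w1 = b0 - fb, b1 + fb
        if w0 < 0 or w1 > nb or L < 1:
            n_skipped += 1
            continue
        obs, exp, valid = obs_exp_window(matrix, chrom, (w0, w1), (w0, w1), expected)
        with np.errstate(invalid="ignore", divide="ignore"):
            oe = np.where(valid, obs / exp, np.nan)
        resized = box_resample(oe, (grid_side, grid_side))
        finite = np.isfinite(resized)
        grid_sum[finite] += resized[finite]
        grid_count[finite] += 1
        n += 1
    if n == 0:
        raise EmptyPileupError(
            f"no regions accumulated ({n_skipped} skipped of {len(regions)})"
        )
    return RescaledPileup(grid_sum, grid_count, n, n_skipped, grid_side, flank_factor)
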