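"""Containers and I/O for binned cis Hi-C contact maps.

Coordinates are 0-based and half-open throughout (BED convention); a bin
index is ``floor(position / resolution)``.  Contact matrices are stored per
chromosome as sparse upper-triangular count matrices (``i <= j``); the
symmetric matrix is implied.  Balanced values are ``count(i, j) * w_i * w_j``
with per-bin weights ``w`` from iterative correction, and are NaN wherever a
masked (filtered) bin is involved.

Only cis (within-chromosome) contacts are modelled: every downstream
statistic in this package is a cis quantity.  Upstream pair-level filtering
(mapping quality, duplicate removal) is an input contract, not re-checked
here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "FormatError",
    "BalancingError",
    "GenomeBins",
    "RawContactMatrix",
    "BalanceStats",
    "BalanceWeights",
    "BalancedContactMatrix",
    "read_chromsizes",
    "write_chromsizes",
    "read_contacts",
    "write_contacts",
    "balance_ic",
    "balance",
    "aggregate",
    "aggregate_raw",
    "point_to_bin",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "read_bedgraph",
    "write_bedgraph",
    "track_to_windows",
    "track_to_bins",
]


class FormatError(ValueError):
    """Malformed input: bad coordinates, duplicate pixels, unknown chromosome."""


class BalancingError(RuntimeError):
    """Matrix balancing could not produce usable weights."""


def point_to_bin(pos: float, resolution: int) -> int:
    """Bin index containing a genomic point; ties at an exact bin boundary
    go to the left bin."""
    b = int(pos // resolution)
    if pos > 0 and pos % resolution == 0:
        b -= 1
    return b


class GenomeBins:
    """Uniform bins tiling an ordered set of chromosomes.

    All bins on a chromosome have width ``resolution`` except possibly the
    last, which is truncated at the chromosome end.
    """

    def __init__(self, chromsizes: Mapping[str, int], resolution: int):
        resolution = int(resolution)
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        self.chromsizes: dict[str, int] = {}
        for name, length in dict(chromsizes).items():
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            self.chromsizes[str(name)] = length
        self.resolution = resolution

    @property
    def chroms(self) -> list[str]:
        return list(self.chromsizes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromsizes

    def n_bins(self, chrom: str) -> int:
        return -(-self.chromsizes[chrom] // self.resolution)

    def bins_table(self, chrom: str | None = None) -> pd.DataFrame:
        chroms = [chrom] if chrom is not None else self.chroms
        frames = []
        for c in chroms:
            n = self.n_bins(c)
            starts = np.arange(n, dtype=np.int64) * self.resolution
            ends = np.minimum(starts + self.resolution, self.chromsizes[c])
            frames.append(pd.DataFrame({"chrom": c, "start": starts, "end": ends}))
        return pd.concat(frames, ignore_index=True)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenomeBins)
            and self.resolution == other.resolution
            and self.chromsizes == other.chromsizes
        )

    def __repr__(self) -> str:
        return f"GenomeBins({len(self.chromsizes)} chroms, resolution={self.resolution})"


def read_chromsizes(path) -> dict[str, int]:
    """Two-column TSV (name, length) -> ordered mapping."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "length"], comment="#")
    if df.isna().any().any():
        raise FormatError(f"malformed chrom.sizes file: {path}")
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def write_chromsizes(chromsizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in chromsizes.items():
            fh.write(f"{name}\t{int(length)}\n")


class RawContactMatrix:
    """Per-chromosome sparse upper-triangular cis contact counts."""

    def __init__(
        self,
        bins: GenomeBins,
        counts: Mapping[str, sp.spmatrix],
        trans_dropped: int = 0,
    ):
        self.bins = bins
        self._counts: dict[str, sp.csr_matrix] = {}
        for chrom in bins.chroms:
            n = bins.n_bins(chrom)
            mat = counts.get(chrom)
            if mat is None:
                mat = sp.csr_matrix((n, n))
            mat = sp.csr_matrix(mat)
            if mat.shape != (n, n):
                raise ValueError(f"matrix for {chrom} has shape {mat.shape}, expected {(n, n)}")
            coo = mat.tocoo()
            if np.any(coo.row > coo.col):
                raise ValueError(f"matrix for {chrom} has entries below the diagonal")
            if np.any(~np.isfinite(coo.data)) or np.any(coo.data < 0):
                raise ValueError(f"matrix for {chrom} has negative or non-finite counts")
            mat.sum_duplicates()
            self._counts[chrom] = mat
        self.trans_dropped = int(trans_dropped)
        self._sym_cache: dict[str, sp.csr_matrix] = {}

    @property
    def chroms(self) -> list[str]:
        return self.bins.chroms

    def counts(self, chrom: str) -> sp.csr_matrix:
        if chrom not in self._counts:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self._counts[chrom]

    def symmetric(self, chrom: str) -> sp.csr_matrix:
        """Full symmetric matrix U + U.T - diag(U), cached."""
        if chrom not in self._sym_cache:
            upper = self.counts(chrom)
            diag = sp.diags(upper.diagonal())
            self._sym_cache[chrom] = (upper + upper.T - diag).tocsr()
        return self._sym_cache[chrom]

    def total(self) -> float:
        return float(sum(m.sum() for m in self._counts.values()))


def _parse_triplets(path) -> tuple[pd.DataFrame, int]:
    """Read a bin-pair triplet file; returns (cis table, n trans dropped).

    Accepts the 4-column dialect ``chrom start_i start_j count`` and the
    5-column dialect ``chrom1 start_i chrom2 start_j count`` (trans rows in
    the latter are counted and dropped).
    """
    ncols = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ncols = len(line.split())
                break
    if ncols is None:
        return pd.DataFrame(columns=["chrom", "start1", "start2", "count"]), 0
    if ncols == 4:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#",
            names=["chrom", "start1", "start2", "count"],
        )
        trans = 0
    elif ncols == 5:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#",
            names=["chrom", "start1", "chrom2", "start2", "count"],
        )
        is_cis = df["chrom"].astype(str) == df["chrom2"].astype(str)
        trans = int((~is_cis).sum())
        df = df.loc[is_cis, ["chrom", "start1", "start2", "count"]].reset_index(drop=True)
    else:
        raise FormatError(f"expected 4 or 5 columns in triplet file, got {ncols}")
    return df, trans


def read_contacts(triplet_file, chromsizes, resolution: int) -> RawContactMatrix:
    """Load a bin-pair triplet text file into a RawContactMatrix.

    ``chromsizes`` may be a path to a chrom.sizes file or a mapping.
    Bin starts must be multiples of ``resolution``; entries given as (j, i)
    with j > i are stored as (i, j).  Duplicate (i, j) keys are an error.
    """
    if not isinstance(chromsizes, Mapping):
        chromsizes = read_chromsizes(chromsizes)
    bins = GenomeBins(chromsizes, resolution)
    df, trans = _parse_triplets(triplet_file)
    if trans:
        warnings.warn(f"dropped {trans} trans contact entries (cis-only analysis)")
    if len(df) == 0:
        return RawContactMatrix(bins, {}, trans_dropped=trans)

    df["chrom"] = df["chrom"].astype(str)
    unknown = set(df["chrom"]) - set(bins.chroms)
    if unknown:
        raise FormatError(f"unknown chromosome(s) in contacts: {sorted(unknown)}")
    for col in ("start1", "start2"):
        vals = df[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise FormatError(f"non-integer bin start in column {col}")
        if np.any(vals < 0) or np.any(vals % resolution != 0):
            raise FormatError(f"bin start not a non-negative multiple of {resolution} in {col}")
    cnt = df["count"].to_numpy()
    if not np.issubdtype(cnt.dtype, np.number) or np.any(~np.isfinite(cnt.astype(float))) or np.any(cnt < 0):
        raise FormatError("counts must be finite and non-negative")

    i = (df["start1"] // resolution).to_numpy(dtype=np.int64)
    j = (df["start2"] // resolution).to_numpy(dtype=np.int64)
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)

    key = pd.DataFrame({"chrom": df["chrom"], "i": lo, "j": hi})
    dup = key.duplicated()
    if dup.any():
        first = key[dup].iloc[0]
        raise FormatError(
            f"duplicate pixel ({first['chrom']}, bin {first['i']}, bin {first['j']}) in input"
        )

    mats = {}
    for chrom, sub in key.assign(count=cnt).groupby("chrom", sort=False):
        n = bins.n_bins(chrom)
        if np.any(sub["j"].to_numpy() >= n):
            raise FormatError(f"bin start beyond chromosome end on {chrom}")
        mats[chrom] = sp.csr_matrix(
            (sub["count"].to_numpy(dtype=float), (sub["i"].to_numpy(), sub["j"].to_numpy())),
            shape=(n, n),
        )
    return RawContactMatrix(bins, mats, trans_dropped=trans)


def write_contacts(raw: RawContactMatrix, path) -> None:
    """Write the upper-triangular entries as a 4-column triplet file."""
    res = raw.bins.resolution
    with open(path, "w") as fh:
        for chrom in raw.chroms:
            coo = raw.counts(chrom).tocoo()
            order = np.lexsort((coo.col, coo.row))
            for r, c, v in zip(coo.row[order], coo.col[order], coo.data[order]):
                v = int(v) if float(v).is_integer() else v
                fh.write(f"{chrom}\t{r * res}\t{c * res}\t{v}\n")


# ---------------------------------------------------------------------------
# Iterative-correction balancing
# ---------------------------------------------------------------------------

@dataclass
class BalanceStats:
    n_iter: int
    converged: bool
    cv: float
    n_masked: int


class BalanceWeights:
    """Per-bin multiplicative balancing weights; NaN marks a masked bin."""

    def __init__(self, weights: dict[str, np.ndarray], stats: dict[str, BalanceStats]):
        self.weights = weights
        self.stats = stats

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.weights[chrom]

    def valid(self, chrom: str) -> np.ndarray:
        return np.isfinite(self.weights[chrom])


def balance_ic(
    raw: RawContactMatrix,
    max_iter: int = 300,
    tol: float = 1e-5,
    min_nnz_frac: float = 0.02,
) -> BalanceWeights:
    """Iterative correction (ICE) per chromosome.

    Bins whose fraction of nonzero cis pixels falls below ``min_nnz_frac``
    (or whose marginal is zero) are masked.  Remaining weights are iterated
    until the coefficient of variation of the balanced marginals drops below
    ``tol``, then rescaled so the mean balanced marginal is 1.
    """
    weights: dict[str, np.ndarray] = {}
    stats: dict[str, BalanceStats] = {}
    for chrom in raw.chroms:
        M = raw.symmetric(chrom).astype(float)
        M.eliminate_zeros()
        n = M.shape[0]
        nnz_frac = M.getnnz(axis=1) / n
        marg0 = np.asarray(M.sum(axis=1)).ravel()
        mask = (nnz_frac < min_nnz_frac) | (marg0 <= 0)
        if int((~mask).sum()) < 2:
            raise BalancingError(
                f"chromosome {chrom}: fewer than 2 bins pass the coverage filter"
            )
        w = np.ones(n)
        w[mask] = 0.0
        converged = False
        cv = np.inf
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            s = w * (M @ w)
            su = s[~mask]
            m = su.mean()
            cv = float(su.std() / m)
            if cv < tol:
                converged = True
                break
            w[~mask] *= m / su
        if not converged:
            warnings.warn(
                f"balancing on {chrom} did not converge in {max_iter} iterations (cv={cv:.2e})"
            )
        s = w * (M @ w)
        m = s[~mask].mean()
        if m > 0:
            w /= math.sqrt(m)
        arr = w.copy()
        arr[mask] = np.nan
        weights[chrom] = arr
        stats[chrom] = BalanceStats(n_iter, converged, cv, int(mask.sum()))
    return BalanceWeights(weights, stats)


class BalancedContactMatrix:
    """Raw counts plus balancing weights; balanced values on demand.

    ``balanced(i, j) = count(i, j) * w_i * w_j``, NaN wherever either bin is
    masked.  Absent sparse entries are zeros, not missing data.
    """

    def __init__(self, raw: RawContactMatrix, weights: BalanceWeights):
        self.raw = raw
        self.weights = weights

    @property
    def bins(self) -> GenomeBins:
        return self.raw.bins

    @property
    def chroms(self) -> list[str]:
        return self.raw.chroms

    def valid_bins(self, chrom: str) -> np.ndarray:
        return self.weights.valid(chrom)

    def balanced_dense(
        self,
        chrom: str,
        rows: tuple[int, int] | None = None,
        cols: tuple[int, int] | None = None,
    ) -> np.ndarray:
        """Dense balanced submatrix over half-open bin ranges (NaN at masked)."""
        n = self.bins.n_bins(chrom)
        r0, r1 = rows if rows is not None else (0, n)
        c0, c1 = cols if cols is not None else (0, n)
        if not (0 <= r0 <= r1 <= n and 0 <= c0 <= c1 <= n):
            raise ValueError(
                f"bin range rows={rows} cols={cols} out of bounds for {chrom} ({n} bins)"
            )
        sub = self.raw.symmetric(chrom)[r0:r1, c0:c1].toarray()
        w = self.weights[chrom]
        return sub * w[r0:r1, None] * w[None, c0:c1]

    def balanced_upper_entries(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(i, j, balanced value) for stored upper-triangular entries."""
        coo = self.raw.counts(chrom).tocoo()
        w = self.weights[chrom]
        return coo.row, coo.col, coo.data * w[coo.row] * w[coo.col]


def balance(raw: RawContactMatrix, **kwargs) -> BalancedContactMatrix:
    return BalancedContactMatrix(raw, balance_ic(raw, **kwargs))


def aggregate_raw(raw: RawContactMatrix, factor: int) -> RawContactMatrix:
    """Sum raw counts into coarse bins of ``factor`` times the resolution."""
    if int(factor) != factor or factor < 2:
        raise ValueError("aggregation factor must be an integer >= 2")
    factor = int(factor)
    coarse = GenomeBins(raw.bins.chromsizes, raw.bins.resolution * factor)
    mats = {}
    for chrom in raw.chroms:
        coo = raw.counts(chrom).tocoo()
        n = coarse.n_bins(chrom)
        mats[chrom] = sp.csr_matrix(
            (coo.data, (coo.row // factor, coo.col // factor)), shape=(n, n)
        )
    return RawContactMatrix(coarse, mats, trans_dropped=raw.trans_dropped)


def aggregate(matrix: BalancedContactMatrix, factor: int, **balance_kwargs) -> BalancedContactMatrix:
    """Coarsen raw counts by an integer factor and re-balance."""
    return balance(aggregate_raw(matrix.raw, factor), **balance_kwargs)


# ---------------------------------------------------------------------------
# Region sets, loops and coverage tracks (plain DataFrames)
# ---------------------------------------------------------------------------

def _check_intervals(df: pd.DataFrame, what: str, start="start", end="end") -> None:
    if len(df) and np.any(df[start].to_numpy() >= df[end].to_numpy()):
        raise FormatError(f"{what}: interval with start >= end")
    if len(df) and np.any(df[start].to_numpy() < 0):
        raise FormatError(f"{what}: negative coordinate")


def read_bed(path) -> pd.DataFrame:
    """BED 3-6 -> DataFrame(chrom, start, end[, name[, score]])."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if df.shape[1] < 3:
        raise FormatError(f"BED file {path} has fewer than 3 columns")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    _check_intervals(df, f"BED {path}")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score") if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path, cis_only: bool = True) -> pd.DataFrame:
    """BEDPE 6-7 -> DataFrame(chrom1, start1, end1, chrom2, start2, end2[, name]).

    Anchors are reordered so the first anchor midpoint is the smaller one.
    Trans records raise FormatError when ``cis_only`` (every analysis here is cis).
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if df.shape[1] < 6:
        raise FormatError(f"BEDPE file {path} has fewer than 6 columns")
    names = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name"][: df.shape[1]]
    df.columns = names
    for c in ("chrom1", "chrom2"):
        df[c] = df[c].astype(str)
    for c in ("start1", "end1", "start2", "end2"):
        df[c] = df[c].astype(np.int64)
    _check_intervals(df, f"BEDPE {path}", "start1", "end1")
    _check_intervals(df, f"BEDPE {path}", "start2", "end2")
    if cis_only and len(df) and np.any(df["chrom1"] != df["chrom2"]):
        raise FormatError(f"BEDPE {path}: trans loop records are not supported")
    if len(df):
        mid1 = (df["start1"] + df["end1"]) / 2
        mid2 = (df["start2"] + df["end2"]) / 2
        flip = (mid1 > mid2).to_numpy()
        if flip.any():
            a = df.loc[flip, ["start1", "end1"]].to_numpy()
            b = df.loc[flip, ["start2", "end2"]].to_numpy()
            df.loc[flip, ["start1", "end1"]] = b
            df.loc[flip, ["start2", "end2"]] = a
    return df


def write_bedpe(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom1", "start1", "end1", "chrom2", "start2", "end2", "name")
            if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    """bedGraph -> DataFrame(chrom, start, end, value); intervals must not overlap."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["value"] = df["value"].astype(float)
    _check_intervals(df, f"bedGraph {path}")
    if np.any(~np.isfinite(df["value"].to_numpy())):
        raise FormatError(f"bedGraph {path}: non-finite value")
    for chrom, sub in df.groupby("chrom", sort=False):
        s = sub.sort_values("start")
        if np.any(s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]):
            raise FormatError(f"bedGraph {path}: overlapping intervals on {chrom}")
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


def track_to_windows(
    track: pd.DataFrame,
    chrom: str,
    starts: np.ndarray,
    ends: np.ndarray,
    how: str = "sum",
) -> np.ndarray:
    """Reduce a coverage track onto windows.

    ``how='sum'`` gives the overlap-weighted sum (read-density semantics,
    value x overlap bp); ``how='mean'`` the overlap-weighted mean (fraction
    tracks such as GC content).
    """
    if how not in ("sum", "mean"):
        raise ValueError("how must be 'sum' or 'mean'")
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    acc = np.zeros(len(starts))
    cov = np.zeros(len(starts))
    sub = track[track["chrom"] == chrom]
    ts = sub["start"].to_numpy()
    te = sub["end"].to_numpy()
    tv = sub["value"].to_numpy()
    # windows are sorted and equal-length in all callers
    for s, e, v in zip(ts, te, tv):
        lo = int(np.searchsorted(ends, s, side="right"))
        hi = int(np.searchsorted(starts, e, side="left"))
        if lo >= hi:
            continue
        ov = np.minimum(ends[lo:hi], e) - np.maximum(starts[lo:hi], s)
        acc[lo:hi] += v * ov
        cov[lo:hi] += ov
    if how == "sum":
        return acc
    with np.errstate(invalid="ignore"):
        return np.where(cov > 0, acc / np.maximum(cov, 1), np.nan)


def track_to_bins(track: pd.DataFrame, bins: GenomeBins, chrom: str, how: str = "mean") -> np.ndarray:
    """Reduce a coverage track onto the uniform bins of one chromosome."""
    n = bins.n_bins(chrom)
    starts = np.arange(n, dtype=np.int64) * bins.resolution
    ends = np.minimum(starts + bins.resolution, bins.chromsizes[chrom])
    return track_to_windows(track, chrom, starts, ends, how=how)
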