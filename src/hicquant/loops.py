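"""Classification of loop calls by anchor proximity to ChIP peaks.

A loop is associated with a peak set iff *both* anchor points (anchor
interval midpoints) lie within a tolerance (default 5 kb, inclusive) of some
peak; a missing peak on either side means no association.  The two flags
(CTCF, RING1B) partition loops into CTCF_only / RING1B_only / both /
neither, and per-class pileups quantify how each class behaves across
conditions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .expected import ExpectedProfile
from .matrixio import BalancedContactMatrix
from .pileups import Pileup, PileupConfig, pileup_loops

__all__ = ["classify_loops", "point_to_peak_gap", "loop_class_pileups", "LOOP_CLASSES"]

LOOP_CLASSES = ("CTCF_only", "RING1B_only", "both", "neither")


def _merged_intervals(peaks: pd.DataFrame, chrom: str) -> tuple[np.ndarray, np.ndarray]:
    sub = peaks[peaks["chrom"] == chrom].sort_values("start")
    starts, ends = [], []
    for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
        if starts and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def point_to_peak_gap(points: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Gap (bp) from each point to the nearest interval; 0 inside an interval.

    For a point right of an interval the gap is measured from the interval's
    last base, so a point at ``end - 1 + g`` has gap g (widen-by-tolerance
    then test containment semantics).
    """
    points = np.asarray(points, dtype=np.int64)
    if len(starts) == 0:
        return np.full(len(points), np.iinfo(np.int64).max, dtype=np.int64)
    idx = np.searchsorted(starts, points, side="right") - 1
    gap = np.full(len(points), np.iinfo(np.int64).max, dtype=np.int64)
    has_left = idx >= 0
    left_gap = np.where(
        has_left & (points < ends[np.clip(idx, 0, None)]),
        0,
        np.where(has_left, points - (ends[np.clip(idx, 0, None)] - 1), np.iinfo(np.int64).max),
    )
    nxt = idx + 1
    has_right = nxt < len(starts)
    right_gap = np.where(
        has_right, starts[np.clip(nxt, None, len(starts) - 1)] - points, np.iinfo(np.int64).max
    )
    return np.minimum(np.minimum(left_gap, gap), right_gap)


def _associated(loops: pd.DataFrame, peaks: pd.DataFrame, tolerance_bp: int) -> np.ndarray:
    if len(peaks) == 0:
        warnings.warn("empty peak set: all association flags are False")
        return np.zeros(len(loops), dtype=bool)
    flags = np.zeros(len(loops), dtype=bool)
    mid1 = ((loops["start1"] + loops["end1"]) // 2).to_numpy()
    mid2 = ((loops["start2"] + loops["end2"]) // 2).to_numpy()
    for chrom in loops["chrom1"].unique():
        sel = (loops["chrom1"] == chrom).to_numpy()
        starts, ends = _merged_intervals(peaks, chrom)
        g1 = point_to_peak_gap(mid1[sel], starts, ends)
        g2 = point_to_peak_gap(mid2[sel], starts, ends)
        flags[sel] = (g1 <= tolerance_bp) & (g2 <= tolerance_bp)
    return flags


def classify_loops(
    loops: pd.DataFrame,
    ctcf: pd.DataFrame,
    ring1b: pd.DataFrame,
    tolerance_bp: int = 5000,
) -> pd.DataFrame:
    """Flag each loop's association with CTCF and RING1B peaks and derive
    the four-way class.  The tolerance is inclusive: a 5,000 bp gap on both
    ends associates, 5,001 bp does not."""
    out = loops.copy().reset_index(drop=True)
    out["ctcf_assoc"] = _associated(out, ctcf, tolerance_bp)
    out["ring1b_assoc"] = _associated(out, ring1b, tolerance_bp)
    klass = np.select(
        [
            out["ctcf_assoc"] & ~out["ring1b_assoc"],
            ~out["ctcf_assoc"] & out["ring1b_assoc"],
            out["ctcf_assoc"] & out["ring1b_assoc"],
        ],
        ["CTCF_only", "RING1B_only", "both"],
        default="neither",
    )
    out["loop_class"] = klass
    return out


def loop_class_pileups(
    matrix: BalancedContactMatrix,
    classified: pd.DataFrame,
    expected: ExpectedProfile,
    config: PileupConfig | None = None,
    classes: tuple[str, ...] = ("all",) + LOOP_CLASSES,
) -> dict[str, Pileup | None]:
    """Per-class loop pileups ('all' plus the four association classes).

    Empty classes map to None (reported, never an error)."""
    out: dict[str, Pileup | None] = {}
    for klass in classes:
        sub = classified if klass == "all" else classified[classified["loop_class"] == klass]
        if len(sub) == 0:
            out[klass] = None
            continue
        out[klass] = pileup_loops(matrix, sub, expected, config)
    return out
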