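"""Distance-decay expected values and observed/expected transforms.

The expected value at diagonal offset ``d`` is the mean balanced value over
all pixel pairs ``(i, i + d)`` on a chromosome where both bins are unmasked.
Zero pixels (absent sparse entries) count toward the mean -- in a balanced
matrix an absent entry is an observed zero, not missing data; only pixels
touching a masked bin are excluded.  No smoothing is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrixio import BalancedContactMatrix

__all__ = ["ExpectedProfile", "compute_expected", "obs_exp_window"]


@dataclass
class ExpectedProfile:
    """Per-chromosome mean balanced value and valid-pixel count per diagonal."""

    values: dict[str, np.ndarray] = field(default_factory=dict)
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def expected(self, chrom: str) -> np.ndarray:
        if chrom not in self.values:
            raise KeyError(f"no expected profile for chromosome {chrom!r}")
        return self.values[chrom]

    def expected_matrix(self, chrom: str, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Dense expected submatrix: expected[|i - j|] over given bin indices."""
        exp = self.expected(chrom)
        offsets = np.abs(np.asarray(rows)[:, None] - np.asarray(cols)[None, :])
        return exp[offsets]

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for chrom, vals in self.values.items():
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "diag": np.arange(len(vals)),
                        "n_valid": self.counts[chrom],
                        "expected": vals,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def compute_expected(matrix: BalancedContactMatrix, chrom: str | None = None) -> ExpectedProfile:
    """Per-diagonal mean balanced value for one chromosome (or all).

    ``expected[d]`` is NaN where no unmasked pixel pair exists at offset d.
    """
    chroms = [chrom] if chrom is not None else matrix.chroms
    profile = ExpectedProfile()
    for c in chroms:
        if c not in matrix.bins:
            raise KeyError(f"unknown chromosome {c!r}")
        n = matrix.bins.n_bins(c)
        valid = matrix.valid_bins(c)
        i, j, b = matrix.balanced_upper_entries(c)
        keep = np.isfinite(b)
        sums = np.bincount((j - i)[keep], weights=b[keep], minlength=n).astype(float)
        cnts = np.empty(n, dtype=np.int64)
        cnts[0] = int(valid.sum())
        for d in range(1, n):
            cnts[d] = int(np.count_nonzero(valid[:-d] & valid[d:]))
        with np.errstate(invalid="ignore"):
            vals = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
        profile.values[c] = vals
        profile.counts[c] = cnts
    return profile


def obs_exp_window(
    matrix: BalancedContactMatrix,
    chrom: str,
    rows: tuple[int, int],
    cols: tuple[int, int],
    expected: ExpectedProfile,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense (observed, expected, valid-mask) for a rectangular bin window.

    Observed is the balanced submatrix (NaN at masked pixels); expected is
    ``expected[|i - j|]``; the mask is True where observed is finite and
    expected is defined and positive.  Ranges out of bounds raise ValueError
    (callers such as the pileup accumulators decide whether to skip).
    """
    obs = matrix.balanced_dense(chrom, rows, cols)
    exp = expected.expected_matrix(
        chrom, np.arange(rows[0], rows[1]), np.arange(cols[0], cols[1])
    )
    with np.errstate(invalid="ignore"):
        valid = np.isfinite(obs) & np.isfinite(exp) & (exp > 0)
    return obs, exp, valid
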