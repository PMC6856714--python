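"""Shared fixtures: desk-scale paired-condition simulations and toy matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import hicquant as hq

FIXTURE_SEED = 7


@dataclass
class SimBundle:
    spec: hq.SimulationSpec
    raw: hq.RawContactMatrix
    truth: hq.TruthTables
    matrix: hq.BalancedContactMatrix
    expected: hq.ExpectedProfile
    tracks: hq.SimulatedTracks


def make_bundle(spec: hq.SimulationSpec) -> SimBundle:
    raw, truth = hq.simulate_contact_map(spec)
    matrix = hq.balance(raw)
    expected = hq.compute_expected(matrix)
    tracks = hq.simulate_tracks(spec, truth)
    return SimBundle(spec, raw, truth, matrix, expected, tracks)


@pytest.fixture(scope="session")
def serum_bundle() -> SimBundle:
    """Default study conditions, serum-like."""
    return make_bundle(hq.default_spec(FIXTURE_SEED))


@pytest.fixture(scope="session")
def twoi_bundle() -> SimBundle:
    """Paired 2i-like condition with full polycomb depletion (rho = 0)."""
    return make_bundle(hq.default_spec(FIXTURE_SEED).paired("2i"))


@pytest.fixture(scope="session")
def small_bundle() -> SimBundle:
    """One 3 Mb chromosome, features scaled down -- fast unit-level checks."""
    spec = hq.default_spec(
        FIXTURE_SEED, n_chroms=1, chrom_length=3_000_000, total_count=8e5,
        n_polycomb_domains=4, n_cgi_anchors=10, n_ctcf_sites=12, n_ctcf_loops=15,
    )
    return make_bundle(spec)


def random_raw(seed: int, n_bins: int = 30, chrom: str = "chrA",
               resolution: int = 1000, density: float = 0.3) -> hq.RawContactMatrix:
    """Small random upper-triangular count matrix."""
    rng = np.random.default_rng(seed)
    bins = hq.GenomeBins({chrom: n_bins * resolution}, resolution)
    i, j = np.triu_indices(n_bins)
    keep = rng.random(len(i)) < density
    counts = rng.integers(1, 20, size=keep.sum())
    mat = sp.csr_matrix((counts.astype(float), (i[keep], j[keep])), shape=(n_bins, n_bins))
    return hq.RawContactMatrix(bins, {chrom: mat})


def uniform_balanced(n_bins: int = 40, value: float = 2.0, chrom: str = "chrA",
                     resolution: int = 1000) -> hq.BalancedContactMatrix:
    """Matrix whose balanced values are a constant on every pixel."""
    bins = hq.GenomeBins({chrom: n_bins * resolution}, resolution)
    i, j = np.triu_indices(n_bins)
    mat = sp.csr_matrix((np.full(len(i), value), (i, j)), shape=(n_bins, n_bins))
    raw = hq.RawContactMatrix(bins, {chrom: mat})
    w = hq.BalanceWeights({chrom: np.ones(n_bins)}, {})
    return hq.BalancedContactMatrix(raw, w)


def decay_balanced(n_bins: int = 40, chrom: str = "chrA",
                   resolution: int = 1000) -> hq.BalancedContactMatrix:
    """Matrix with balanced value exactly 1 / (|i-j| + 1)."""
    bins = hq.GenomeBins({chrom: n_bins * resolution}, resolution)
    i, j = np.triu_indices(n_bins)
    vals = 1.0 / (j - i + 1.0)
    mat = sp.csr_matrix((vals, (i, j)), shape=(n_bins, n_bins))
    raw = hq.RawContactMatrix(bins, {chrom: mat})
    w = hq.BalanceWeights({chrom: np.ones(n_bins)}, {})
    return hq.BalancedContactMatrix(raw, w)


def bed(records) -> pd.DataFrame:
    return pd.DataFrame(records, columns=["chrom", "start", "end"])


def bedpe(records) -> pd.DataFrame:
    return pd.DataFrame(
        records, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    )
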