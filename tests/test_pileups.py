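"""Fixed-size and rescaled pileups: geometry, accumulation semantics, oracles."""

import numpy as np
import pandas as pd
import pytest

import hicquant as hq
from conftest import bed, bedpe, decay_balanced, random_raw, uniform_balanced


def _regions(chrom, centers, width=1000):
    return bed([(chrom, c - width // 2, c + width // 2) for c in centers])


def test_default_window_geometry():
    cfg = hq.PileupConfig()
    assert cfg.side == 41
    assert cfg.flank_bins == 20  # center index (20, 20)
    assert cfg.min_separation == 205_000 + 0  # 2 * flank + resolution


def test_flank_must_align_with_resolution():
    with pytest.raises(ValueError):
        hq.PileupConfig(flank_bp=10_500, resolution=5000)


def _decay_setup(n_bins=400, resolution=1000):
    matrix = decay_balanced(n_bins=n_bins, resolution=resolution)
    prof = hq.compute_expected(matrix)
    return matrix, prof


def test_observed_equal_expected_gives_flat_pileup():
    matrix, prof = _decay_setup()
    cfg = hq.PileupConfig(flank_bp=10_000, resolution=1000)
    regs = _regions("chrA", [50_500, 120_500, 200_500, 300_500])
    pile = hq.pileup_pairs(matrix, regs, regs, prof, cfg)
    assert np.allclose(pile.enrichment, 1.0)
    assert pile.center_enrichment == pytest.approx(1.0)


def test_single_loop_pileup_equals_its_window():
    raw = random_raw(4, n_bins=200, density=0.5)
    matrix = hq.balance(raw)
    prof = hq.compute_expected(matrix)
    cfg = hq.PileupConfig(flank_bp=5000, resolution=1000)
    loops = bedpe([("chrA", 50_000, 51_000, "chrA", 150_000, 151_000)])
    pile = hq.pileup_loops(matrix, loops, prof, cfg)
    assert pile.n == 1
    obs, exp, valid = hq.obs_exp_window(matrix, "chrA", (45, 56), (145, 156), prof)
    with np.errstate(invalid="ignore"):
        direct = np.where(valid, obs / exp, np.nan)
    assert np.allclose(pile.enrichment[valid], direct[valid], equal_nan=True)


@pytest.mark.parametrize("seed", range(3))
def test_pileup_matches_brute_force_dense_oracle(seed):
    """Sparse-accumulation pileup equals a dense whole-matrix reimplementation."""
    raw = random_raw(seed, n_bins=200, density=0.4)
    matrix = hq.balance(raw)
    prof = hq.compute_expected(matrix)
    f = 5
    cfg = hq.PileupConfig(flank_bp=f * 1000, resolution=1000)
    rng = np.random.default_rng(seed)
    centers = rng.choice(np.arange(10, 190), size=12, replace=False) * 1000 + 500
    loops = []
    for k in range(0, 12, 2):
        a, b = sorted((centers[k], centers[k + 1]))
        if b - a >= cfg.min_separation:
            loops.append(("chrA", a - 500, a + 500, "chrA", b - 500, b + 500))
    loops = bedpe(loops)
    pile = hq.pileup_loops(matrix, loops, prof, cfg)

    dense = matrix.balanced_dense("chrA")
    exp_full = prof.expected_matrix("chrA", np.arange(200), np.arange(200))
    obs_sum = np.zeros((11, 11))
    exp_sum = np.zeros((11, 11))
    n = 0
    for _, row in loops.iterrows():
        a = (row.start1 + 500) // 1000
        b = (row.start2 + 500) // 1000
        if min(a, b) - f < 0 or max(a, b) + f >= 200:
            continue
        o = dense[a - f:a + f + 1, b - f:b + f + 1]
        e = exp_full[a - f:a + f + 1, b - f:b + f + 1]
        valid = np.isfinite(o) & np.isfinite(e) & (e > 0)
        obs_sum[valid] += o[valid]
        exp_sum[valid] += e[valid]
        n += 1
    assert pile.n == n
    assert np.allclose(pile.obs_sum, obs_sum)
    assert np.allclose(pile.exp_sum, exp_sum)


def test_sum_then_divide_not_mean_of_ratios():
    """Two windows with unequal expected: the enrichment must be the ratio of
    sums, which differs from the mean of per-window ratios."""
    matrix = decay_balanced(n_bins=500, resolution=1000)
    prof = hq.compute_expected(matrix)
    cfg = hq.PileupConfig(flank_bp=2000, resolution=1000)
    loops = bedpe([
        ("chrA", 100_000, 101_000, "chrA", 150_000, 151_000),   # sep 50 kb
        ("chrA", 300_000, 301_000, "chrA", 440_000, 441_000),   # sep 140 kb
    ])
    # scale observed in the first window by 3, second by 2
    dense_scale = {(100, 150): 3.0, (300, 440): 2.0}
    lil = matrix.raw.counts("chrA").tolil()
    for (a, b), s in dense_scale.items():
        for i in range(a - 2, a + 3):
            for j in range(b - 2, b + 3):
                lil[i, j] = lil[i, j] * s
    raw2 = hq.RawContactMatrix(matrix.bins, {"chrA": lil.tocsr()})
    matrix2 = hq.BalancedContactMatrix(raw2, matrix.weights)
    pile = hq.pileup_loops(matrix2, loops, prof, cfg)
    e1 = 1.0 / 51  # expected at the two planted separations
    e2 = 1.0 / 141
    sum_then_divide = (3 * e1 + 2 * e2) / (e1 + e2)
    mean_of_ratios = (3 + 2) / 2
    assert pile.center_enrichment == pytest.approx(sum_then_divide, rel=1e-9)
    assert abs(pile.center_enrichment - mean_of_ratios) > 0.1


def test_region_order_invariance():
    raw = random_raw(9, n_bins=300, density=0.4)
    matrix = hq.balance(raw)
    prof = hq.compute_expected(matrix)
    cfg = hq.PileupConfig(flank_bp=5000, resolution=1000)
    regs = _regions("chrA", [20_500, 80_500, 150_500, 220_500, 280_500])
    shuffled = regs.sample(frac=1.0, random_state=1).reset_index(drop=True)
    p1 = hq.pileup_pairs(matrix, regs, regs, prof, cfg)
    p2 = hq.pileup_pairs(matrix, shuffled, shuffled, prof, cfg)
    assert np.array_equal(p1.obs_sum, p2.obs_sum)
    assert np.array_equal(p1.exp_sum, p2.exp_sum)


def test_pairs_transpose_symmetry_between_region_sets():
    raw = random_raw(10, n_bins=300, density=0.4)
    matrix = hq.balance(raw)
    prof = hq.compute_expected(matrix)
    cfg = hq.PileupConfig(flank_bp=5000, resolution=1000)
    A = _regions("chrA", [30_500, 120_500, 250_500])
    B = _regions("chrA", [70_500, 180_500])
    pab = hq.pileup_pairs(matrix, A, B, prof, cfg)
    pba = hq.pileup_pairs(matrix, B, A, prof, cfg)
    assert np.allclose(pab.obs_sum, pba.obs_sum.T, equal_nan=True)
    assert np.allclose(pab.exp_sum, pba.exp_sum.T, equal_nan=True)


def test_same_set_pileup_is_symmetrized_by_default():
    raw = random_raw(11, n_bins=300, density=0.4)
    matrix = hq.balance(raw)
    prof = hq.compute_expected(matrix)
    cfg = hq.PileupConfig(flank_bp=5000, resolution=1000)
    regs = _regions("chrA", [30_500, 120_500, 250_500])
    pile = hq.pileup_pairs(matrix, regs, regs, prof, cfg)
    assert np.allclose(pile.enrichment, pile.enrichment.T, equal_nan=True)


def test_edge_windows_skipped_and_counted():
    matrix, prof = _decay_setup(n_bins=100)
    cfg = hq.PileupConfig(flank_bp=10_000, resolution=1000, min_separation=30_000)
    loops = bedpe([
        ("chrA", 5_000, 6_000, "chrA", 50_000, 51_000),    # left edge: skipped
        ("chrA", 40_000, 41_000, "chrA", 95_000, 96_000),  # right edge: skipped
        ("chrA", 30_000, 31_000, "chrA", 70_000, 71_000),  # fits
    ])
    pile = hq.pileup_loops(matrix, loops, prof, cfg)
    assert pile.n == 1
    assert pile.n_skipped == 2


def test_empty_pileup_is_an_explicit_error():
    matrix, prof = _decay_setup(n_bins=100)
    cfg = hq.PileupConfig(flank_bp=10_000, resolution=1000)
    loops = bedpe([("chrA", 10_000, 11_000, "chrA", 20_000, 21_000)])  # below min sep
    with pytest.raises(hq.EmptyPileupError):
        hq.pileup_loops(matrix, loops, prof, cfg)


def test_separation_band_filters_pairs():
    matrix, prof = _decay_setup(n_bins=400)
    cfg = hq.PileupConfig(flank_bp=5000, resolution=1000,
                          min_separation=50_000, max_separation=100_000)
    regs = _regions("chrA", [50_500, 120_500, 300_500])
    pile = hq.pileup_pairs(matrix, regs, regs, prof, cfg)
    assert pile.n == 1  # only the 70 kb pair falls in [50, 100] kb


class TestBoxResample:
    def test_identity_when_shapes_match(self):
        a = np.arange(25, dtype=float).reshape(5, 5)
        assert np.allclose(hq.box_resample(a, (5, 5)), a)

    def test_block_mean_downsampling(self):
        a = np.arange(16, dtype=float).reshape(4, 4)
        out = hq.box_resample(a, (2, 2))
        assert np.allclose(out, [[2.5, 4.5], [10.5, 12.5]])

    def test_nan_ignored_in_footprint(self):
        a = np.array([[1.0, np.nan], [3.0, 5.0]])
        out = hq.box_resample(a, (1, 1))
        assert out[0, 0] == pytest.approx((1 + 3 + 5) / 3)

    def test_all_nan_footprint_stays_nan(self):
        a = np.full((4, 4), np.nan)
        assert np.isnan(hq.box_resample(a, (2, 2))).all()

    def test_upsampling_preserves_constants(self):
        a = np.full((3, 3), 7.0)
        assert np.allclose(hq.box_resample(a, (9, 9)), 7.0)


class TestRescaledPileup:
    def test_flat_map_gives_unit_grid(self):
        matrix = decay_balanced(n_bins=300, resolution=1000)
        prof = hq.compute_expected(matrix)
        regs = bed([("chrA", 50_000, 70_000), ("chrA", 150_000, 195_000)])
        pile = hq.rescaled_pileup(matrix, regs, prof, grid_side=21)
        assert np.allclose(pile.grid, 1.0, atol=1e-9)
        assert pile.central_block_mean == pytest.approx(1.0)

    def test_single_region_equals_direct_resampling(self):
        raw = random_raw(7, n_bins=200, density=0.5)
        matrix = hq.balance(raw)
        prof = hq.compute_expected(matrix)
        regs = bed([("chrA", 60_000, 80_000)])
        pile = hq.rescaled_pileup(matrix, regs, prof, grid_side=21)
        b0, b1 = 60, 80
        fb = b1 - b0
        obs, exp, valid = hq.obs_exp_window(
            matrix, "chrA", (b0 - fb, b1 + fb), (b0 - fb, b1 + fb), prof
        )
        with np.errstate(invalid="ignore"):
            oe = np.where(valid, obs / exp, np.nan)
        direct = hq.box_resample(oe, (21, 21))
        assert np.allclose(pile.grid, direct, equal_nan=True)

    def test_short_and_out_of_bounds_regions_skipped(self):
        matrix = decay_balanced(n_bins=100, resolution=1000)
        prof = hq.compute_expected(matrix)
        regs = bed([
            ("chrA", 10_000, 15_000),   # shorter than min length
            ("chrA", 2_000, 30_000),    # window leaves the chromosome
            ("chrA", 40_000, 60_000),   # fits
        ])
        pile = hq.rescaled_pileup(matrix, regs, prof, grid_side=11)
        assert pile.n == 1
        assert pile.n_skipped == 2

    def test_even_grid_rejected(self):
        matrix = decay_balanced(n_bins=100, resolution=1000)
        prof = hq.compute_expected(matrix)
        with pytest.raises(ValueError):
            hq.rescaled_pileup(matrix, bed([("chrA", 40_000, 60_000)]), prof, grid_side=10)
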