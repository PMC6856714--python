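"""Insulation, compartment eigenvector, track similarity, domain z-score."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import hicquant as hq
from conftest import make_bundle, random_raw, uniform_balanced


class TestInsulation:
    def test_uniform_matrix_has_zero_normalized_score(self):
        matrix = uniform_balanced(n_bins=40, value=3.0)
        track = hq.diamond_insulation(matrix, window_bp=4000)
        valid = track["valid"]
        assert valid.sum() == 40 - 2 * 4 + 1  # i in [w-1, n-w): n-2w+1 bins
        assert np.allclose(track.loc[valid, "score"], 0.0, atol=1e-12)

    def test_diamond_pixel_count_at_defaults(self):
        # 100 kb window at 25 kb bins -> 4x4 = 16 pixels
        w = 100_000 // 25_000
        assert w * w == 16

    def test_masked_bin_invalidates_touching_diamonds(self):
        matrix = uniform_balanced(n_bins=40, value=1.0)
        matrix.weights.weights["chrA"][20] = np.nan
        track = hq.diamond_insulation(matrix, window_bp=3000)
        w = 3
        invalid_span = track.loc[~track["valid"], "start"].to_numpy() // 1000
        for i in range(20 - w + 1, 20 + w):
            if w - 1 <= i < 40 - w:
                assert i in invalid_span

    def test_short_chromosome_all_invalid_with_warning(self):
        matrix = uniform_balanced(n_bins=5)
        with pytest.warns(UserWarning, match="shorter"):
            track = hq.diamond_insulation(matrix, window_bp=4000)
        assert not track["valid"].any()

    def test_mean_normalization_identity(self):
        raw = random_raw(3, n_bins=80, density=0.7)
        matrix = hq.balance(raw)
        track = hq.diamond_insulation(matrix, window_bp=5000)
        valid = track["valid"]
        # log2 normalization against the chromosome mean of raw scores
        back = 2.0 ** track.loc[valid, "score"] * np.nanmean(track.loc[valid, "raw"])
        assert np.allclose(back, track.loc[valid, "raw"], rtol=1e-9)

    def test_boundary_recovery_on_planted_tads(self, serum_bundle):
        b = serum_bundle
        m25 = hq.aggregate(b.matrix, 5)
        track = hq.diamond_insulation(m25)
        minima = hq.find_insulation_minima(track)
        res = 25_000
        hits = total = 0
        tads = b.truth.domains.query("klass == 'ctcf'")
        for chrom, sub in tads.groupby("chrom"):
            edges = sorted(set(sub["start"]) | set(sub["end"]))
            edges = [e for e in edges if 0 < e < b.spec.chromsizes[chrom]]
            mb = minima[minima["chrom"] == chrom]["start"].to_numpy() // res
            for e in edges:
                total += 1
                if len(mb) and np.min(np.abs(mb - e // res)) <= 1:
                    hits += 1
        assert total >= 20
        assert hits / total >= 0.9

    def test_boundary_bins_fall_in_bottom_score_decile(self, serum_bundle):
        b = serum_bundle
        m25 = hq.aggregate(b.matrix, 5)
        track = hq.diamond_insulation(m25)
        res = 25_000
        scores = []
        for chrom, sub in b.truth.domains.query("klass == 'ctcf'").groupby("chrom"):
            tr = track[track["chrom"] == chrom].reset_index(drop=True)
            cutoff = np.nanquantile(tr.loc[tr["valid"], "score"], 0.1)
            for e in sorted(set(sub["start"]) | set(sub["end"])):
                if 0 < e < b.spec.chromsizes[chrom]:
                    window = tr.iloc[max(0, e // res - 1): e // res + 2]
                    s = np.nanmin(window["score"].to_numpy())
                    scores.append(s <= cutoff)
        assert np.mean(scores) >= 0.8


class TestEigenvector:
    def _block_matrix(self, n=40, r=0.4):
        # exact two-block checkerboard obs/exp: 1 +/- r
        e = np.where(np.arange(n) < n // 2, 1.0, -1.0)
        oe = 1.0 + r * np.outer(e, e)
        decay = np.ones((n, n))
        vals = oe * decay
        i, j = np.triu_indices(n)
        bins = hq.GenomeBins({"chrA": n * 1000}, 1000)
        raw = hq.RawContactMatrix(
            bins, {"chrA": sp.csr_matrix((vals[i, j], (i, j)), shape=(n, n))}
        )
        w = hq.BalanceWeights({"chrA": np.ones(n)}, {})
        return hq.BalancedContactMatrix(raw, w), e

    def _gc(self, e, n, resolution=1000, flip=False):
        sign = -1.0 if flip else 1.0
        return pd.DataFrame(
            {"chrom": "chrA", "start": np.arange(n) * resolution,
             "end": (np.arange(n) + 1) * resolution, "value": 0.4 + sign * 0.02 * e}
        )

    def test_two_block_checkerboard_recovered(self):
        matrix, e = self._block_matrix()
        track, info = hq.compartment_eigenvector(matrix, self._gc(e, 40))
        v = track["E1"].to_numpy()
        # the per-diagonal expected normalization perturbs the ideal rank-1
        # structure slightly, so recovery is near-exact, not bitwise
        assert np.corrcoef(v, e)[0, 1] > 0.95
        # coherent within blocks, opposite signs across blocks
        assert np.all(np.sign(v[:20]) == np.sign(v[0]))
        assert np.all(np.sign(v[20:]) == np.sign(v[-1]))
        assert np.sign(v[0]) != np.sign(v[-1])
        gap = abs(v[:20].mean() - v[20:].mean())
        assert v[:20].std() < 0.2 * gap and v[20:].std() < 0.2 * gap

    def test_gc_flip_flips_sign_only(self):
        matrix, e = self._block_matrix()
        t1, _ = hq.compartment_eigenvector(matrix, self._gc(e, 40))
        t2, _ = hq.compartment_eigenvector(matrix, self._gc(e, 40, flip=True))
        assert np.allclose(t1["E1"].to_numpy(), -t2["E1"].to_numpy())

    def test_scalar_rescaling_leaves_eigenvector_invariant_up_to_sign(self):
        matrix, e = self._block_matrix()
        scaled_counts = matrix.raw.counts("chrA") * 7.5
        raw2 = hq.RawContactMatrix(matrix.bins, {"chrA": scaled_counts})
        matrix2 = hq.BalancedContactMatrix(
            raw2, hq.BalanceWeights({"chrA": np.ones(40)}, {})
        )
        t1, _ = hq.compartment_eigenvector(matrix, self._gc(e, 40))
        t2, _ = hq.compartment_eigenvector(matrix2, self._gc(e, 40))
        assert np.allclose(t1["E1"].to_numpy(), t2["E1"].to_numpy(), atol=1e-9)

    def test_simulation_compartments_recovered(self, serum_bundle):
        b = serum_bundle
        m200 = hq.aggregate(b.matrix, 40)
        track, info = hq.compartment_eigenvector(m200, b.tracks.gc)
        for chrom in m200.chroms:
            sub = track[track["chrom"] == chrom]
            e_true = b.truth.compartments[chrom][::40][: len(sub)]
            ok = sub["valid"].to_numpy()
            r = np.corrcoef(sub["E1"].to_numpy()[ok], e_true[ok])[0, 1]
            assert abs(r) > 0.9

    def test_too_few_valid_bins_skipped_with_warning(self):
        matrix = uniform_balanced(n_bins=5)
        gc = self._gc(np.ones(5), 5)
        with pytest.warns(UserWarning, match="valid bins"):
            track, info = hq.compartment_eigenvector(matrix, gc, min_valid_bins=10)
        assert not track["valid"].any()


class TestSimilarity:
    def test_track_against_itself_r_is_one(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=500)
        corr, order, _ = hq.track_similarity([t, t.copy()])
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=2000), rng.normal(size=2000)
        corr, _, _ = hq.track_similarity([a, b])
        assert abs(corr.iloc[0, 1]) < 0.05

    def test_nan_bins_dropped_for_all_tracks(self):
        a = np.array([1.0, 2, 3, np.nan, 5, 6])
        b = np.array([2.0, 4, 6, 8, np.nan, 12])
        corr, _, _ = hq.track_similarity([a, 2 * a, b])
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_too_few_common_bins_is_an_error(self):
        a = np.array([1.0, np.nan, 3.0])
        b = np.array([np.nan, 2.0, 3.0])
        with pytest.raises(ValueError):
            hq.track_similarity([a, b])

    def test_replicates_pair_in_dendrogram(self):
        """Two replicates per condition: insulation profiles cluster by
        condition, mirroring the separation of culture conditions."""
        tracks = {}
        genome = hq.default_spec(
            21, n_chroms=1, chrom_length=4_000_000, total_count=1.5e6,
            n_polycomb_domains=6, n_cgi_anchors=10, n_ctcf_sites=10,
            n_ctcf_loops=10,
        )
        for cond in ("serum", "2i"):
            for rep, noise in (("r1", 101), ("r2", 102)):
                spec = genome.paired(cond).replicate(noise)
                bundle = make_bundle(spec)
                m25 = hq.aggregate(bundle.matrix, 5)
                tr = hq.diamond_insulation(m25)
                tracks[f"{cond}_{rep}"] = tr["score"].to_numpy()
        corr, order, _ = hq.track_similarity(
            list(tracks.values()), list(tracks.keys())
        )
        pos = {name: k for k, name in enumerate(order)}
        assert abs(pos["serum_r1"] - pos["serum_r2"]) == 1
        assert abs(pos["2i_r1"] - pos["2i_r2"]) == 1


class TestDomainZScore:
    def test_identical_matrices_give_zero_differential_z(self, small_bundle):
        b = small_bundle
        dom = b.truth.domains.query("klass == 'polycomb'").iloc[0]
        zs = hq.domain_contact_zscore(
            b.matrix, b.expected, dom["chrom"], int(dom["start"]), int(dom["end"]),
            n_null=50, seed=0, matrix2=b.matrix, expected2=b.expected,
        )
        assert zs.statistic == 0.0
        assert zs.z == 0.0 or abs(zs.z) < 3

    def test_seed_determines_null_windows(self, small_bundle):
        b = small_bundle
        dom = b.truth.domains.query("klass == 'polycomb'").iloc[0]
        args = (b.matrix, b.expected, dom["chrom"], int(dom["start"]), int(dom["end"]))
        z1 = hq.domain_contact_zscore(*args, n_null=50, seed=5)
        z2 = hq.domain_contact_zscore(*args, n_null=50, seed=5)
        z3 = hq.domain_contact_zscore(*args, n_null=50, seed=6)
        assert z1.z == z2.z
        assert z1.null_mean == z2.null_mean
        assert z3.z != z1.z  # different placements

    def test_too_small_domain_rejected(self, small_bundle):
        b = small_bundle
        with pytest.raises(ValueError, match="3 bins"):
            hq.domain_contact_zscore(b.matrix, b.expected, "chr1", 0, 10_000)

    def test_too_many_null_windows_requested(self, small_bundle):
        b = small_bundle
        with pytest.raises(ValueError, match="placements"):
            hq.domain_contact_zscore(
                b.matrix, b.expected, "chr1", 100_000, 200_000, n_null=10_000
            )

    def test_planted_domain_depletion_detected_differentially(
        self, serum_bundle, twoi_bundle
    ):
        """log2(2i / serum) of a planted polycomb domain is strongly negative
        against the random-window null."""
        s, t = serum_bundle, twoi_bundle
        for _, dom in s.truth.domains.query("klass == 'polycomb'").head(3).iterrows():
            zs = hq.domain_contact_zscore(
                s.matrix, s.expected, dom["chrom"], int(dom["start"]), int(dom["end"]),
                n_null=100, seed=1, matrix2=t.matrix, expected2=t.expected,
            )
            assert zs.z <= -3
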