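import numpy as np
import pandas as pd
import pytest

from sctarget import hic
from sctarget.hic import ContactMap
from sctarget.simulate import HicSimConfig, simulate_hic


def _bins(n, size=40_000, chrom="chr1"):
    return pd.DataFrame(
        {"chrom": chrom, "start": np.arange(n) * size, "end": (np.arange(n) + 1) * size}
    )


def _cmap(M, size=40_000):
    return ContactMap(bins=_bins(M.shape[0], size), matrix=M, resolution=size)


class TestContactMapValidation:
    def test_asymmetric_rejected(self):
        M = np.array([[1.0, 2.0], [3.0, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            _cmap(M)

    def test_negative_rejected(self):
        M = np.array([[1.0, -2.0], [-2.0, 1.0]])
        with pytest.raises(ValueError):
            _cmap(M)


class TestIce:
    def test_balanced_matrix_fixed_point(self):
        M = np.ones((6, 6))  # equal marginals already
        out = hic.ice_normalize(_cmap(M))
        assert np.allclose(out.matrix, M, atol=1e-8)
        assert np.allclose(out.bias[np.isfinite(out.bias)], 1.0, atol=1e-8)

    def test_marginals_equal_after_convergence(self):
        rng = np.random.default_rng(0)
        A = rng.random((30, 30))
        out = hic.ice_normalize(_cmap(A + A.T + 0.5), tol=1e-6)
        s = out.matrix.sum(axis=1)
        s = s[s > 0]
        assert s.std() / s.mean() < 1e-6

    def test_small_matrix_matches_sinkhorn_oracle(self):
        # independent alternating row/column normalization to the doubly
        # stochastic form, compared after rescaling marginals to 1
        M = np.array(
            [
                [1.0, 2.0, 3.0, 1.0],
                [2.0, 5.0, 1.0, 2.0],
                [3.0, 1.0, 4.0, 1.0],
                [1.0, 2.0, 1.0, 6.0],
            ]
        )
        W = M.copy()
        for _ in range(20_000):
            W = W / W.sum(axis=1, keepdims=True)
            W = W / W.sum(axis=0, keepdims=True)
        ours = hic.ice_normalize(_cmap(M), tol=1e-10, max_iter=5000, low_coverage_frac=0.0)
        scaled = ours.matrix / ours.matrix.sum(axis=1, keepdims=True)
        assert np.allclose(scaled, W, atol=1e-6)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        A = rng.random((40, 40))
        M = A + A.T + 1
        M[5] *= 0.01
        M[:, 5] *= 0.01  # one genuinely low-coverage bin
        b1 = hic.ice_normalize(_cmap(M), tol=1e-8)
        b2 = hic.ice_normalize(b1, tol=1e-8)
        assert np.abs(b1.matrix - b2.matrix).max() < 1e-6


class TestObservedExpected:
    def test_pure_distance_profile_gives_ones(self):
        # a matrix that equals its own distance-mean profile: every diagonal
        # is constant, so dividing by the diagonal mean gives all ones
        n = 12
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        M = 1.0 / (d + 1.0)
        cmap = ContactMap(bins=_bins(n), matrix=M, resolution=40_000,
                          bias=np.ones(n), balanced=True)
        oe = hic.observed_expected(cmap)
        assert np.allclose(oe.matrix, 1.0, atol=1e-12)

    def test_every_diagonal_means_one(self):
        rng = np.random.default_rng(2)
        A = rng.random((15, 15))
        oe = hic.observed_expected(hic.ice_normalize(_cmap(A + A.T + 0.2)))
        for d in range(15):
            diag = np.diagonal(oe.matrix, offset=d)
            diag = diag[diag > 0]
            if diag.size:
                assert diag.mean() == pytest.approx(1.0, abs=1e-10)

    def test_manual_entry_on_six_bin_fixture(self):
        rng = np.random.default_rng(3)
        A = rng.random((6, 6))
        M = A + A.T + 0.1
        bal = hic.ice_normalize(_cmap(M), low_coverage_frac=0.0)
        oe = hic.observed_expected(bal)
        B = bal.matrix
        exp_d2 = np.mean([B[0, 2], B[1, 3], B[2, 4], B[3, 5]])
        assert oe.matrix[1, 3] == pytest.approx(B[1, 3] / exp_d2)


class TestCompartments:
    def _checkerboard(self, noise_sd=0.0, seed=0, blocks=(25, 25, 25, 25)):
        cfg = HicSimConfig(
            n_bins=sum(blocks),
            bin_size=500_000,
            compartment_blocks={"c": list(blocks)},
            noise_sd=noise_sd,
            seed=seed,
        )
        maps, truth = simulate_hic(cfg)
        return maps["c"], truth.compartment_sign_track["c"]

    def test_noiseless_checkerboard_recovered_exactly(self):
        cmap, signs = self._checkerboard()
        gd = np.where(signs > 0, 8.0, 2.0)
        oe = hic.observed_expected(hic.ice_normalize(cmap))
        track = hic.compartment_track(oe, gd)
        ev = track["eigenvector"].to_numpy()
        called = np.isfinite(ev)  # low-coverage edge bins carry no call
        assert called.mean() >= 0.95
        assert np.array_equal(np.where(ev[called] > 0, 1, -1), signs[called])
        comp = track["compartment"].to_numpy()
        assert (comp[called & (signs > 0)] == "A").all()

    def test_orientation_follows_gene_density(self):
        # flipping which block is gene-denser flips the A/B labels
        cmap, signs = self._checkerboard()
        oe = hic.observed_expected(hic.ice_normalize(cmap))
        t1 = hic.compartment_track(oe, np.where(signs > 0, 8.0, 2.0))
        t2 = hic.compartment_track(oe, np.where(signs > 0, 2.0, 8.0))
        e1, e2 = t1["eigenvector"].to_numpy(), t2["eigenvector"].to_numpy()
        ok = np.isfinite(e1)
        assert np.allclose(e1[ok], -e2[ok])

    def test_equal_density_falls_back_to_larger_block(self):
        cfg = HicSimConfig(
            n_bins=30, bin_size=500_000, compartment_blocks={"c": [20, 10]},
            noise_sd=0.0, seed=0,
        )
        maps, truth = simulate_hic(cfg)
        oe = hic.observed_expected(hic.ice_normalize(maps["c"]))
        with pytest.warns(UserWarning, match="larger block"):
            track = hic.compartment_track(oe, np.ones(30))
        # the larger (first, positive) block gets the A label
        assert (track["compartment"].iloc[:20] == "A").all()


class TestCompartmentSwitch:
    def _track(self, labels, size=500_000):
        n = len(labels)
        t = _bins(n, size)
        t["eigenvector"] = [1.0 if l == "A" else -1.0 for l in labels]
        t["compartment"] = list(labels)
        return t

    def test_stable_labels(self):
        t = self._track("AABB")
        assert hic.compartment_switch(t, t, ("chr1", 0, 500_000)) == "A->A"
        assert hic.compartment_switch(t, t, ("chr1", 1_500_000, 2_000_000)) == "B->B"

    def test_planted_flip(self):
        t1 = self._track("ABBA")
        t2 = self._track("AABA")
        assert hic.compartment_switch(t1, t2, ("chr1", 500_000, 1_000_000)) == "B->A"

    def test_tie_is_ambiguous(self):
        t1 = self._track("AB")
        t2 = self._track("AA")
        assert hic.compartment_switch(t1, t2, ("chr1", 0, 1_000_000)) == "ambiguous"

    def test_locus_outside_bins_rejected(self):
        t = self._track("AB")
        with pytest.raises(ValueError):
            hic.compartment_switch(t, t, ("chr2", 0, 100))


class TestInsulation:
    def test_uniform_matrix_zero_scores(self):
        M = np.ones((40, 40)) * 3.0
        track = hic.insulation_track(_cmap(M), window=200_000)
        vals = track["insulation"].dropna()
        assert len(vals) > 0
        assert np.allclose(vals, 0.0, atol=1e-12)

    def test_invariant_to_global_scaling(self):
        cfg = HicSimConfig(n_bins=40, bin_size=40_000, tad_boundaries={"c": [20]},
                           noise_sd=0.1, seed=4)
        maps, _ = simulate_hic(cfg)
        m = maps["c"]
        t1 = hic.insulation_track(m, window=200_000)
        t2 = hic.insulation_track(_cmap(m.matrix * 7.5), window=200_000)
        assert np.allclose(
            t1["insulation"].dropna(), t2["insulation"].dropna(), atol=1e-10
        )

    def test_boundary_is_local_minimum_noiseless(self):
        cfg = HicSimConfig(n_bins=30, bin_size=40_000, tad_boundaries={"c": [10, 20]},
                           noise_sd=0.0, seed=0)
        maps, _ = simulate_hic(cfg)
        track = hic.insulation_track(hic.ice_normalize(maps["c"]), window=240_000)
        is_ = track["insulation"].to_numpy()
        order = np.argsort(np.where(np.isfinite(is_), is_, np.inf))
        lowest = set(order[:4].tolist())
        # the two deepest valleys sit at the planted edges (within the
        # boundary-bin convention: the edge lies between bins b-1 and b)
        assert lowest <= {9, 10, 19, 20}
        assert any(b in lowest for b in (9, 10))
        assert any(b in lowest for b in (19, 20))


class TestCallTads:
    def test_three_equal_blocks(self):
        cfg = HicSimConfig(n_bins=30, bin_size=40_000, tad_boundaries={"c": [10, 20]},
                           noise_sd=0.0, seed=0)
        maps, _ = simulate_hic(cfg)
        track = hic.insulation_track(hic.ice_normalize(maps["c"]), window=240_000)
        tads = hic.call_tads(track, resolution=40_000, delta_window=120_000)
        assert len(tads) == 3
        assert tads["retained"].all()

    def test_small_tad_flagged_min_size(self):
        cfg = HicSimConfig(n_bins=23, bin_size=50_000, tad_boundaries={"c": [10, 13]},
                           noise_sd=0.0, seed=0)
        maps, _ = simulate_hic(cfg)
        track = hic.insulation_track(hic.ice_normalize(maps["c"]), window=250_000)
        tads = hic.call_tads(track, resolution=50_000, delta_window=50_000)
        flagged = tads[~tads["retained"]]
        assert len(flagged) == 1
        assert flagged["reason"].iloc[0] == "min_size"
        assert (flagged["end"] - flagged["start"]).iloc[0] < 200_000

    def test_excluded_region_flagged(self):
        cfg = HicSimConfig(n_bins=30, bin_size=40_000, tad_boundaries={"c": [10, 20]},
                           noise_sd=0.0, seed=0)
        maps, _ = simulate_hic(cfg)
        track = hic.insulation_track(hic.ice_normalize(maps["c"]), window=240_000)
        tads = hic.call_tads(
            track, resolution=40_000, delta_window=120_000,
            excluded=[("chr1", 0, 50_000)],
        )
        assert tads.iloc[0]["reason"] == "excluded_region"

    def test_boundaries_invariant_to_constant_shift(self):
        cfg = HicSimConfig(n_bins=40, bin_size=40_000, tad_boundaries={"c": [13, 26]},
                           noise_sd=0.05, seed=5)
        maps, _ = simulate_hic(cfg)
        track = hic.insulation_track(hic.ice_normalize(maps["c"]), window=240_000)
        shifted = track.copy()
        shifted["insulation"] = shifted["insulation"] + 1.7
        t1 = hic.call_tads(track, resolution=40_000)
        t2 = hic.call_tads(shifted, resolution=40_000)
        assert t1[["start", "end"]].equals(t2[["start", "end"]])


def _tads(intervals, chrom="chr1"):
    return pd.DataFrame(
        [
            {"chrom": chrom, "start": s, "end": e, "retained": True, "reason": ""}
            for s, e in intervals
        ]
    )


class TestConservedTads:
    def test_identical_sets_all_conserved(self):
        t = _tads([(0, 400_000), (400_000, 900_000)])
        out = hic.conserved_tads(t, t)
        assert out["conserved"].all()

    def test_seventy_percent_boundary_case_accepted(self):
        a = _tads([(0, 1_000_000)])
        b = _tads([(0, 700_000)])
        out = hic.conserved_tads(a, b)
        assert out["conserved"].iloc[0]  # 700/1000 = 0.70 and 700/700 = 1.0

    def test_half_overlap_rejected(self):
        a = _tads([(0, 1_000_000)])
        b = _tads([(500_000, 1_000_000)])
        assert not hic.conserved_tads(a, b)["conserved"].iloc[0]

    def test_symmetry_when_reciprocal(self):
        rng = np.random.default_rng(6)
        edges_a = np.sort(rng.choice(np.arange(1, 50), size=6, replace=False)) * 100_000
        edges_b = np.sort(rng.choice(np.arange(1, 50), size=6, replace=False)) * 100_000
        a = _tads(list(zip([0, *edges_a], [*edges_a, 5_000_000])))
        b = _tads(list(zip([0, *edges_b], [*edges_b, 5_000_000])))
        ab = hic.conserved_tads(a, b)
        ba = hic.conserved_tads(b, a)
        pairs_ab = {
            (r.start, r.end, int(r.match_start), int(r.match_end))
            for r in ab.itertuples()
            if r.conserved
        }
        pairs_ba = {
            (int(r.match_start), int(r.match_end), r.start, r.end)
            for r in ba.itertuples()
            if r.conserved
        }
        assert pairs_ab == pairs_ba


class TestGeneStructureReport:
    def _setup(self):
        cfg = HicSimConfig(
            n_bins=60,
            bin_size=40_000,
            compartment_blocks={"normal": [30, 10, 20], "tumor": [40, 20]},
            tad_boundaries={"normal": [20, 40], "tumor": [20, 33, 40]},
            noise_sd=0.0,
            seed=0,
        )
        maps, truth = simulate_hic(cfg)
        gd = np.zeros(60)
        for signs in truth.compartment_sign_track.values():
            gd[signs > 0] += 5.0
        tracks, tads, ins = {}, {}, {}
        for cond, cm in maps.items():
            bal = hic.ice_normalize(cm)
            tracks[cond] = hic.compartment_track(hic.observed_expected(bal), gd)
            ins[cond] = hic.insulation_track(bal, window=240_000)
            tads[cond] = hic.call_tads(ins[cond], resolution=40_000, delta_window=120_000)
        return tracks, tads, ins

    def test_identical_conditions_stable(self):
        tracks, tads, ins = self._setup()
        # gene in the interior, where the insulation track is defined
        ann = pd.DataFrame(
            {"gene_id": ["gA"], "chrom": ["chr1"], "start": [400_000], "end": [410_000]}
        )
        rep = hic.gene_structure_report(
            ann, tracks["normal"], tracks["normal"], tads["normal"], tads["normal"],
            ins["normal"], ins["normal"],
        )
        assert rep["switch"].iloc[0] in ("A->A", "B->B")
        assert not rep["boundary_change"].iloc[0]
        assert rep["is_diff"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_planted_flip_and_new_boundary_flagged(self):
        tracks, tads, ins = self._setup()
        # bins 30-39 flip B (normal) -> A (tumor); new tumor boundary at bin 33
        genes = pd.DataFrame(
            {
                "gene_id": ["hit", "quiet"],
                "chrom": ["chr1", "chr1"],
                "start": [33 * 40_000 + 1000, 5 * 40_000],
                "end": [33 * 40_000 + 9000, 5 * 40_000 + 8000],
            }
        )
        rep = hic.gene_structure_report(
            genes, tracks["normal"], tracks["tumor"], tads["normal"], tads["tumor"],
            ins["normal"], ins["tumor"],
        ).set_index("gene_id")
        assert rep.loc["hit", "switch"] == "B->A"
        assert rep.loc["hit", "boundary_change"]
        assert rep.loc["quiet", "switch"] == "A->A"
        assert not rep.loc["quiet", "boundary_change"]

    def test_row_count_matches_annotation(self):
        tracks, tads, ins = self._setup()
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(5)] + ["unmapped"],
                "chrom": ["chr1"] * 5 + ["chrX"],
                "start": [i * 300_000 for i in range(5)] + [0],
                "end": [i * 300_000 + 10_000 for i in range(5)] + [100],
            }
        )
        rep = hic.gene_structure_report(
            genes, tracks["normal"], tracks["tumor"], tads["normal"], tads["tumor"],
            ins["normal"], ins["tumor"],
        )
        assert len(rep) == 6
        assert rep["switch"].isna().sum() == 1
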