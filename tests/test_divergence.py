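"""Distances, normalization/fusion, UPGMA, Mojena cut and Mantel test."""

import numpy as np
import pandas as pd
import pytest

from jucara import divergence
from jucara.divergence import DistanceMatrix


def dm(values, labels=None, kind=""):
    values = np.asarray(values, float)
    labels = labels or [f"g{i}" for i in range(values.shape[0])]
    return DistanceMatrix(labels, values, kind)


@pytest.fixture
def random_dm():
    def make(seed, n=15):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        return dm(D)

    return make


class TestDempDistance:
    def test_identical_rows_zero(self):
        b = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [3.0, 1.0]], index=list("abc"))
        D = divergence.demp_distance(b)
        assert D.values[0, 1] == pytest.approx(0.0)

    def test_single_trait_scaling(self):
        b = pd.DataFrame({"t": [0.0, 1.0]}, index=["a", "b"])
        s = b["t"].std(ddof=1)
        D = divergence.demp_distance(b)
        assert D.values[0, 1] == pytest.approx(1.0 / s * 1.0 / 1.0 / np.sqrt(1))
        # with SD scaling of a two-point trait, d = |x1-x2|/sd
        assert D.values[0, 1] == pytest.approx(1.0 / s)

    def test_worked_3x2_matrix(self):
        b = pd.DataFrame(
            [[0.0, 0.0], [1.0, 2.0], [2.0, 0.0]], index=list("abc"), columns=["u", "v"]
        )
        su = b["u"].std(ddof=1)
        sv = b["v"].std(ddof=1)
        expect_ab = np.sqrt((((1 - 0) / su) ** 2 + ((2 - 0) / sv) ** 2) / 2)
        expect_ac = np.sqrt((((2 - 0) / su) ** 2 + 0.0) / 2)
        D = divergence.demp_distance(b)
        assert D.values[0, 1] == pytest.approx(expect_ab, abs=1e-12)
        assert D.values[0, 2] == pytest.approx(expect_ac, abs=1e-12)

    def test_zero_sd_trait_excluded(self):
        b = pd.DataFrame({"t": [0.0, 1.0, 2.0], "c": [1.0, 1.0, 1.0]}, index=list("abc"))
        with pytest.warns(UserWarning, match="zero spread"):
            D = divergence.demp_distance(b)
        assert D.values[0, 2] > 0


class TestUnweightedSSRDistance:
    def make_table(self, rows, loci=1):
        data = {}
        for k in range(loci):
            data[f"L{k + 1:02d}.a"] = [r[k][0] for r in rows]
            data[f"L{k + 1:02d}.b"] = [r[k][1] for r in rows]
        return pd.DataFrame(data, index=[f"g{i}" for i in range(len(rows))])

    def test_identical_genotypes_zero(self):
        t = self.make_table([[(100, 120)], [(100, 120)]])
        assert divergence.unweighted_ssr_distance(t).values[0, 1] == 0.0

    def test_one_shared_allele_half(self):
        t = self.make_table([[(100, 120)], [(100, 140)]])
        assert divergence.unweighted_ssr_distance(t).values[0, 1] == 0.5

    def test_disjoint_alleles_one(self):
        t = self.make_table([[(100, 120), (200, 202)], [(130, 140), (210, 212)]], loci=2)
        assert divergence.unweighted_ssr_distance(t).values[0, 1] == 1.0

    def test_multiplicity_counting(self):
        # (100,100) vs (100,120): one copy of 100 matches → similarity 0.5
        t = self.make_table([[(100, 100)], [(100, 120)]])
        assert divergence.unweighted_ssr_distance(t).values[0, 1] == 0.5

    def test_mean_over_shared_loci_only(self):
        t = self.make_table(
            [[(100, 120), (np.nan, np.nan)], [(100, 120), (200, 202)]], loci=2
        )
        assert divergence.unweighted_ssr_distance(t).values[0, 1] == 0.0

    def test_no_shared_locus_errors(self):
        t = self.make_table(
            [[(100, 120), (np.nan, np.nan)], [(np.nan, np.nan), (200, 202)]], loci=2
        )
        with pytest.raises(ValueError, match="no scored locus"):
            divergence.unweighted_ssr_distance(t)


class TestNormalizeAndFuse:
    def test_divide_by_max(self):
        D = dm([[0, 2, 4], [2, 0, 1], [4, 1, 0]])
        N = divergence.normalize01(D)
        assert N.values[0, 1] == pytest.approx(0.5)
        assert N.values.max() == pytest.approx(1.0)

    def test_idempotent_at_max_one(self):
        D = dm([[0, 1, 0.5], [1, 0, 0.2], [0.5, 0.2, 0]])
        N = divergence.normalize01(D)
        assert np.allclose(N.values, D.values)

    def test_rank_preservation_both_variants(self, random_dm):
        D = random_dm(1)
        iu = np.triu_indices(D.n, 1)
        order = np.argsort(D.values[iu])
        for method in ("max", "minmax"):
            N = divergence.normalize01(D, method=method)
            assert np.array_equal(np.argsort(N.values[iu]), order)

    def test_fuse_average_and_bounds(self, random_dm):
        D1 = divergence.normalize01(random_dm(1))
        D2 = divergence.normalize01(random_dm(2))
        F = divergence.fuse_average(D1, D2)
        assert np.allclose(F.values, 0.5 * (D1.values + D2.values))
        assert (F.values >= np.minimum(D1.values, D2.values) - 1e-12).all()
        assert (F.values <= np.maximum(D1.values, D2.values) + 1e-12).all()
        same = divergence.fuse_average(D1, D1)
        assert np.allclose(same.values, D1.values)

    def test_label_mismatch_reported(self, random_dm):
        D1 = random_dm(1)
        D2 = random_dm(2)
        D2.labels[0] = "other"
        with pytest.raises(ValueError, match="other"):
            divergence.fuse_average(D1, D2)


class TestUPGMA:
    def test_three_leaf_hand_agglomeration(self):
        D = dm([[0, 2, 6], [2, 0, 6], [6, 6, 0]], labels=["A", "B", "C"])
        tree = divergence.upgma(D)
        assert tree.heights.tolist() == pytest.approx([2.0, 6.0])

    def test_ultrametric_input_reproduced_exactly(self):
        # cophenetic distances of an ultrametric matrix equal the input
        U = dm(
            [
                [0, 2, 8, 8],
                [2, 0, 8, 8],
                [8, 8, 0, 4],
                [8, 8, 4, 0],
            ],
            labels=list("abcd"),
        )
        tree = divergence.upgma(U)
        assert np.allclose(tree.cophenetic(), U.values)

    def test_label_permutation_invariance(self, random_dm):
        D = random_dm(3, n=8)
        perm = [3, 1, 4, 0, 7, 6, 2, 5]
        Dp = D.reorder([D.labels[i] for i in perm])
        g1, _ = divergence.mojena_cut(divergence.upgma(D))
        g2, _ = divergence.mojena_cut(divergence.upgma(Dp))
        # same partition up to group renumbering
        joint = pd.crosstab(g1, g2.loc[g1.index])
        assert (joint.gt(0).sum(axis=1) == 1).all()

    def test_monotone_heights(self, random_dm):
        tree = divergence.upgma(random_dm(4, n=12))
        assert (np.diff(tree.heights) >= -1e-12).all()

    def test_nan_rejected(self):
        vals = np.array([[0, np.nan], [np.nan, 0]])
        D = DistanceMatrix(["a", "b"], vals)
        with pytest.raises(ValueError, match="missing"):
            divergence.upgma(D)

    def test_newick_roundtrip_heights(self, random_dm):
        tree = divergence.upgma(random_dm(5, n=6))
        nwk = tree.to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 5


class TestMojena:
    def fake_tree(self, heights):
        # caterpillar linkage with prescribed fusion heights
        n = len(heights) + 1
        Z = np.array(
            [[0, 1, heights[0], 2]]
            + [[n + k - 1, k + 1, heights[k], k + 2] for k in range(1, len(heights))],
            dtype=float,
        )
        return divergence.Dendrogram(Z, labels=[f"g{i}" for i in range(n)])

    def test_threshold_arithmetic(self):
        tree = self.fake_tree([1.0, 2.0, 3.0, 4.0])
        thr = divergence.mojena_threshold(tree, k=1.25)
        assert thr == pytest.approx(2.5 + 1.25 * np.std([1, 2, 3, 4], ddof=1))
        groups, _ = divergence.mojena_cut(tree, k=1.25)
        assert groups.nunique() == 1  # no merge exceeds 4.11

    def test_outlier_merge_cut(self):
        tree = self.fake_tree([1.0, 1.1, 0.9, 1.05, 30.0])
        groups, thr = divergence.mojena_cut(tree, k=1.25)
        assert groups.nunique() == 2

    def test_k_zero_threshold_is_mean(self):
        tree = self.fake_tree([1.0, 2.0, 3.0])
        assert divergence.mojena_threshold(tree, k=0.0) == pytest.approx(2.0)


class TestMantel:
    def test_identical_matrices(self, random_dm):
        D = random_dm(6)
        res = divergence.mantel(D, D, permutations=999, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0 / 1000.0)

    def test_affine_transform_unit_correlation(self, random_dm):
        D = random_dm(6)
        D2 = dm(2.0 * D.values + 0.3 * (1 - np.eye(D.n)), labels=D.labels)
        res = divergence.mantel(D, D2, permutations=99, seed=1)
        assert res.r == pytest.approx(1.0)

    def test_matches_independent_implementation(self, random_dm):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        D1, D2 = random_dm(7), random_dm(8)
        res = divergence.mantel(D1, D2, permutations=999, seed=3)
        r_ref, p_ref, _ = skbio_mantel(
            SkbioDM(D1.values, ids=D1.labels),
            SkbioDM(D2.values, ids=D2.labels),
            method="pearson",
            permutations=999,
            alternative="greater",
        )
        assert res.r == pytest.approx(float(r_ref), abs=1e-12)
        assert res.p_value == pytest.approx(float(p_ref), abs=0.05)

    def test_null_p_uniform(self, random_dm):
        from scipy import stats

        ps = []
        for s in range(200):
            D1 = random_dm(10_000 + 2 * s, n=12)
            D2 = random_dm(10_001 + 2 * s, n=12)
            D2.labels = D1.labels
            ps.append(divergence.mantel(D1, D2, permutations=99, seed=s).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_matrix_rejected(self):
        vals = 1.0 - np.eye(4)
        D = dm(vals)
        with pytest.raises(ValueError, match="constant"):
            divergence.mantel(D, D, permutations=9, seed=0)

    def test_determinism(self, random_dm):
        D1, D2 = random_dm(9), random_dm(10)
        D2.labels = D1.labels
        r1 = divergence.mantel(D1, D2, permutations=199, seed=5)
        r2 = divergence.mantel(D1, D2, permutations=199, seed=5)
        assert (r1.r, r1.p_value) == (r2.r, r2.p_value)


def test_planted_clusters_recovered():
    from jucara import simulate

    hits = 0
    for s in range(50):
        traits, ssr, truth = simulate.simulate_clustered_panel(seed=7000 + s)
        d1 = divergence.normalize01(divergence.demp_distance(traits))
        d2 = divergence.normalize01(divergence.unweighted_ssr_distance(ssr))
        fused = divergence.fuse_average(d1, d2)
        groups, _ = divergence.mojena_cut(divergence.upgma(fused))
        if groups.nunique() == 3:
            hits += 1
    assert hits >= 45  # >= 90% of 50 runs
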