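import numpy as np
import pandas as pd
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ortho_group
from skbio import DistanceMatrix, TreeNode

from hybridbiome import ordination as od
from hybridbiome.tableio import SampleTable


def _table(counts: dict, index):
    return SampleTable(pd.DataFrame(counts, index=index))


class TestDistanceMatrix:
    def test_identical_samples_zero(self, four_tip_tree):
        t = _table({"s1": [1, 2, 0, 3], "s2": [1, 2, 0, 3]}, list("ABCD"))
        for metric in ("jaccard", "braycurtis", "euclidean", "u_unifrac"):
            dm = od.distance_matrix(t, metric, tree=four_tip_tree)
            assert dm["s1", "s2"] == pytest.approx(0.0)

    def test_two_tip_disjoint_unifrac_is_one(self):
        tree = TreeNode.read(["(A:1,B:1):0;"])
        t = _table({"s1": [4, 0], "s2": [0, 9]}, ["A", "B"])
        dm = od.distance_matrix(t, "u_unifrac", tree=tree)
        assert dm["s1", "s2"] == pytest.approx(1.0)

    def test_unweighted_unifrac_hand_enumeration(self, four_tip_tree):
        # {A,B} vs {A,C}: unique branches B,C and the two internal edges;
        # union subtree has 5 unit branches -> 3/5
        t = _table({"s1": [1, 1, 0, 0], "s2": [1, 0, 1, 0]}, list("ABCD"))
        dm = od.distance_matrix(t, "u_unifrac", tree=four_tip_tree)
        assert dm["s1", "s2"] == pytest.approx(0.6)

    def test_empty_sample_errors(self):
        t = _table({"s1": [1, 0], "s2": [0, 0]}, ["A", "B"])
        with pytest.raises(ValueError, match="empty"):
            od.distance_matrix(t, "jaccard")

    def test_symmetry_and_range(self, four_tip_tree):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 50, (4, 6)), index=list("ABCD"),
                              columns=[f"s{i}" for i in range(6)])
        counts.iloc[0] += 1  # no empty samples
        t = SampleTable(counts)
        for metric in ("jaccard", "braycurtis", "u_unifrac"):
            dm = od.distance_matrix(t, metric, tree=four_tip_tree)
            assert np.allclose(dm.data, dm.data.T)
            assert (dm.data >= 0).all() and (dm.data <= 1 + 1e-12).all()


class TestPCoA:
    def test_three_equidistant_points(self):
        dm = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float),
                            ids=list("abc"))
        res = od.pcoa_ordination(dm)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_recovers_planted_configuration(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 2))
        dm = DistanceMatrix(squareform(pdist(X)),
                            ids=[f"s{i}" for i in range(15)])
        res = od.pcoa_ordination(dm)
        Y = res.coordinates.to_numpy()[:, :2]
        Xc = X - X.mean(axis=0)
        R, _ = orthogonal_procrustes(Y, Xc)
        assert np.abs(Y @ R - Xc).max() < 1e-8

    def test_duplicate_sample_coincident(self):
        d = np.array([[0, 0, 1.0], [0, 0, 1.0], [1, 1, 0]])
        res = od.pcoa_ordination(DistanceMatrix(d, ids=list("abc")))
        Y = res.coordinates.to_numpy()
        assert np.allclose(Y[0], Y[1], atol=1e-10)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="at least 3"):
            od.pcoa_ordination(DistanceMatrix(np.zeros((2, 2)), ids=["a", "b"]))

    def test_axis_retention_rule(self):
        eig = np.array([10.0, 5.0, 1.0])
        res = od.OrdinationResult(
            coordinates=pd.DataFrame(np.zeros((4, 3))),
            eigenvalues=eig, proportion_explained=eig / eig.sum(),
            negative_eigenvalue_mass=0.0)
        assert od.n_retained_axes(res) == 3
        eig = np.ones(30)
        res = od.OrdinationResult(
            coordinates=pd.DataFrame(np.zeros((31, 30))),
            eigenvalues=eig, proportion_explained=eig / eig.sum(),
            negative_eigenvalue_mass=0.0)
        # 20 axes cover only 2/3 of the variance -> need 29 for 95%
        assert od.n_retained_axes(res) == 29


class TestPCALoadings:
    def test_single_variable_taxon_dominates(self):
        rng = np.random.default_rng(2)
        base = np.full(20, 0.2)
        big = 0.2 + 0.1 * rng.standard_normal(20)
        rel = pd.DataFrame({f"s{i}": [big[i], base[i], 1 - big[i] - base[i]]
                            for i in range(20)}, index=["big", "flat", "rest"])
        res = od.pca_dominant_loadings(rel)
        assert res.dominant.loc["PC1", "taxon"] in ("big", "rest")
        assert res.dominant.loc["PC1", "share_pct"] > 45

    def test_two_independent_taxa_dominate_distinct_axes(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 3, 40)
        b = rng.normal(0, 1, 40)
        X = pd.DataFrame(
            {f"s{i}": [a[i], b[i], 0.0, 0.0] for i in range(40)},
            index=["ta", "tb", "tc", "td"])
        res = od.pca_dominant_loadings(X)
        assert res.dominant.loc["PC1", "taxon"] == "ta"
        assert res.dominant.loc["PC2", "taxon"] == "tb"

    def test_constant_table_errors(self):
        rel = pd.DataFrame(np.full((3, 5), 1 / 3))
        with pytest.raises(ValueError, match="zero variance"):
            od.pca_dominant_loadings(rel)


class TestTriangleGeometry:
    def test_hybrid_at_p1(self):
        pos, h = od.triangle_position_height([0, 0], [0, 0], [2, 0])
        assert (pos, h) == (0.0, 0.0)

    def test_plane_example(self):
        pos, h = od.triangle_position_height([1, 1], [0, 0], [2, 0])
        assert (pos, h) == (0.5, 0.5)

    def test_matches_brute_force_projection_in_5d(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            p1, p2, hyb = rng.normal(size=(3, 5))
            pos, h = od.triangle_position_height(hyb, p1, p2)
            axis = p2 - p1
            pos_expect = np.dot(hyb - p1, axis) / np.dot(axis, axis)
            h_expect = np.linalg.norm(
                (hyb - p1) - pos_expect * axis) / np.linalg.norm(axis)
            assert pos == pytest.approx(pos_expect, abs=1e-10)
            assert h == pytest.approx(h_expect, abs=1e-10)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        coords = pd.DataFrame(rng.normal(size=(45, 6)),
                              index=[f"s{i}" for i in range(45)])
        groups = pd.Series(["H"] * 15 + ["P1"] * 15 + ["P2"] * 15,
                           index=coords.index)
        stats_a = od.triangle_bootstrap(coords, groups, "H", "P1", "P2",
                                        n_sub=12, trials=20, seed=9)
        Q = ortho_group.rvs(6, random_state=1)
        shifted = pd.DataFrame(coords.to_numpy() @ Q + 3.0,
                               index=coords.index)
        stats_b = od.triangle_bootstrap(shifted, groups, "H", "P1", "P2",
                                        n_sub=12, trials=20, seed=9)
        assert np.abs(stats_a[["position", "height"]].to_numpy()
                      - stats_b[["position", "height"]].to_numpy()).max() < 1e-8

    def test_coincident_progenitors_error(self):
        with pytest.raises(ValueError, match="coincide"):
            od.triangle_position_height([1, 1], [0, 0], [0, 0])


class TestNullModels:
    def test_incidence_identical_parents_copy(self):
        rng = np.random.default_rng(0)
        x = np.array([1, 0, 1, 1, 0], bool)
        out = od.hybrid_null_incidence(x, x, rng)
        assert (out == x).all()

    def test_incidence_two_taxon_symmetric_difference(self):
        rng = np.random.default_rng(1)
        p1 = np.array([1, 1, 0], bool)   # {a, b}
        p2 = np.array([0, 1, 1], bool)   # {b, c}
        for _ in range(50):
            out = od.hybrid_null_incidence(p1, p2, rng)
            assert out[1]                 # b always present
            assert out.sum() == 2         # b plus exactly one of {a, c}

    def test_incidence_richness_deterministic(self):
        rng = np.random.default_rng(2)
        p1 = np.array([1, 1, 1, 0, 0, 0, 1], bool)
        p2 = np.array([1, 0, 0, 1, 1, 0, 0], bool)
        both = (p1 & p2).sum()
        m = (p1 ^ p2).sum()
        expected = both + int(np.floor(m / 2 + 0.5))
        for _ in range(100):
            assert od.hybrid_null_incidence(p1, p2, rng).sum() == expected

    def test_abundance_null_average(self):
        a = np.array([1.0, 0.0, 0.0])
        b = np.array([0.0, 0.5, 0.5])
        out = od.hybrid_null_abundance(a, b)
        assert out == pytest.approx([0.5, 0.25, 0.25])
        assert out.sum() == pytest.approx(1.0)

    def test_progenitor_nulls_center_at_zero_and_one(self):
        rng = np.random.default_rng(6)
        hits = 0
        runs = 20
        for run in range(runs):
            coords = pd.DataFrame(
                np.concatenate([rng.normal(0, 0.3, (15, 3)),
                                rng.normal([3, 0, 0], 0.3, (15, 3))]),
                index=[f"s{i}" for i in range(30)])
            members = {"P1": list(coords.index[:15]),
                       "P2": list(coords.index[15:])}
            null1 = od.triangle_bootstrap(
                coords, {**members, "N1": members["P1"]}, "N1", "P1", "P2",
                n_sub=12, trials=10, seed=run)
            null2 = od.triangle_bootstrap(
                coords, {**members, "N2": members["P2"]}, "N2", "P1", "P2",
                n_sub=12, trials=10, seed=run)
            assert abs(null1["position"].mean()) < 0.2
            assert abs(null2["position"].mean() - 1) < 0.2
            hits += null1["position"].mean() < null2["position"].mean()
        assert hits == runs


class TestComparisons:
    def test_identical_sets_not_significant(self):
        df = pd.DataFrame({"position": np.ones(50), "height": np.ones(50)})
        assert od.triangle_compare(df, df.copy()) == 1.0

    def test_disjoint_support_extreme(self):
        a = pd.DataFrame({"position": np.linspace(0, 1, 50),
                          "height": np.zeros(50)})
        b = pd.DataFrame({"position": np.linspace(5, 6, 50),
                          "height": np.zeros(50)})
        assert od.triangle_compare(a, b, axis="position") < 1e-10

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(7)
        a = pd.DataFrame({"position": rng.normal(size=30),
                          "height": rng.random(30)})
        b = pd.DataFrame({"position": rng.normal(1, 1, 30),
                          "height": rng.random(30)})
        assert od.triangle_compare(a, b) == pytest.approx(
            od.triangle_compare(b, a))

    def test_axis_group_test_shifted_normals(self):
        rng = np.random.default_rng(8)
        coords = pd.DataFrame(
            np.concatenate([rng.normal(0, 1, (15, 2)),
                            rng.normal([3, 0], 1, (15, 2))]),
            index=[f"s{i}" for i in range(30)])
        ga = [f"s{i}" for i in range(15)]
        gb = [f"s{i}" for i in range(15, 30)]
        assert od.axis_group_test(coords, 0, ga, gb) < 0.001

    def test_axis_test_rank_invariance(self):
        rng = np.random.default_rng(9)
        coords = pd.DataFrame(rng.normal(size=(30, 1)),
                              index=[f"s{i}" for i in range(30)])
        ga, gb = list(coords.index[:15]), list(coords.index[15:])
        p_raw = od.axis_group_test(coords, 0, ga, gb)
        p_mono = od.axis_group_test(np.exp(coords), 0, ga, gb)
        assert p_raw == pytest.approx(p_mono)
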