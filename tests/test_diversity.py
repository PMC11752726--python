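import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode
from skbio.diversity.alpha import faith_pd as skbio_faith_pd

from hybridbiome import diversity as dv
from hybridbiome._tree import BranchIndex, is_ultrametric
from hybridbiome.simulate import simulate_tree


class TestAlphaDiversity:
    def test_shannon_uniform_two_taxa(self):
        assert dv.alpha_diversity([5, 5], "shannon") == pytest.approx(np.log(2))

    def test_simpson_is_gini_form(self):
        assert dv.alpha_diversity([1, 1, 1, 1], "simpson") == pytest.approx(0.75)

    def test_richness_counts_presences(self):
        assert dv.alpha_diversity([3, 0, 1, 0], "richness") == 2

    def test_faith_single_tip_includes_root_path(self, four_tip_tree):
        v = dv.alpha_diversity([1, 0, 0, 0], "faith_pd", tree=four_tip_tree,
                               taxa=list("ABCD"))
        assert v == pytest.approx(2.0)

    def test_faith_all_tips_is_total_length(self, four_tip_tree):
        v = dv.alpha_diversity([1, 1, 1, 1], "faith_pd", tree=four_tip_tree,
                               taxa=list("ABCD"))
        assert v == pytest.approx(6.0)

    def test_faith_matches_reference_implementation(self):
        """Independent cross-check of our branch-index Faith's PD against
        scikit-bio on random trees and communities."""
        rng = np.random.default_rng(0)
        for seed in range(10):
            tree = simulate_tree(12, seed=seed)
            taxa = [t.name for t in tree.tips()]
            counts = (rng.random(12) < 0.5).astype(int)
            if counts.sum() == 0:
                counts[0] = 1
            ours = dv.alpha_diversity(counts, "faith_pd", tree=tree, taxa=taxa)
            theirs = skbio_faith_pd(counts, taxa, tree)
            assert ours == pytest.approx(theirs, rel=1e-9)

    def test_faith_monotone_in_community(self, four_tip_tree):
        small = dv.alpha_diversity([1, 0, 0, 0], "faith_pd",
                                   tree=four_tip_tree, taxa=list("ABCD"))
        large = dv.alpha_diversity([1, 1, 0, 1], "faith_pd",
                                   tree=four_tip_tree, taxa=list("ABCD"))
        assert small <= large

    def test_empty_sample_shannon_errors(self):
        with pytest.raises(ValueError, match="empty"):
            dv.alpha_diversity([0, 0], "shannon")

    def test_rao_requires_ultrametric(self, four_tip_tree):
        skewed = TreeNode.read(["((A:1,B:3):1,(C:1,D:1):1):0;"])
        with pytest.raises(ValueError, match="ultrametric"):
            dv.alpha_diversity([1, 1, 1, 1], "rao_q", tree=skewed,
                               taxa=list("ABCD"))

    def test_rao_hand_value(self, four_tip_tree):
        # equal abundances on A and C: d(A,C) = 4, p_A = p_C = 0.5
        # rao = 2 * 0.5 * 0.5 * 4 = 2
        v = dv.alpha_diversity([1, 0, 1, 0], "rao_q", tree=four_tip_tree,
                               taxa=list("ABCD"))
        assert v == pytest.approx(2.0)


class TestUltrametricize:
    def test_fixed_point(self, four_tip_tree):
        out = dv.ultrametricize_mpl(four_tip_tree)
        depths = {t.name: t.accumulate_to_ancestor(out) for t in out.tips()}
        assert max(depths.values()) - min(depths.values()) < 1e-9
        assert depths["A"] == pytest.approx(2.0)

    def test_cherry_mean_of_path_lengths(self):
        tree = TreeNode.read(["(A:1,B:3):0;"])
        out = dv.ultrametricize_mpl(tree)
        depths = [t.accumulate_to_ancestor(out) for t in out.tips()]
        assert depths == pytest.approx([2.0, 2.0])

    def test_multichotomy_resolved_tips_preserved(self):
        tree = TreeNode.read(["(A:1,B:1,C:1,D:1):0;"])
        out = dv.ultrametricize_mpl(tree)
        assert sorted(t.name for t in out.tips()) == ["A", "B", "C", "D"]
        assert all(len(n.children) <= 2 for n in out.traverse())
        assert is_ultrametric(out, tol=1e-9)


class TestChaoAssemblage:
    def test_no_singletons_no_undetected(self):
        prof = dv.IncidenceProfile(T=10, frequencies=pd.Series(
            [2, 3, 5], index=list("abc")))
        asm = dv.chao_assemblage(prof)
        assert asm.q0 == 0 and asm.q0_hat == 0.0

    def test_chao2_worked_value(self):
        # T=15, Q1=2, Q2=1 -> Q0_hat = (14/15) * 4 / 2 = 1.8667
        prof = dv.IncidenceProfile(T=15, frequencies=pd.Series(
            [1, 1, 2, 6, 9], index=list("abcde")))
        asm = dv.chao_assemblage(prof)
        assert asm.q0_hat == pytest.approx((14 / 15) * 4 / 2, rel=1e-12)
        assert asm.q0 == 2

    def test_observed_only_drops_undetected(self):
        prof = dv.IncidenceProfile(T=15, frequencies=pd.Series(
            [1, 1, 2, 6, 9], index=list("abcde")))
        asm = dv.chao_assemblage(prof, observed_only=True)
        assert asm.q0 == 0
        assert asm.all_taxa() == list("abcde")

    def test_probabilities_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            T = 15
            y = pd.Series(rng.integers(1, T + 1, size=30),
                          index=[f"t{i}" for i in range(30)])
            asm = dv.chao_assemblage(dv.IncidenceProfile(T=T, frequencies=y))
            p = asm.all_probabilities()
            assert ((p > 0) & (p <= 1)).all()

    def test_empty_population_errors(self):
        with pytest.raises(ValueError):
            dv.IncidenceProfile(T=5, frequencies=pd.Series([0], index=["a"]))
        prof = dv.IncidenceProfile(T=5, frequencies=pd.Series([], dtype=int))
        with pytest.raises(ValueError, match="empty"):
            dv.chao_assemblage(prof)


class TestBootstrapDraws:
    def test_certain_taxa_always_present(self):
        asm = dv.BootstrapAssemblage(taxa=list("ab"), pi=np.array([1.0, 1.0]),
                                     q0=0, pi0=None)
        draw = dv.draw_bootstrap_population(asm, n=15, seed=0)
        assert draw.values.all()

    def test_mean_occupancy_matches_probability(self):
        asm = dv.BootstrapAssemblage(taxa=list("ab"), pi=np.array([0.5, 0.5]),
                                     q0=0, pi0=None)
        rng = np.random.default_rng(7)
        draws = dv.draw_bootstrap_matrix(asm, n=15, B=10_000, rng=rng)
        assert draws.mean() == pytest.approx(0.5, abs=0.02)

    def test_seed_reproducibility(self):
        asm = dv.BootstrapAssemblage(taxa=list("abc"),
                                     pi=np.array([0.2, 0.5, 0.9]),
                                     q0=1, pi0=0.1)
        a = dv.draw_bootstrap_population(asm, n=15, seed=3)
        b = dv.draw_bootstrap_population(asm, n=15, seed=3)
        assert (a.values == b.values).all()
        assert list(a.index) == ["a", "b", "c", "undetected_0"]


def _pairwise_jaccard(x, y):
    x, y = np.asarray(x, bool), np.asarray(y, bool)
    union = (x | y).sum()
    return (union - (x & y).sum()) / union


class TestMultisiteBeta:
    def test_identical_sites_zero(self):
        inc = pd.DataFrame(np.ones((4, 5), dtype=bool))
        assert dv.multisite_beta(inc) == 0.0

    def test_disjoint_sites_one(self):
        inc = pd.DataFrame(np.eye(3, dtype=bool))
        assert dv.multisite_beta(inc) == 1.0

    def test_two_site_hand_value(self):
        inc = pd.DataFrame({"s1": [1, 1, 0], "s2": [0, 1, 1]},
                           index=list("ABC"))
        assert dv.multisite_beta(inc) == pytest.approx(2 / 3)

    def test_pairwise_jaccard_reduction(self):
        """For N=2, the multisite formula equals pairwise Jaccard
        dissimilarity; checked on 100 random instances."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            x = rng.random(12) < 0.6
            y = rng.random(12) < 0.6
            if not x.any() or not y.any():
                continue
            ours = dv.multisite_beta(np.column_stack([x, y]))
            assert ours == pytest.approx(_pairwise_jaccard(x, y), abs=1e-12)

    def test_phylo_two_site_reduction(self):
        """For N=2, phylogenetic multisite beta equals the branch-set
        Jaccard dissimilarity computed by brute-force enumeration."""
        rng = np.random.default_rng(6)
        for seed in range(25):
            tree = simulate_tree(8, seed=seed)
            taxa = [t.name for t in tree.tips()]
            bi = BranchIndex(tree, taxa)
            x = rng.random(8) < 0.6
            y = rng.random(8) < 0.6
            if not x.any() or not y.any():
                continue
            bx = bi.presence_to_branches(x)
            by = bi.presence_to_branches(y)
            union = bi.lengths[bx | by].sum()
            shared = bi.lengths[bx & by].sum()
            expected = (union - shared) / union
            ours = dv.multisite_beta(
                pd.DataFrame({"a": x, "b": y}, index=taxa),
                family="phylo_jaccard", tree=tree)
            assert ours == pytest.approx(expected, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            dv.multisite_beta(np.ones((3, 1), dtype=bool))
        with pytest.raises(ValueError, match="empty"):
            dv.multisite_beta(np.array([[1, 0], [1, 0]]))


class TestGammaDiversity:
    def test_single_site_equals_alpha(self):
        inc = np.array([[1], [0], [1]])
        assert dv.gamma_diversity(inc) == 2

    def test_disjoint_sites_sum(self):
        inc = np.eye(4)
        assert dv.gamma_diversity(inc) == 4

    def test_union_brute_force(self):
        rng = np.random.default_rng(2)
        inc = rng.random((20, 3)) < 0.4
        expected = len({i for i in range(20) if inc[i].any()})
        assert dv.gamma_diversity(inc) == expected

    def test_gamma_at_least_max_alpha(self):
        rng = np.random.default_rng(3)
        inc = rng.random((30, 6)) < 0.5
        gamma = dv.gamma_diversity(inc)
        assert gamma >= inc.sum(axis=0).max()


class TestCoreSets:
    def test_eight_hosts_at_fifteen(self):
        assert dv.core_threshold(15, 0.5) == 8

    def test_zero_threshold_is_union(self):
        inc = pd.DataFrame(np.eye(3, dtype=bool), index=list("abc"))
        assert dv.core_set(inc, f=0.0) == {"a", "b", "c"}

    def test_half_of_four_needs_two(self):
        inc = pd.DataFrame([[1, 1, 0, 0]], index=["a"])
        assert dv.core_set(inc, f=0.5) == {"a"}

    def test_unique_core_all_identical_empty(self):
        cores = {p: {"x", "y"} for p in ("h1", "h2", "m", "f")}
        roles = {"h1": "hybrid", "h2": "hybrid", "m": "maternal",
                 "f": "paternal"}
        assert all(s == set() for s in dv.unique_core_set(cores, roles).values())

    def test_hybrid_unique_despite_other_hybrid(self):
        cores = {"h1": {"x"}, "h2": {"x"}, "m": {"y"}, "f": {"z"}}
        roles = {"h1": "hybrid", "h2": "hybrid", "m": "maternal",
                 "f": "paternal"}
        unique = dv.unique_core_set(cores, roles)
        assert unique["h1"] == {"x"} and unique["h2"] == {"x"}

    def test_progenitor_rule_brute_force(self):
        cores = {"h1": {"a", "b"}, "h2": {"b", "c"}, "m": {"a", "d"},
                 "f": {"d", "e"}}
        roles = {"h1": "hybrid", "h2": "hybrid", "m": "maternal",
                 "f": "paternal"}
        unique = dv.unique_core_set(cores, roles)
        assert unique["m"] == {"a"} - ({"a", "b"} | {"b", "c"} | {"d", "e"})
        assert unique["f"] == {"e"}
        assert unique["h1"] == {"b"}  # excluded only by progenitor cores
        assert unique["h2"] == {"b", "c"}


class TestConfidenceIntervals:
    def test_order_statistics_b500(self):
        lo, hi = dv.ci_from_bootstraps(np.arange(1, 501))
        assert (lo, hi) == (83, 417)

    def test_constant_vector_degenerate(self):
        lo, hi = dv.ci_from_bootstraps(np.full(500, 7.0))
        assert (lo, hi) == (7.0, 7.0)

    def test_scaling_to_b1000(self):
        lo, hi = dv.ci_from_bootstraps(np.arange(1, 1001))
        assert (lo, hi) == (166, 834)

    def test_overlap_rule(self):
        assert dv.ci_overlap_test((1, 2), (3, 4))
        assert not dv.ci_overlap_test((1, 3), (2, 4))
        assert not dv.ci_overlap_test((1, 2), (2, 3))  # touching = overlap


class TestGroupTests:
    def test_identical_groups_not_significant(self):
        groups = {k: np.ones(10) for k in "abcd"}
        res = dv.group_tests(groups)
        assert res.omnibus_p > 0.9
        assert res.pairwise is None

    def test_separated_groups_strongly_significant(self):
        rng = np.random.default_rng(0)
        groups = {
            "a": rng.normal(0, 1, 15), "b": rng.normal(0, 1, 15),
            "c": rng.normal(10, 1, 15), "d": rng.normal(10, 1, 15),
        }
        res = dv.group_tests(groups)
        assert res.omnibus_p < 1e-6
        assert res.pairwise_p("a", "c") < 0.001

    def test_two_group_mode(self):
        rng = np.random.default_rng(1)
        res = dv.group_tests({"x": rng.normal(0, 1, 15),
                              "y": rng.normal(5, 1, 15)})
        assert res.omnibus_test == "mannwhitneyu"
        assert res.omnibus_p < 0.001

    def test_small_group_errors(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            dv.group_tests({"a": [1.0], "b": [1.0, 2.0]})

    def test_null_p_values_roughly_uniform(self):
        """Permuted labels give a flat p-value distribution."""
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(300):
            pooled = rng.normal(size=60)
            groups = {k: pooled[i * 15:(i + 1) * 15]
                      for i, k in enumerate("abcd")}
            ps.append(dv.group_tests(groups).omnibus_p)
        # 5% of omnibus tests should reject at alpha = 0.05, very roughly
        rate = np.mean(np.array(ps) <= 0.05)
        assert 0.01 <= rate <= 0.12


class TestBootstrapSuite:
    def test_long_format_and_percent_bounds(self, sim_dataset, sim_pops):
        table, _, tree = sim_dataset
        inc = table.incidence()
        roles = {p: table.metadata.loc[ids[0], "role"]
                 for p, ids in sim_pops.items()}
        long = dv.bootstrap_core_suite(
            {p: inc[ids] for p, ids in sim_pops.items()}, roles, tree=tree,
            metric="richness", f=0.5, B=40, n=15, seed=0)
        assert set(long["trait"]) == set(dv.CORE_TRAITS)
        pct = long[long["trait"].str.startswith("pct")]["value"].dropna()
        assert ((pct >= 0) & (pct <= 100)).all()
        assert len(long) == 4 * 40 * len(dv.CORE_TRAITS)

    def test_clonal_hybrid_has_lower_beta(self):
        """Low-occupancy-variance (clone-like) populations show lower
        interindividual turnover than heterogeneous ones."""
        rng = np.random.default_rng(10)
        n_taxa, n = 80, 15
        hits = 0
        runs = 20
        for _ in range(runs):
            clone = rng.random((n_taxa, n)) < 0.9
            hetero = rng.random((n_taxa, n)) < rng.beta(0.4, 0.4, n_taxa)[:, None]
            if not (hetero.sum(axis=0) > 0).all():
                hetero[0] = True
            b_clone = dv.multisite_beta(clone)
            b_het = dv.multisite_beta(hetero)
            hits += b_clone < b_het
        assert hits >= int(0.95 * runs)
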