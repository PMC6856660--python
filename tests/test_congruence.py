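import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

import oracles
from conftest import small_config
from phylosym.congruence import (
    collapse_by_group,
    congruence_pipeline,
    jackknife_support,
    partial_mantel,
    patristic_distances,
    pvr_manova,
    random_tree_null,
    random_tree_topology,
    robinson_foulds_normalized,
    upgma,
)
from phylosym.containers import OtuTable
from phylosym.simulate import simulate_community


class TestCollapse:
    def _table_md(self):
        counts = pd.DataFrame(
            [[8, 2, 0], [4, 1, 0], [0, 5, 5]],
            index=["s1", "s2", "s3"],
            columns=["o1", "o2", "o3"],
        )
        md = pd.DataFrame(
            {"sample_type": "skin", "species": ["x", "x", "y"],
             "locality": "L", "microhabitat": "m", "grp": ["gx", "gx", "gy"]},
            index=counts.index,
        )
        return OtuTable(counts), md

    def test_single_sample_group_equals_its_profile(self):
        table, md = self._table_md()
        out = collapse_by_group(table, md, "grp")
        np.testing.assert_allclose(out.loc["gy"], [0, 0.5, 0.5])

    def test_identical_samples_collapse_to_same_profile(self):
        table, md = self._table_md()
        out = collapse_by_group(table, md, "grp")
        np.testing.assert_allclose(out.loc["gx"], [0.8, 0.2, 0.0])

    def test_rows_sum_to_one(self):
        table, md = self._table_md()
        for mode in ("mean", "pooled"):
            out = collapse_by_group(table, md, "grp", mode=mode)
            np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)


class TestUpgma:
    def test_hand_agglomeration(self):
        dm = DistanceMatrix(np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float), ids=list("ABC"))
        tree = upgma(dm).tree
        a = tree.find("A")
        assert a.length == pytest.approx(1.0)  # A,B merge at height 1
        root_children_heights = sorted(
            tree.find(t).accumulate_to_ancestor(tree) for t in "ABC"
        )
        assert root_children_heights == pytest.approx([2.0, 2.0, 2.0])  # +C at height 2

    def test_ultrametric_input_reproduced_cophenetically(self):
        # build an ultrametric matrix from a known dendrogram
        d = np.array(
            [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]], float
        )
        dm = DistanceMatrix(d, ids=list("ABCD"))
        tree = upgma(dm).tree
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    coph = tree.find(a).distance(tree.find(b))
                    assert coph == pytest.approx(d[i, j], abs=1e-12)

    def test_two_labels_single_cherry_at_half_distance(self):
        dm = DistanceMatrix(np.array([[0, 3.0], [3.0, 0]]), ids=["x", "y"])
        tree = upgma(dm).tree
        assert tree.find("x").length == pytest.approx(1.5)

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            upgma(DistanceMatrix(np.zeros((1, 1)), ids=["x"]))


class TestRobinsonFoulds:
    def test_identical_topologies_zero(self):
        a = TreeNode.read(["((A,B),(C,(D,E)));"])
        b = TreeNode.read(["((B,A),((D,E),C));"])
        assert robinson_foulds_normalized(a, b) == 0.0

    def test_no_shared_clades_is_one(self):
        a = TreeNode.read(["((A,B),(C,D));"])
        b = TreeNode.read(["((A,C),(B,D));"])
        assert robinson_foulds_normalized(a, b) == 1.0

    def test_five_tip_single_shared_clade_two_thirds(self):
        # clades a: {AB},{CD},{ABCD...}: ((A,B),((C,D),E)) -> {AB},{CD},{CDE}
        # clades b: ((A,C),((B,D),E)) -> {AC},{BD},{BDE}; share none -> craft
        a = TreeNode.read(["(((A,B),C),(D,E));"])  # {AB},{ABC},{DE}
        b = TreeNode.read(["(((D,E),A),(B,C));"])  # {DE},{ADE},{BC}
        # shared: {DE}; symdiff 4 of 6
        assert robinson_foulds_normalized(a, b) == pytest.approx(4 / 6)

    def test_mismatching_tips_rejected(self):
        a = TreeNode.read(["((A,B),C);"])
        b = TreeNode.read(["((A,B),D);"])
        with pytest.raises(ValueError, match="differ"):
            robinson_foulds_normalized(a, b)

    def test_pseudometric_properties_random_topologies(self):
        rng = np.random.default_rng(0)
        labels = list("ABCDEF")
        for _ in range(30):
            ta = random_tree_topology(labels, rng)
            tb = random_tree_topology(labels, rng)
            d_ab = robinson_foulds_normalized(ta, tb)
            assert 0 <= d_ab <= 1
            assert d_ab == pytest.approx(robinson_foulds_normalized(tb, ta))
            same_clades = oracles.treenode_clades(ta) == oracles.treenode_clades(tb)
            assert (d_ab == 0) == same_clades


class TestRandomTreeNull:
    def test_uniform_over_topologies_four_tips(self):
        """Random addition hits all 15 rooted 4-tip topologies uniformly."""
        rng = np.random.default_rng(1)
        from collections import Counter

        c = Counter()
        n = 3000
        for _ in range(n):
            t = random_tree_topology(list("ABCD"), rng)
            c[frozenset(oracles.treenode_clades(t))] += 1
        assert len(c) == 15
        chi2 = sum((obs - n / 15) ** 2 / (n / 15) for obs in c.values())
        from scipy.stats import chi2 as chi2_dist

        assert chi2 > 0
        assert chi2_dist.sf(chi2, 14) > 0.01

    def test_observed_one_gives_p_one(self):
        ref = TreeNode.read(["((A,B),(C,(D,E)));"])
        res = random_tree_null(ref, 1.0, n_random=200, seed=0)
        assert res.p_value == 1.0

    def test_perfect_congruence_p_matches_exact_enumeration(self):
        ref = TreeNode.read(["(((A,B),C),(D,E));"])
        exact = oracles.exact_nrf_null(ref)
        p_exact = (exact <= 0).mean()  # 1/105 for binary 5-tip reference
        assert p_exact == pytest.approx(1 / 105)
        res = random_tree_null(ref, 0.0, n_random=1000, seed=3)
        se = np.sqrt(p_exact * (1 - p_exact) / 1000)
        assert abs(res.p_value - p_exact) < 3 * se + 2 / 1001

    def test_invalid_observed_rejected(self):
        ref = TreeNode.read(["((A,B),C);"])
        with pytest.raises(ValueError):
            random_tree_null(ref, 1.5, n_random=10, seed=0)


class TestPatristic:
    def test_hand_path_sums(self):
        t = TreeNode.read(["((A:1,B:1):1,C:2);"])
        dm = patristic_distances(t)
        assert dm["A", "B"] == pytest.approx(2.0)
        assert dm["A", "C"] == pytest.approx(4.0)
        assert dm["B", "C"] == pytest.approx(4.0)

    def test_ultrametric_distance_is_twice_mrca_height(self):
        from phylosym.simulate import simulate_host_tree

        t = simulate_host_tree(6, seed=2)
        dm = patristic_distances(t)
        height = list(t.tips())[0].accumulate_to_ancestor(t)
        lca = t.lowest_common_ancestor([list(t.tips())[0].name, list(t.tips())[1].name])
        assert np.allclose(dm.data, dm.data.T)
        assert np.allclose(np.diag(dm.data), 0)
        assert dm.data.max() <= 2 * height + 1e-9

    def test_missing_length_named(self):
        t = TreeNode.read(["((A:1,B):1,C:2);"])
        with pytest.raises(ValueError, match="B"):
            patristic_distances(t)


class TestPartialMantel:
    @staticmethod
    def _rand_dm(rng, ids):
        pts = rng.normal(size=(len(ids), 2))
        return DistanceMatrix(squareform(pdist(pts)), ids=ids)

    def test_identical_target_and_other_r_near_one(self):
        rng = np.random.default_rng(4)
        ids = [f"g{i}" for i in range(7)]
        a = self._rand_dm(rng, ids)
        c = self._rand_dm(rng, ids)
        res = partial_mantel(a, a, c, n_perm=99, seed=0)
        assert res.statistic > 0.999

    def test_matches_three_correlation_formula(self):
        rng = np.random.default_rng(5)
        ids = list("abcde")
        a, b, c = (self._rand_dm(rng, ids) for _ in range(3))
        res = partial_mantel(a, b, c, n_perm=9, seed=0)

        def off(m):
            iu, ju = np.triu_indices(5, 1)
            return m.data[iu, ju]

        r_ab = np.corrcoef(off(a), off(b))[0, 1]
        r_ac = np.corrcoef(off(a), off(c))[0, 1]
        r_bc = np.corrcoef(off(b), off(c))[0, 1]
        expected = (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))
        assert res.statistic == pytest.approx(expected, abs=1e-12)

    def test_degenerate_control_rejected(self):
        rng = np.random.default_rng(6)
        ids = list("abcd")
        a = self._rand_dm(rng, ids)
        with pytest.raises(ValueError, match="degenerate"):
            partial_mantel(a, a.copy(), a.copy(), n_perm=9, seed=0)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        a = self._rand_dm(rng, list("abcd"))
        b = self._rand_dm(rng, list("abce"))
        with pytest.raises(ValueError):
            partial_mantel(a, b, a.copy(), n_perm=9, seed=0)


class TestPvrManova:
    def test_univariate_retained_space_equals_anova_f(self):
        from scipy import stats as sps

        from phylosym.congruence import _pillai_manova

        rng = np.random.default_rng(8)
        y = rng.normal(size=(12, 1))
        factor = pd.Series(np.repeat(list("ab"), 6), index=range(12))
        y[:6] += 1
        res = _pillai_manova(y, factor)
        f_ref = sps.f_oneway(y[:6, 0], y[6:, 0]).statistic
        assert res.extras["F"] == pytest.approx(f_ref, abs=1e-10)

    def test_locality_clustered_dendrogram_detects_locality_only(self):
        dend = TreeNode.read(
            ["(((A:1,B:1):1,(C:1.2,D:0.8):1):2,((E:1,F:1):1,(G:1,H:1):1):2);"]
        )
        factors = pd.DataFrame(
            {"locality": ["L1"] * 4 + ["L2"] * 4,
             "microhabitat": ["m1", "m2", "m1", "m2"] * 2},
            index=list("ABCDEFGH"),
        )
        res = {r.extras["term"]: r for r in pvr_manova(dend, factors)}
        assert res["locality"].p_value < 0.05
        assert res["microhabitat"].p_value > 0.05

    def test_unrelated_factor_p_uniformish(self):
        rng = np.random.default_rng(9)
        from phylosym.simulate import simulate_host_tree

        pvals = []
        for seed in range(60):
            t = simulate_host_tree(10, seed=1000 + seed)
            labels = [x.name for x in t.tips()]
            fac = pd.DataFrame(
                {"f": rng.permutation(["u"] * 5 + ["v"] * 5)}, index=labels
            )
            pvals.append(pvr_manova(t, fac)[0].p_value)
        rate = np.mean(np.asarray(pvals) < 0.05)
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 60)

    def test_insufficient_tips_rejected(self):
        dend = TreeNode.read(["((A:1,B:1):1,C:2);"])
        factors = pd.DataFrame({"f": ["x", "y", "z"]}, index=list("ABC"))
        with pytest.raises(ValueError):
            pvr_manova(dend, factors)


class TestJackknife:
    def test_full_depth_supports_all_one(self):
        ds = simulate_community(small_config(seed=31, species_effect=0.8, n_contaminants=0))
        skin = ds.metadata[ds.metadata["sample_type"] == "skin"]
        from phylosym.preprocess import rarefy

        tbl = rarefy(ds.otu_table.select_samples(list(skin.index)), depth=800, seed=0)
        dend = jackknife_support(
            tbl, ds.metadata, "group", ds.bacterial_tree,
            depth_fraction=1.0, n_reps=5, seed=0,
        )
        assert dend.supports
        assert all(v == 1.0 for v in dend.supports.values())

    def test_supports_are_rep_count_multiples(self):
        ds = simulate_community(small_config(seed=32, n_contaminants=0))
        skin = ds.metadata[ds.metadata["sample_type"] == "skin"]
        from phylosym.preprocess import rarefy

        tbl = rarefy(ds.otu_table.select_samples(list(skin.index)), depth=800, seed=0)
        dend = jackknife_support(
            tbl, ds.metadata, "group", ds.bacterial_tree,
            depth_fraction=0.75, n_reps=10, seed=0,
        )
        assert all(round(v * 10, 9) == int(round(v * 10)) for v in dend.supports.values())

    def test_invalid_depth_fraction(self, small_dataset):
        with pytest.raises(ValueError):
            jackknife_support(
                small_dataset.otu_table, small_dataset.metadata, "group",
                small_dataset.bacterial_tree, depth_fraction=0.0, n_reps=2, seed=0,
            )


class TestCongruencePipeline:
    @pytest.fixture(scope="class")
    def study_like_run(self):
        from phylosym.preprocess import rarefy
        from phylosym.simulate import SimulationConfig

        cfg = SimulationConfig(
            samples_per_group=4, n_environment_samples=4, n_control_samples=2,
            n_otus=120, environment_extra_otus=30, depth_mean=1200,
            control_depth_mean=150, n_contaminants=0, seed=17,
        )
        ds = simulate_community(cfg)
        skin = ds.metadata[ds.metadata["sample_type"] == "skin"]
        tbl = rarefy(ds.otu_table.select_samples(list(skin.index)), depth=900, seed=1)
        report = congruence_pipeline(
            tbl, ds.metadata, ds.bacterial_tree, ds.host_tree,
            n_perm=49, n_random=100, jackknife_reps=5, seed=2,
        )
        return ds, report

    def test_eight_dendrogram_tips_with_both_populations(self, study_like_run):
        ds, report = study_like_run
        assert len(report["groups"]) == 8  # 7 species + second population
        for metric_report in report["metrics"].values():
            tree = TreeNode.read([metric_report["dendrogram"]])
            assert len(list(tree.tips())) == 8

    def test_per_locality_nrf_present_and_bounded(self, study_like_run):
        _, report = study_like_run
        for metric_report in report["metrics"].values():
            for loc_result in metric_report["per_locality_nrf"].values():
                if loc_result.get("skipped"):
                    continue
                assert 0 <= loc_result["nrf"] <= 1
                assert 0 < loc_result["p_value"] <= 1

    def test_leave_one_group_out_supported(self, study_like_run):
        ds, full_report = study_like_run
        from phylosym.preprocess import rarefy

        skin = ds.metadata[ds.metadata["sample_type"] == "skin"]
        tbl = rarefy(ds.otu_table.select_samples(list(skin.index)), depth=900, seed=1)
        report = congruence_pipeline(
            tbl, ds.metadata, ds.bacterial_tree, ds.host_tree,
            n_perm=19, n_random=50, jackknife_reps=2, seed=2,
            exclude_groups=("E_cooki|Quebrada",),
        )
        assert len(report["groups"]) == 7
        assert "E_cooki|Quebrada" not in report["groups"]

    def test_missing_host_species_rejected(self, study_like_run):
        ds, _ = study_like_run
        from phylosym.preprocess import rarefy

        skin = ds.metadata[ds.metadata["sample_type"] == "skin"]
        tbl = rarefy(ds.otu_table.select_samples(list(skin.index)), depth=900, seed=1)
        pruned_host = ds.host_tree.shear(["E_coqui", "E_cooki", "E_richmondi"])
        with pytest.raises(ValueError, match="host tree missing"):
            congruence_pipeline(
                tbl, ds.metadata, ds.bacterial_tree, pruned_host,
                n_perm=9, n_random=20, jackknife_reps=2, seed=0,
            )
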