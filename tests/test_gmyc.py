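import math

import numpy as np
import pytest

from barcodelim.distances import DistanceMatrix
from barcodelim.gmyc import (BranchingIntervals, UltrametricityError,
                             branching_intervals, fit_multiple_threshold,
                             fit_single_threshold, likelihood_ratio_test,
                             mixed_loglik, null_loglik, upgma_tree)
from barcodelim.seq_io import read_tree
from barcodelim.simulate import (SimConfig, generate_dataset,
                                 simulate_coalescent_tree)

BALANCED4 = "((A:1,B:1):2,(C:1,D:1):2);"  # node heights {3, 1, 1}


class TestUpgma:
    def test_three_taxon_hand_agglomeration(self):
        d = np.array([[0.0, 0.2, 0.6],
                      [0.2, 0.0, 0.6],
                      [0.6, 0.6, 0.0]])
        tree = upgma_tree(DistanceMatrix(list("ABC"), d, "p"))
        heights = sorted(n.distance_from_tip()
                         for n in tree.preorder_internal_node_iter())
        assert heights == pytest.approx([0.1, 0.3])
        ab = tree.mrca(taxa=[t for t in tree.taxon_namespace
                             if t.label in "AB"])
        assert {l.taxon.label for l in ab.leaf_iter()} == {"A", "B"}

    def test_ultrametric_matrix_reproduced_exactly(self):
        tree_src = read_tree(BALANCED4)
        pdm = tree_src.phylogenetic_distance_matrix()
        taxa = sorted(tree_src.taxon_namespace, key=lambda t: t.label)
        ids = [t.label for t in taxa]
        d = np.array([[pdm.patristic_distance(a, b) for b in taxa]
                      for a in taxa])
        rebuilt = upgma_tree(DistanceMatrix(ids, d, "p"))
        pdm2 = rebuilt.phylogenetic_distance_matrix()
        taxa2 = {t.label: t for t in rebuilt.taxon_namespace}
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                assert pdm2.patristic_distance(taxa2[a], taxa2[b]) == \
                    pytest.approx(d[i, ids.index(b)], abs=1e-12)

    def test_two_taxa_cherry(self):
        d = np.array([[0.0, 0.3], [0.3, 0.0]])
        tree = upgma_tree(DistanceMatrix(["A", "B"], d, "p"))
        root = tree.seed_node
        assert root.distance_from_tip() == pytest.approx(0.15)


class TestBranchingIntervals:
    def test_threshold_below_root_gives_two_otus(self):
        iv = branching_intervals(read_tree(BALANCED4), threshold=2.9)
        assert iv.n_otus == 2
        assert sorted(sorted(g) for g in iv.otu_groups) == \
            [["A", "B"], ["C", "D"]]

    def test_threshold_above_tips_gives_singletons(self):
        iv = branching_intervals(read_tree(BALANCED4), threshold=0.1)
        assert iv.n_otus == 4
        assert all(len(g) == 1 for g in iv.otu_groups)

    def test_hand_enumeration_heights_3_1_1(self):
        iv = branching_intervals(read_tree(BALANCED4), threshold=2.0)
        # intervals: (3 -> 1), then (1 -> 0)
        assert iv.x == pytest.approx([2.0, 1.0])
        assert list(iv.events) == [2, 0]
        # above T both stems count toward k; below T, k = number of OTUs
        assert list(iv.k) == [2, 2]
        # the coalescent processes hold 2 lineages each in the tip interval
        assert list(iv.coal_idx) == [1, 1]
        assert list(iv.coal_n) == [2.0, 2.0]
        assert list(iv.n_total) == [2, 4]

    def test_lineage_counts_sum_to_branches_crossing(self):
        _, _, truth = generate_dataset(
            SimConfig(n_species=5, tips_per_species=3, seed=2),
            preset="separated")
        tree = read_tree(truth.genealogy)
        root_h = tree.seed_node.distance_from_tip()
        for frac in (0.2, 0.5, 0.9):
            iv = branching_intervals(tree, threshold=frac * root_h)
            # below T every crossing branch is in some coalescent process
            # and k holds the (constant) OTU count; above T all crossing
            # branches are diversification lineages
            for i in range(len(iv.x)):
                coal = iv.coal_n[iv.coal_idx == i].sum()
                singletons = iv.n_total[i] - coal
                if iv.k[i] == iv.n_total[i]:     # pure-Yule interval
                    assert coal == 0
                else:                            # coalescent interval
                    assert iv.k[i] == iv.n_otus
                    assert coal + (iv.n_otus - np.sum(
                        iv.coal_idx == i)) >= 0  # singleton OTUs implicit

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            branching_intervals(read_tree(BALANCED4), threshold=5.0)


class TestMixedLoglik:
    def test_hand_computed_balanced_tree(self):
        iv = branching_intervals(read_tree(BALANCED4), threshold=2.0)
        lam1, p1, lam2, p2 = 0.7, 1.1, 2.0, 0.9
        b1 = lam1 * 2 ** p1                       # interval (3 -> 1)
        b2 = lam1 * 2 ** p1 + lam2 * 2 * (2 * 1) ** p2   # interval (1 -> 0)
        expected = 2 * math.log(b1) - b1 * 2.0 - b2 * 1.0
        assert mixed_loglik(iv, lam1, p1, lam2, p2) == pytest.approx(expected)

    def test_threshold_at_tips_reduces_to_pure_yule(self):
        iv = branching_intervals(read_tree(BALANCED4), threshold=0.5)
        lam1, p1 = 0.9, 1.3
        b1 = lam1 * 2 ** p1
        b2 = lam1 * 4 ** p1
        expected = 2 * math.log(b1) - 2 * b1 - 1.0 * b2
        # lambda2 is irrelevant when every OTU is a singleton
        assert mixed_loglik(iv, lam1, p1, 5.0, 2.0) == pytest.approx(expected)
        assert mixed_loglik(iv, lam1, p1, 0.01, 0.5) == pytest.approx(expected)

    def test_one_otu_spanning_tree_matches_null_plus_constant_rate(self):
        # degenerate configuration: the whole tree is one coalescent
        # process, so the diversification term is the constant lambda1
        from barcodelim.gmyc import _TreeIndex, _intervals_for_stems
        tree = read_tree(BALANCED4)
        idx = _TreeIndex(tree)
        iv = _intervals_for_stems(idx, [tree.seed_node])
        assert iv.n_otus == 1 and list(iv.k) == [1, 1]
        lam2, p2 = 1.7, 0.8
        tiny = 1e-8
        mixed = mixed_loglik(iv, tiny, 1.0, lam2, p2)
        null = null_loglik(iv, lam2, p2)
        assert mixed == pytest.approx(null, abs=1e-4)

    def test_brute_force_interval_sum_on_simulated_tree(self):
        tree = simulate_coalescent_tree(10, theta=0.01, seed=4)
        root_h = tree.seed_node.distance_from_tip()
        T = 0.4 * root_h
        iv = branching_intervals(tree, T)
        params = (1.3, 0.9, 40.0, 1.1)

        # independent brute force: walk height slices between events
        heights = sorted({round(n.distance_from_tip(), 12)
                          for n in tree.preorder_internal_node_iter()},
                         reverse=True)
        edges = [(n.parent_node.distance_from_tip(), n.distance_from_tip(),
                  frozenset(l.taxon.label for l in n.leaf_iter()))
                 for n in tree.preorder_node_iter() if n.parent_node]
        stems = [leafset for ph, ch, leafset in edges if ch < T < ph]
        logL = 0.0
        bounds = heights + [0.0]
        for top, bottom in zip(bounds, bounds[1:]):
            hm = (top + bottom) / 2
            crossing = [(ph, ch, ls) for ph, ch, ls in edges
                        if ch < hm < ph]
            if hm > T:
                k = len(crossing)
                coal = 0.0
            else:
                k = len(stems)
                coal = 0.0
                for s in stems:
                    n_j = sum(1 for _, _, ls in crossing if ls <= s)
                    if n_j >= 2:
                        coal += (n_j * (n_j - 1)) ** params[3]
            b = params[0] * k ** params[1] + params[2] * coal
            n_events = sum(1 for h in heights if abs(h - bottom) < 1e-12)
            logL += n_events * math.log(b) - b * (top - bottom)
        assert mixed_loglik(iv, *params) == pytest.approx(logL, rel=1e-9)

    def test_rate_validation(self):
        iv = branching_intervals(read_tree(BALANCED4), threshold=2.0)
        with pytest.raises(ValueError):
            mixed_loglik(iv, -1.0, 1.0, 1.0, 1.0)


class TestLikelihoodRatioTest:
    def test_published_single_threshold_statistic(self):
        LR, p = likelihood_ratio_test(2495.37, 2539.71)
        assert LR == pytest.approx(88.68)
        assert p < 0.001

    def test_published_multiple_threshold_statistic(self):
        LR, _ = likelihood_ratio_test(2495.37, 2541.51)
        assert LR == pytest.approx(92.28)

    def test_equal_likelihoods(self):
        LR, p = likelihood_ratio_test(100.0, 100.0)
        assert LR == 0.0 and p == 1.0

    def test_negative_ratio_flags_optimizer_failure(self):
        with pytest.raises(ValueError, match="negative"):
            likelihood_ratio_test(100.0, 90.0)


class TestFitSingleThreshold:
    def test_recovers_species_count_on_clean_simulation(self):
        _, _, truth = generate_dataset(
            SimConfig(n_species=5, tips_per_species=4, seed=11),
            preset="separated")
        fit = fit_single_threshold(read_tree(truth.genealogy))
        assert fit.entities == 5
        assert fit.clusters == 5
        assert fit.partition.as_sets() == truth.partition.as_sets()
        assert fit.LR > 0 and fit.p_value < 0.05

    def test_entity_count_monotone_as_threshold_moves_tipward(self):
        _, _, truth = generate_dataset(
            SimConfig(n_species=4, tips_per_species=4, seed=13),
            preset="separated")
        fit = fit_single_threshold(read_tree(truth.genealogy))
        cand = fit.candidates.sort_values("threshold", ascending=False)
        ent = cand["entities"].to_numpy()
        assert ent[0] == 2 and ent[-1] == 16
        assert (np.diff(ent) >= 0).all()

    def test_confidence_set_brackets_point_estimate(self):
        _, _, truth = generate_dataset(
            SimConfig(n_species=5, tips_per_species=4, seed=11),
            preset="separated")
        fit = fit_single_threshold(read_tree(truth.genealogy))
        lo, hi = fit.entities_ci
        assert lo <= fit.entities <= hi

    def test_partition_invariant_under_time_rescaling(self):
        _, _, truth = generate_dataset(
            SimConfig(n_species=4, tips_per_species=4, seed=17),
            preset="separated")
        t1 = read_tree(truth.genealogy)
        fit1 = fit_single_threshold(t1)
        t2 = read_tree(truth.genealogy)
        for e in t2.preorder_edge_iter():
            if e.length is not None:
                e.length *= 37.0
        fit2 = fit_single_threshold(t2)
        assert fit1.partition.as_sets() == fit2.partition.as_sets()
        assert fit1.LR == pytest.approx(fit2.LR, abs=0.05)

    def test_non_ultrametric_tree_rejected(self):
        with pytest.raises(UltrametricityError):
            fit_single_threshold(read_tree("((A:1,B:2):1,(C:1,D:1):2);"))


class TestFitMultipleThreshold:
    def test_max_one_threshold_equals_single(self):
        _, _, truth = generate_dataset(
            SimConfig(n_species=4, tips_per_species=4, seed=19),
            preset="separated")
        tree = read_tree(truth.genealogy)
        single = fit_single_threshold(tree)
        multi = fit_multiple_threshold(tree, max_thresholds=1)
        assert multi.entities == single.entities
        assert multi.logL_gmyc == pytest.approx(single.logL_gmyc)

    def test_entities_never_below_single(self):
        _, _, truth = generate_dataset(
            SimConfig(n_species=5, tips_per_species=4, seed=23),
            preset="separated")
        tree = read_tree(truth.genealogy)
        single = fit_single_threshold(tree)
        multi = fit_multiple_threshold(tree)
        assert multi.entities >= single.entities

    def test_single_transition_depth_needs_no_extra_threshold(self):
        extra = 0
        n = 10
        for seed in range(n):
            _, _, truth = generate_dataset(
                SimConfig(n_species=5, tips_per_species=4, seed=100 + seed),
                preset="separated")
            fit = fit_multiple_threshold(read_tree(truth.genealogy))
            extra += len(fit.thresholds) > 1
        assert extra <= 0.2 * n
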