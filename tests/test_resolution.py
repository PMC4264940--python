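import numpy as np
import pytest

from barcodelim.consensus import build_report
from barcodelim.distances import DistanceMatrix, pairwise_distances
from barcodelim.gmyc import upgma_tree
from barcodelim.resolution import (diagnostic_sites, final_count,
                                   is_monophyletic, nj_tree,
                                   otu_accumulation_curve, resolve,
                                   sister_pairs, sympatry)
from barcodelim.seq_io import (Alignment, Partition, SpecimenRecord,
                               read_tree)
from barcodelim.simulate import SimConfig, generate_dataset


class TestNjTree:
    def additive_matrix(self):
        # unrooted tree: A,B on one side, C,D on the other, internal edge 2
        # A-B: 5, A-C: 9, A-D: 10, B-C: 8, B-D: 9, C-D: 5
        ids = list("ABCD")
        d = np.array([[0, 5, 9, 10],
                      [5, 0, 8, 9],
                      [9, 8, 0, 5],
                      [10, 9, 5, 0]], dtype=float)
        return DistanceMatrix(ids, d, "p")

    def test_additive_matrix_recovered_exactly(self):
        dm = self.additive_matrix()
        tree = nj_tree(dm)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(dm.ids):
            for j in range(i + 1, len(dm.ids)):
                b = dm.ids[j]
                assert pdm.patristic_distance(taxa[a], taxa[b]) == \
                    pytest.approx(dm.d[i, j], abs=1e-9)

    def test_three_taxa_midpoint_rooted(self):
        d = np.array([[0.0, 0.2, 0.5],
                      [0.2, 0.0, 0.5],
                      [0.5, 0.5, 0.0]], dtype=float)
        tree = nj_tree(DistanceMatrix(list("ABC"), d, "p"))
        assert len(tree.seed_node.child_nodes()) == 2
        # C is the outlier: midpoint falls on its pendant edge
        sides = [{l.taxon.label for l in c.leaf_iter()}
                 for c in tree.seed_node.child_nodes()]
        assert {"C"} in sides

    def test_matches_upgma_topology_on_ultrametric_input(self):
        for seed in (1, 2, 3):
            _, _, truth = generate_dataset(
                SimConfig(n_species=4, tips_per_species=3, seed=seed),
                preset="separated")
            tree = read_tree(truth.genealogy)
            pdm = tree.phylogenetic_distance_matrix()
            taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
            ids = [t.label for t in taxa]
            d = np.array([[pdm.patristic_distance(a, b) for b in taxa]
                          for a in taxa])
            dm = DistanceMatrix(ids, d, "p")
            nj_t, up_t = nj_tree(dm), upgma_tree(dm)
            nj_clades = {frozenset(l.taxon.label for l in n.leaf_iter())
                         for n in nj_t.preorder_internal_node_iter()}
            up_clades = {frozenset(l.taxon.label for l in n.leaf_iter())
                         for n in up_t.preorder_internal_node_iter()}
            assert nj_clades == up_clades

    def test_too_few_specimens(self):
        d = np.array([[0.0, 0.1], [0.1, 0.0]])
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], d, "p"))


class TestMonophyly:
    tree = "((A:1,B:1):1,(C:1,D:1):1);"

    def test_clade_is_monophyletic(self):
        assert is_monophyletic(read_tree(self.tree), {"A", "B"})

    def test_paraphyletic_pair(self):
        assert not is_monophyletic(read_tree(self.tree), {"A", "C"})

    def test_entire_leaf_set(self):
        assert is_monophyletic(read_tree(self.tree), {"A", "B", "C", "D"})

    def test_unknown_tip_errors(self):
        with pytest.raises(KeyError):
            is_monophyletic(read_tree(self.tree), {"A", "Z"})


class TestDiagnosticSites:
    def aln(self):
        return Alignment([
            SpecimenRecord("a1", "GGAAT"),
            SpecimenRecord("a2", "GGTAT"),
            SpecimenRecord("b1", "TGAAC"),
            SpecimenRecord("b2", "TGCAC"),
        ])

    def test_fixed_difference_found_one_based(self):
        sites = diagnostic_sites(self.aln(), {"a1", "a2"}, {"b1", "b2"})
        assert [s[0] for s in sites] == [1, 5]
        assert sites[0][1:] == ("G", "T")

    def test_overlapping_polymorphism_not_diagnostic(self):
        # position 3: A {A,T} vs B {A,C} share 'A'
        sites = diagnostic_sites(self.aln(), {"a1", "a2"}, {"b1", "b2"})
        assert 3 not in [s[0] for s in sites]

    def test_ambiguous_positions_ignored(self):
        aln = Alignment([SpecimenRecord("x", "GN"),
                         SpecimenRecord("y", "TA")])
        assert [s[0] for s in diagnostic_sites(aln, {"x"}, {"y"})] == [1]

    def test_singleton_group_allowed(self):
        sites = diagnostic_sites(self.aln(), {"a1"}, {"b1", "b2"})
        assert 1 in [s[0] for s in sites]

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_sites(self.aln(), {"a1"}, {"a1", "b1"})


class TestSisterPairs:
    def test_two_way_split(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        pairs = sister_pairs(tree, [{"A", "B"}, {"C", "D"}])
        assert pairs == [(frozenset("AB"), frozenset("CD"))]

    def test_ladder_resolved_innermost_first(self):
        tree = read_tree("(((A:1,B:1):1,C:2):1,D:3);")
        pairs = sister_pairs(tree, [{"A", "B"}, {"C"}, {"D"}])
        assert pairs[0] == (frozenset("AB"), frozenset("C"))
        assert pairs[1] == (frozenset("ABC"), frozenset("D"))

    def test_unsplit_unit_yields_nothing(self):
        tree = read_tree("((A:1,B:1):1,C:2);")
        assert sister_pairs(tree, [{"A", "B", "C"}]) == []

    def test_member_missing_from_tree(self):
        tree = read_tree("((A:1,B:1):1,C:2);")
        with pytest.raises(KeyError):
            sister_pairs(tree, [{"A"}, {"Z"}])


class TestSympatry:
    def test_shared_region(self):
        assert sympatry({"SWP"}, {"SWP", "EYR"})

    def test_disjoint_regions_allopatric(self):
        assert not sympatry({"SWP"}, {"EYR"})

    def test_identical_singleton_regions(self):
        assert sympatry({"SWP"}, {"SWP"})

    def test_missing_regions_error(self):
        with pytest.raises(ValueError):
            sympatry(set(), {"SWP"})


def partial_scenario(region_b2):
    """Two methods split {a...}/{b...}, one merges; regions configurable."""
    seqs = {
        "a1": "GGGGGAAAAA", "a2": "GGGGGAAAAT",
        "b1": "CCCCCAAAAA", "b2": "CCCCCAAAAT",
        "o1": "TTTTTTTTTT", "o2": "TTTTTTTTTG",
    }
    regions = {"a1": "R1", "a2": "R1", "b1": "R2", "b2": region_b2,
               "o1": "R9", "o2": "R9"}
    records = [SpecimenRecord(k, v, region=regions[k])
               for k, v in seqs.items()]
    aln = Alignment(records)
    ids = aln.ids
    split = [["a1", "a2"], ["b1", "b2"], ["o1", "o2"]]
    merged = [["a1", "a2", "b1", "b2"], ["o1", "o2"]]
    p1 = Partition.from_groups(split, "abgd", ids)
    p2 = Partition.from_groups(split, "gmyc", ids)
    p3 = Partition.from_groups(merged, "resl", ids)
    report = build_report([p1, p2, p3])
    tree = nj_tree(pairwise_distances(aln, "p"))
    return report, tree, aln


class TestResolve:
    def test_allopatric_sisters_merged(self):
        report, tree, aln = partial_scenario(region_b2="R2")
        final, decisions = resolve(report, tree, aln)
        assert final.n_otus == 2
        d = [x for x in decisions if x.decision == "MERGED"]
        assert len(d) == 1 and not d[0].sympatric

    def test_sympatric_sisters_kept(self):
        report, tree, aln = partial_scenario(region_b2="R1")
        final, decisions = resolve(report, tree, aln)
        assert final.n_otus == 3
        kept = [x for x in decisions if x.decision == "SPLIT_KEPT"]
        assert len(kept) == 1 and kept[0].sympatric
        assert "microallopatric" in kept[0].warning

    def test_diagnostics_and_monophyly_reported_not_decisive(self):
        report, tree, aln = partial_scenario(region_b2="R2")
        _, decisions = resolve(report, tree, aln)
        # the a/b split has fixed differences at 5 positions, yet the
        # allopatric pair is still merged
        assert decisions[0].diagnostic_count == 5
        assert decisions[0].decision == "MERGED"

    def test_missing_region_label_names_specimen(self):
        report, tree, aln = partial_scenario(region_b2="R2")
        regions = aln.regions()
        regions["b2"] = None
        with pytest.raises(ValueError, match="b2"):
            resolve(report, tree, aln, regions)

    def test_all_full_report_passes_through(self, separated_dataset):
        aln, _, truth = separated_dataset
        ids = aln.ids
        groups = list(truth.partition.groups().values())
        parts = [Partition.from_groups(groups, m, ids)
                 for m in ("abgd", "gmyc", "resl")]
        report = build_report(parts)
        assert all(u.category == "FULL" for u in report.units)
        tree = nj_tree(pairwise_distances(aln, "p"))
        final, decisions = resolve(report, tree, aln)
        assert final.partition.as_sets() == truth.partition.as_sets()
        assert decisions == []
        assert final.bookkeeping["FULL"] == truth.partition.n_otus

    def test_resolution_is_idempotent(self):
        report, tree, aln = partial_scenario(region_b2="R2")
        final, _ = resolve(report, tree, aln)
        groups = list(final.partition.groups().values())
        parts = [Partition.from_groups(groups, m, aln.ids)
                 for m in ("abgd", "gmyc", "resl")]
        report2 = build_report(parts)
        final2, _ = resolve(report2, tree, aln)
        assert final2.partition.as_sets() == final.partition.as_sets()

    def test_final_sandwiched_between_finest_and_coarsest(self):
        report, tree, aln = partial_scenario(region_b2="R2")
        final, _ = resolve(report, tree, aln)
        finest = {frozenset(b) for u in report.units
                  for b in u.split_candidate}
        for block in final.partition.as_sets():
            assert any(piece <= block for piece in finest)
            covering = [u for u in report.units
                        if block <= frozenset(u.members)]
            assert len(covering) == 1  # never merges across units


class TestFinalCount:
    def test_published_bookkeeping(self):
        assert final_count(96, 3 + 5 + 14, 2) == 120

    def test_degenerate_cases(self):
        assert final_count(7, 0, 0) == 7
        assert final_count(0, 0, 4) == 4

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            final_count(-1, 0, 0)


class TestAccumulationCurve:
    def test_single_otu_constant_one(self):
        p = Partition.from_groups([["a", "b", "c"]], "final", list("abc"))
        curve = otu_accumulation_curve(p, n_permutations=10, seed=1)
        assert (curve["mean_otus"] == 1.0).all()

    def test_all_singletons_identity_line(self):
        ids = list("abcde")
        p = Partition.from_groups([[i] for i in ids], "final", ids)
        curve = otu_accumulation_curve(p, n_permutations=5, seed=1)
        assert curve["mean_otus"].tolist() == [1, 2, 3, 4, 5]
        assert (curve["sd_otus"] == 0).all()

    def test_deterministic_under_seed(self):
        ids = [f"s{i}" for i in range(10)]
        p = Partition.from_groups([ids[:3], ids[3:5], ids[5:]], "final", ids)
        c1 = otu_accumulation_curve(p, 20, seed=5)
        c2 = otu_accumulation_curve(p, 20, seed=5)
        assert c1.equals(c2)
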