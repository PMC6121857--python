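import itertools

import numpy as np
import pytest

from radhap import geometry
from radhap.genealogy import (
    GeneTree,
    build_tree_from_merges,
    calibrate_tmrca,
    check_outgroup_monophyly,
    classify_lineage_sorting,
    extract_outgroup_edits,
    haplotype_network,
    pairwise_diff_matrix,
    reconstruct_outgroup_haplotype,
    upgma_tree,
)

import _oracles as oracles
from conftest import random_locus_seq


def random_tree(rng, labels):
    """Random binary clock tree over labels with random merge heights."""
    clusters = [frozenset([l]) for l in labels]
    heights = sorted(rng.uniform(0.1, 10.0, size=len(labels) - 1))
    merges = []
    for h in heights:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        a, b = clusters[i], clusters[j]
        merges.append((a, b, h))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [a | b]
    pops = {l: ("OUT" if l == "outgroup" else l.split("_")[-2]) for l in labels}
    return build_tree_from_merges(labels, merges, populations=pops)


class TestPairwiseDiffMatrix:
    def test_identical_and_two_diffs(self):
        d = pairwise_diff_matrix(["AAAA", "AAAA", "AATT"])
        assert d[0, 1] == 0
        assert d[0, 2] == pytest.approx(2 / 4)
        assert (d == d.T).all()
        assert (np.diag(d) == 0).all()

    def test_matches_bruteforce_on_random_fixtures(self, rng):
        for _ in range(10):
            seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(6)]
            d = pairwise_diff_matrix(seqs)
            for i in range(6):
                for j in range(6):
                    expect = sum(a != b for a, b in zip(seqs[i], seqs[j])) / 30
                    assert d[i, j] == pytest.approx(expect)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            pairwise_diff_matrix(["AA", "AAA"])


class TestUpgma:
    def test_three_taxon_textbook(self):
        d = np.array([[0, 2.0, 6.0], [2.0, 0, 6.0], [6.0, 6.0, 0]])
        gt = upgma_tree(d, ["A_RS_hap1", "B_RS_hap1", "C_RS_hap1"])
        ages = sorted(
            n.age for n in gt.tree.preorder_node_iter() if not n.is_leaf()
        )
        assert ages == [pytest.approx(1.0), pytest.approx(3.0)]

    def test_all_zero_matrix_gives_zero_heights(self):
        d = np.zeros((4, 4))
        gt = upgma_tree(d, [f"S{i}_RS_hap1" for i in range(4)])
        assert all(
            n.age == 0 for n in gt.tree.preorder_node_iter() if not n.is_leaf()
        )

    def test_matches_independent_oracle_on_random_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 8))
            m = rng.uniform(0.5, 10, size=(n, n))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0)
            labels = [f"T{i}_RS_hap1" for i in range(n)]
            gt = upgma_tree(d, labels)
            got = {
                frozenset(lf.taxon.label for lf in node.leaf_iter()): node.age
                for node in gt.tree.preorder_node_iter()
                if not node.is_leaf()
            }
            expect = oracles.brute_upgma_heights(d.tolist(), labels)
            assert set(got) == set(expect)
            for k in got:
                assert got[k] == pytest.approx(expect[k])

    def test_nan_distance_raises(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError):
            upgma_tree(d, ["A_RS_hap1", "B_RS_hap1", "C_RS_hap1"])


class TestOutgroupHaplotype:
    def test_empty_edit_list_identity(self, locus_seq):
        assert reconstruct_outgroup_haplotype(locus_seq, []) == locus_seq

    def test_three_edits_hamming_three(self, locus_seq):
        base = {p: b for p, b in enumerate(locus_seq)}
        edits = []
        for p in (0, 100, 695):
            new = "ACGT"[("ACGT".index(base[p]) + 1) % 4]
            edits.append((p, new))
        out = reconstruct_outgroup_haplotype(locus_seq, edits)
        assert sum(a != b for a, b in zip(out, locus_seq)) == 3

    def test_motif_edit_rejected(self, locus_seq):
        with pytest.raises(ValueError):
            reconstruct_outgroup_haplotype(locus_seq, [(geometry.MOTIF_START, "A")])
        with pytest.raises(ValueError):
            reconstruct_outgroup_haplotype(locus_seq, [(900, "A")])

    def test_simulator_outgroup_roundtrip(self, sim_loci):
        _, loci = sim_loci
        for locus in loci[:10]:
            ing = next(v for k, v in locus.alignment.items() if k != "outgroup")
            out = locus.alignment["outgroup"]
            edits = extract_outgroup_edits(ing, out)
            assert reconstruct_outgroup_haplotype(ing, edits) == out


class TestOutgroupMonophyly:
    def _tree(self, merges, labels):
        pops = {l: ("OUT" if l == "outgroup" else "RS") for l in labels}
        return build_tree_from_merges(labels, merges, populations=pops)

    def test_outgroup_inside_is_false(self):
        a, b, c, o = (frozenset([x]) for x in ("a_RS_hap1", "b_RS_hap1", "c_RS_hap1", "outgroup"))
        merges = [(a, b, 1.0), (c, o, 1.5), (a | b, c | o, 2.0)]
        gt = self._tree(merges, [next(iter(x)) for x in (a, b, c, o)])
        assert check_outgroup_monophyly(gt) is False

    def test_outgroup_basal_is_true(self):
        a, b, c, o = (frozenset([x]) for x in ("a_RS_hap1", "b_RS_hap1", "c_RS_hap1", "outgroup"))
        merges = [(a, b, 1.0), (a | b, c, 1.5), (a | b | c, o, 2.0)]
        gt = self._tree(merges, [next(iter(x)) for x in (a, b, c, o)])
        assert check_outgroup_monophyly(gt) is True

    def test_missing_outgroup_raises(self, rng):
        gt = random_tree(rng, [f"x{i}_RS_hap1" for i in range(4)])
        with pytest.raises(ValueError):
            check_outgroup_monophyly(gt)

    def test_agrees_with_bipartition_oracle_on_random_trees(self, rng):
        for _ in range(100):
            labels = [f"x{i}_RS_hap1" for i in range(6)] + ["outgroup"]
            gt = random_tree(rng, labels)
            ingroup = frozenset(l for l in labels if l != "outgroup")
            assert check_outgroup_monophyly(gt) == (ingroup in oracles.leafsets(gt))


class TestCalibrate:
    def _simple_tree(self):
        a, b, c, o = (
            frozenset([x])
            for x in ("a_RS_hap1", "b_BL_hap1", "c_BL_hap2", "outgroup")
        )
        merges = [(b, c, 1.0), (a, b | c, 2.0), (a | b | c, o, 4.0)]
        labels = [next(iter(x)) for x in (a, b, c, o)]
        pops = {"a_RS_hap1": "RS", "b_BL_hap1": "BL", "c_BL_hap2": "BL", "outgroup": "OUT"}
        return build_tree_from_merges(labels, merges, populations=pops)

    def test_proportional_scaling(self):
        gt = self._simple_tree()
        ages = calibrate_tmrca(gt, calib_years=15e6)
        assert ages.tmrca_ingroup_years == pytest.approx(7.5e6)

    def test_root_maps_to_calibration_age(self):
        gt = self._simple_tree()
        ages = calibrate_tmrca(gt)
        assert ages.scale_years_per_unit * gt.root.age == pytest.approx(15e6)

    def test_scale_invariance(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(5)]
        labels = [f"s{i}_RS_hap1" for i in range(4)] + ["outgroup"]
        d = pairwise_diff_matrix(seqs)
        pops = {l: ("OUT" if l == "outgroup" else "RS") for l in labels}
        g1 = upgma_tree(d, labels, populations=pops)
        g2 = upgma_tree(d * 3.7, labels, populations=pops)
        a1, a2 = calibrate_tmrca(g1), calibrate_tmrca(g2)
        assert a1.tmrca_ingroup_years == pytest.approx(a2.tmrca_ingroup_years)

    def test_zero_root_height_uninformative(self):
        labels = ["a_RS_hap1", "b_RS_hap1"]
        merges = [(frozenset([labels[0]]), frozenset([labels[1]]), 0.0)]
        gt = build_tree_from_merges(labels, merges, populations={l: "RS" for l in labels})
        assert calibrate_tmrca(gt) is None


class TestClassifyLineageSorting:
    def _tree(self, merges, pops):
        labels = sorted(pops)
        return build_tree_from_merges(labels, merges, populations=pops)

    def test_reciprocal_monophyly(self):
        bl, bp, r1, r2 = "a_BL_hap1", "b_BP_hap1", "c_RS_hap1", "d_RS_hap2"
        merges = [
            (frozenset([bl]), frozenset([bp]), 1.0),
            (frozenset([r1]), frozenset([r2]), 1.0),
            (frozenset([bl, bp]), frozenset([r1, r2]), 2.0),
        ]
        gt = self._tree(merges, {bl: "BL", bp: "BP", r1: "RS", r2: "RS"})
        assert classify_lineage_sorting(gt) == "reciprocal_mono"

    def test_interleaved_is_none(self):
        bl, bp, r1, r2 = "a_BL_hap1", "b_BP_hap1", "c_RS_hap1", "d_RS_hap2"
        merges = [
            (frozenset([bl]), frozenset([r1]), 1.0),
            (frozenset([bp]), frozenset([r2]), 1.0),
            (frozenset([bl, r1]), frozenset([bp, r2]), 2.0),
        ]
        gt = self._tree(merges, {bl: "BL", bp: "BP", r1: "RS", r2: "RS"})
        assert classify_lineage_sorting(gt) == "none"

    def test_zero_stem_branch_does_not_count(self):
        bl, bp, r1, r2 = "a_BL_hap1", "b_BP_hap1", "c_RS_hap1", "d_RS_hap2"
        merges = [
            (frozenset([bl]), frozenset([bp]), 2.0),  # fw clade stem = 0
            (frozenset([r1]), frozenset([r2]), 1.0),
            (frozenset([bl, bp]), frozenset([r1, r2]), 2.0),
        ]
        gt = self._tree(merges, {bl: "BL", bp: "BP", r1: "RS", r2: "RS"})
        assert classify_lineage_sorting(gt) == "marine_mono"

    def test_missing_population_undefined(self):
        bl, r1 = "a_BL_hap1", "c_RS_hap1"
        merges = [(frozenset([bl]), frozenset([r1]), 1.0)]
        gt = self._tree(merges, {bl: "BL", r1: "RS"})
        assert classify_lineage_sorting(gt) is None

    def test_agrees_with_enumeration_oracle_on_random_trees(self, rng):
        pops_cycle = ["RS", "RS", "BL", "BL", "BP", "BP"]
        n_checked = 0
        for _ in range(150):
            perm = rng.permutation(pops_cycle)
            labels = [f"x{i}_{p}_hap1" for i, p in enumerate(perm)]
            gt = random_tree(rng, labels)
            assert classify_lineage_sorting(gt) == oracles.brute_classify(gt)
            n_checked += 1
        assert n_checked == 150


class TestHaplotypeNetwork:
    def test_single_edge(self):
        net = haplotype_network(["AAAA", "AAAT"])
        assert net.edges == [(0, 1, 1)]

    def test_chain_has_no_shortcut(self):
        net = haplotype_network(["AAAA", "AAAT", "AATT"])
        weights = sorted((min(i, j), max(i, j), w) for i, j, w in net.edges)
        assert weights == [(0, 1, 1), (1, 2, 1)]

    def test_counts_and_populations(self):
        net = haplotype_network(
            ["AAAA", "AAAA", "TTTT"], populations=["RS", "BL", "BL"]
        )
        assert net.nodes[0][1] == 2
        assert net.nodes[0][2] == {"RS": 1, "BL": 1}

    def test_ties_retained_as_reticulation(self):
        # three haplotypes pairwise distance 2: all three edges in some MST
        net = haplotype_network(["AAA", "ATT", "TAT"])
        assert len(net.edges) == 3

    def test_mst_weight_matches_networkx_oracle(self, rng):
        for _ in range(25):
            seqs = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(8)]
            net = haplotype_network(seqs)
            assert net.total_mst_weight() == oracles.mst_weight(seqs)
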