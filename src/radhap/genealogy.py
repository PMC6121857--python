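"""Per-locus gene trees, outgroup calibration and lineage-sorting classes.

Gene trees are estimated from per-site pairwise distances with UPGMA, which
yields a rooted ultrametric (clock-like) tree directly — the rooted topology
and proportional node heights are all the downstream logic consumes, so any
clock tree estimator (including externally produced newick trees) can be
plugged in via :class:`GeneTree`.

Node ages are converted to years by anchoring the root — the join of the
ingroup with the outgroup lineage — at a known divergence time (15 My for
the threespine/ninespine stickleback split) and scaling every other node
age proportionally.  Loci where the ingroup is not monophyletic to the
exclusion of the outgroup are unusable for calibration and are flagged.

Lineage-sorting classes describe how marine (RS) and freshwater (BL, BP)
haplotypes sort on the tree: ``fw_ibd`` when all freshwater haplotypes form
one clade containing both ponds, ``marine_mono`` when the marine haplotypes
do, ``reciprocal_mono`` when both hold (the operational definition of a
divergent locus), ``none`` otherwise.  A group separated from the rest only
by zero-length branches (no fixed difference) does not count as monophyletic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from . import geometry

OUTGROUP_POP = "OUT"
FRESHWATER_POPS = ("BL", "BP")
MARINE_POP = "RS"

#: branch lengths at or below this are treated as zero (collapsed)
ZERO_BRANCH_TOL = 1e-12

CLASS_NONE = "none"
CLASS_FW_IBD = "fw_ibd"
CLASS_MARINE_MONO = "marine_mono"
CLASS_RECIPROCAL = "reciprocal_mono"


@dataclass
class LocusSummary:
    """Per-locus record of diversity, divergence, class and calibrated ages."""

    locus_id: str
    chrom: str
    pos: int
    pi_rs: float = float("nan")
    pi_bl: float = float("nan")
    pi_bp: float = float("nan")
    pi_fw: float = float("nan")
    pi_all: float = float("nan")
    dxy_mf: float = float("nan")
    fst_rs_bl: float = float("nan")
    fst_rs_bp: float = float("nan")
    fst_bl_bp: float = float("nan")
    lineage_class: str | None = None
    tmrca_ingroup_years: float | None = None
    tmrca_mf_split_years: float | None = None
    outgroup_ok: bool = False
    n_segregating_sites: int = 0


def population_of(label: str) -> str:
    """Population tag encoded in a ``sample_pop_hapN`` tip label."""
    if label == "outgroup" or label.startswith("outgroup"):
        return OUTGROUP_POP
    parts = label.split("_")
    if len(parts) < 3:
        raise ValueError(f"cannot parse population from tip label {label!r}")
    return parts[-2]


@dataclass
class GeneTree:
    """A rooted clock tree with tip population tags.

    Every node carries an ``age`` attribute (height above the tips): in
    substitutions/site for estimated trees, in years for simulated or
    calibrated trees.
    """

    tree: dendropy.Tree
    populations: dict[str, str]
    time_units: str = "subs/site"

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def ingroup_labels(self) -> list[str]:
        return [l for l in self.leaf_labels() if self.populations[l] != OUTGROUP_POP]

    def labels_of_pop(self, pops: Iterable[str]) -> set[str]:
        pops = set(pops)
        return {l for l in self.leaf_labels() if self.populations[l] in pops}

    def mrca_age(self, labels: Iterable[str]) -> float:
        node = self.tree.mrca(taxon_labels=list(labels))
        return float(node.age)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def build_tree_from_merges(
    labels: Sequence[str],
    merges: Sequence[tuple[frozenset, frozenset, float]],
    populations: Mapping[str, str] | None = None,
    time_units: str = "subs/site",
) -> GeneTree:
    """Assemble a dendropy tree from (cluster_a, cluster_b, height) merge events."""
    ns = dendropy.TaxonNamespace()
    nodes: dict[frozenset, dendropy.Node] = {}
    for label in labels:
        taxon = ns.new_taxon(label)
        node = dendropy.Node(taxon=taxon)
        node.age = 0.0
        nodes[frozenset([label])] = node
    for a, b, height in merges:
        parent = dendropy.Node()
        parent.age = float(height)
        for key in (a, b):
            child = nodes.pop(key)
            parent.add_child(child)
        nodes[a | b] = parent
    (root,) = nodes.values()
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = True
    _set_edge_lengths_from_ages(tree)
    pops = dict(populations) if populations is not None else {
        l: population_of(l) for l in labels
    }
    return GeneTree(tree=tree, populations=pops, time_units=time_units)


def _set_edge_lengths_from_ages(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
        else:
            node.edge.length = node.parent_node.age - node.age


def pairwise_diff_matrix(sequences: Sequence[str]) -> np.ndarray:
    """Per-site pairwise distance matrix: differing sites / alignment length."""
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("sequences must be of equal length")
    arr = np.frombuffer("".join(sequences).encode(), dtype=np.uint8).reshape(
        len(sequences), L
    )
    diffs = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
    return diffs / float(L)


def upgma_tree(
    dist: np.ndarray,
    labels: Sequence[str],
    populations: Mapping[str, str] | None = None,
) -> GeneTree:
    """UPGMA clustering with arithmetic-mean cluster distances.

    Node height is half the merging distance.  Ties on the minimal distance
    are broken deterministically by merging the pair whose clusters carry
    the lexicographically smallest representative labels (the smallest tip
    label in each cluster).
    """
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if np.isnan(dist).any():
        raise ValueError("distance matrix contains NaN")

    # active clusters: index -> (member label frozenset, size, representative)
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    reps: dict[int, str] = {i: labels[i] for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[frozenset, frozenset, float]] = []
    next_id = n
    while len(members) > 1:
        dmin = min(d.values())
        best = None
        for (i, j), val in d.items():
            if val == dmin:  # exact float equality on purpose
                key = tuple(sorted((reps[i], reps[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        height = dmin / 2.0
        merges.append((members[i], members[j], height))
        new = next_id
        next_id += 1
        members[new] = members[i] | members[j]
        reps[new] = min(reps[i], reps[j])
        sizes[new] = sizes[i] + sizes[j]
        for k in list(members):
            if k in (i, j, new):
                continue
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            d[(min(new, k), max(new, k))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        d.pop((i, j))
        del members[i], members[j], reps[i], reps[j], sizes[i], sizes[j]
    return build_tree_from_merges(labels, merges, populations=populations)


def reconstruct_outgroup_haplotype(
    threespine_hap: str, edits: Sequence[tuple[int, str]]
) -> str:
    """Insert outgroup substitutions into an ingroup haplotype.

    ``edits`` are (0-based locus position, outgroup base) pairs; the 6-bp
    restriction motif block must not be edited.
    """
    if len(threespine_hap) != geometry.LOCUS_LEN:
        raise ValueError(f"haplotype must be {geometry.LOCUS_LEN} bp")
    seq = list(threespine_hap)
    motif_range = range(geometry.MOTIF_START, geometry.MOTIF_START + geometry.MOTIF_LEN)
    for pos, base in edits:
        if not 0 <= pos < geometry.LOCUS_LEN:
            raise ValueError(f"edit position {pos} out of range")
        if pos in motif_range:
            raise ValueError(f"edit position {pos} falls inside the invariant motif")
        seq[pos] = base
    return "".join(seq)


def extract_outgroup_edits(threespine_hap: str, outgroup_hap: str) -> list[tuple[int, str]]:
    """Substitution list turning an ingroup haplotype into the outgroup one."""
    if len(threespine_hap) != len(outgroup_hap):
        raise ValueError("haplotypes must be of equal length")
    return [
        (i, b) for i, (a, b) in enumerate(zip(threespine_hap, outgroup_hap)) if a != b
    ]


def _clades_with_positive_stem(gtree: GeneTree) -> list[frozenset]:
    """Leaf-label sets of non-root nodes whose stem branch is positive."""
    out = []
    for node in gtree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if (node.edge.length or 0.0) <= ZERO_BRANCH_TOL:
            continue
        out.append(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    return out


def _all_clades(gtree: GeneTree) -> list[frozenset]:
    return [
        frozenset(lf.taxon.label for lf in node.leaf_iter())
        for node in gtree.tree.preorder_internal_node_iter()
    ]


def check_outgroup_monophyly(gtree: GeneTree, outgroup_label: str = "outgroup") -> bool:
    """True iff the ingroup tips form a clade excluding the single outgroup tip."""
    labels = gtree.leaf_labels()
    if outgroup_label not in labels:
        raise ValueError(f"tree has no outgroup tip {outgroup_label!r}")
    ingroup = frozenset(l for l in labels if l != outgroup_label)
    return ingroup in _all_clades(gtree)


@dataclass
class CalibratedAges:
    """Node ages in years after proportional root calibration."""

    tmrca_ingroup_years: float
    tmrca_marine_years: float | None = None
    tmrca_freshwater_years: float | None = None
    tmrca_mf_split_years: float | None = None
    scale_years_per_unit: float = float("nan")


def calibrate_tmrca(gtree: GeneTree, calib_years: float = 15e6) -> CalibratedAges | None:
    """Convert node heights to years by fixing the root age at ``calib_years``.

    Requires the outgroup to subtend the root (checked by the caller via
    :func:`check_outgroup_monophyly`).  Returns ``None`` for uninformative
    loci with zero root height.  Marine/freshwater clade ages are reported
    when the respective group is monophyletic; the habitat split age is the
    age of the node separating the two habitat clades (the ingroup MRCA)
    when the locus is reciprocally monophyletic.
    """
    root_h = float(gtree.root.age)
    if root_h <= 0.0:
        return None
    scale = calib_years / root_h
    ingroup = gtree.ingroup_labels()
    ages = CalibratedAges(
        tmrca_ingroup_years=scale * gtree.mrca_age(ingroup),
        scale_years_per_unit=scale,
    )
    cls = classify_lineage_sorting(gtree)
    marine = gtree.labels_of_pop([MARINE_POP])
    fresh = gtree.labels_of_pop(FRESHWATER_POPS)
    if cls in (CLASS_MARINE_MONO, CLASS_RECIPROCAL) and len(marine) >= 2:
        ages.tmrca_marine_years = scale * gtree.mrca_age(marine)
    if cls in (CLASS_FW_IBD, CLASS_RECIPROCAL) and len(fresh) >= 2:
        ages.tmrca_freshwater_years = scale * gtree.mrca_age(fresh)
    if cls == CLASS_RECIPROCAL:
        ages.tmrca_mf_split_years = scale * gtree.mrca_age(marine | fresh)
    return ages


def classify_lineage_sorting(
    gtree: GeneTree, require_both_fw: bool = True
) -> str | None:
    """Lineage-sorting class of marine vs freshwater haplotypes on a tree.

    The outgroup (if present) is ignored after rooting.  Monophyly requires a
    strictly positive stem branch, so groups separated only by zero-length
    branches (no fixed difference) are not counted.  Returns ``None`` when a
    population is absent at the locus (class undefined).
    """
    marine = gtree.labels_of_pop([MARINE_POP])
    fresh = gtree.labels_of_pop(FRESHWATER_POPS)
    bl = gtree.labels_of_pop(["BL"])
    bp = gtree.labels_of_pop(["BP"])
    if not marine or not bl or not bp:
        return None
    clades = _clades_with_positive_stem(gtree)
    fw_ok = fresh in clades
    if require_both_fw:
        fw_ok = fw_ok and bool(bl) and bool(bp)
    marine_ok = marine in clades
    if fw_ok and marine_ok:
        return CLASS_RECIPROCAL
    if fw_ok:
        return CLASS_FW_IBD
    if marine_ok:
        return CLASS_MARINE_MONO
    return CLASS_NONE


@dataclass
class HaplotypeNetwork:
    """Minimum-spanning network over distinct haplotypes.

    ``nodes[i]`` is (haplotype sequence, count, per-population counts);
    ``edges`` are (i, j, mutational steps) with every edge that occurs in
    some minimum spanning tree retained (ties kept).
    """

    nodes: list[tuple[str, int, dict[str, int]]]
    edges: list[tuple[int, int, int]] = field(default_factory=list)

    def total_mst_weight(self) -> int:
        """Weight of one minimum spanning tree over the distinct haplotypes."""
        # Kruskal on the retained edges reproduces an MST because the network
        # is the union of all MSTs.
        parent = list(range(len(self.nodes)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        total = 0
        for i, j, w in sorted(self.edges, key=lambda e: e[2]):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
                total += w
        return total


def haplotype_network(
    sequences: Sequence[str], populations: Sequence[str] | None = None
) -> HaplotypeNetwork:
    """Collapse identical haplotypes and link them in a minimum-spanning network.

    Edge weights are mutational steps (Hamming distances, valid under the
    infinite-sites model); all edges belonging to any minimum spanning tree
    are retained, so ties appear as reticulations.
    """
    if populations is None:
        populations = ["?"] * len(sequences)
    order: dict[str, int] = {}
    counts: list[int] = []
    pop_counts: list[dict[str, int]] = []
    for seq, pop in zip(sequences, populations):
        if seq not in order:
            order[seq] = len(counts)
            counts.append(0)
            pop_counts.append({})
        i = order[seq]
        counts[i] += 1
        pop_counts[i][pop] = pop_counts[i].get(pop, 0) + 1
    haps = list(order)
    nodes = [(h, counts[i], pop_counts[i]) for i, h in enumerate(haps)]
    m = len(haps)
    if m == 1:
        return HaplotypeNetwork(nodes=nodes)

    ham = (pairwise_diff_matrix(haps) * len(haps[0])).round().astype(int)
    all_edges = sorted(
        ((int(ham[i, j]), i, j) for i in range(m) for j in range(i + 1, m)),
        key=lambda e: e[0],
    )
    # union of all MSTs: an edge of weight w is in some MST iff its endpoints
    # are in different components of the graph restricted to edges < w
    parent = list(range(m))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[tuple[int, int, int]] = []
    for w, group in itertools.groupby(all_edges, key=lambda e: e[0]):
        batch = list(group)
        keep = [(i, j) for _, i, j in batch if find(i) != find(j)]
        edges.extend((i, j, w) for i, j in keep)
        for i, j in keep:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    return HaplotypeNetwork(nodes=nodes, edges=edges)
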