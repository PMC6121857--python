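"""Independent brute-force reference implementations used as test oracles.

Deliberately written with different algorithms/data layouts than the
package (plain Python loops, recursion, networkx) so agreement is
meaningful.
"""

from __future__ import annotations

import itertools

import networkx as nx


def brute_pi(seqs: list[str]) -> float:
    L = len(seqs[0])
    pairs = list(itertools.combinations(range(len(seqs)), 2))
    total = 0
    for i, j in pairs:
        total += sum(a != b for a, b in zip(seqs[i], seqs[j]))
    return total / (len(pairs) * L)


def brute_dxy(xs: list[str], ys: list[str]) -> float:
    L = len(xs[0])
    total = 0
    for x in xs:
        for y in ys:
            total += sum(a != b for a, b in zip(x, y))
    return total / (len(xs) * len(ys) * L)


def brute_hudson_fst(xs: list[str], ys: list[str]) -> float:
    def mean_pairwise(group_a, group_b, within):
        if within:
            pairs = list(itertools.combinations(group_a, 2))
            return sum(
                sum(a != b for a, b in zip(p, q)) for p, q in pairs
            ) / len(pairs)
        return sum(
            sum(a != b for a, b in zip(p, q)) for p in group_a for q in group_b
        ) / (len(group_a) * len(group_b))

    hw = (mean_pairwise(xs, None, True) + mean_pairwise(ys, None, True)) / 2
    hb = mean_pairwise(xs, ys, False)
    if hb == 0:
        return float("nan")
    return 1 - hw / hb


def brute_upgma_heights(dist, labels) -> dict[frozenset, float]:
    """UPGMA by recomputing cluster distances from the original matrix.

    Returns {cluster leafset: merge height}; average-linkage distances are
    recomputed from scratch per step (no running update), with the same
    lexicographic-representative tie rule as the package.
    """
    index = {l: i for i, l in enumerate(labels)}
    clusters = [frozenset([l]) for l in labels]
    out: dict[frozenset, float] = {}

    def cdist(a: frozenset, b: frozenset) -> float:
        return sum(dist[index[x]][index[y]] for x in a for y in b) / (
            len(a) * len(b)
        )

    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = cdist(a, b)
            key = (d, tuple(sorted((min(a), min(b)))))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _), a, b = best
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
        out[a | b] = d / 2
    return out


def leafsets(gtree) -> set[frozenset]:
    """All internal-node leaf-label sets, via explicit recursion."""

    result: set[frozenset] = set()

    def walk(node) -> frozenset:
        if node.is_leaf():
            return frozenset([node.taxon.label])
        ls = frozenset().union(*(walk(c) for c in node.child_nodes()))
        result.add(ls)
        return ls

    walk(gtree.tree.seed_node)
    return result


def brute_classify(gtree) -> str | None:
    """Clade-enumeration oracle for the lineage-sorting classes."""
    labels = [l for l in gtree.leaf_labels() if gtree.populations[l] != "OUT"]
    bl = {l for l in labels if gtree.populations[l] == "BL"}
    bp = {l for l in labels if gtree.populations[l] == "BP"}
    rs = {l for l in labels if gtree.populations[l] == "RS"}
    if not rs or not bl or not bp:
        return None
    positive = set()
    for node in gtree.tree.preorder_node_iter():
        if node.parent_node is None or (node.edge.length or 0.0) <= 1e-12:
            continue
        positive.add(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    fw = frozenset(bl | bp)
    fw_ok = fw in positive
    m_ok = frozenset(rs) in positive
    if fw_ok and m_ok:
        return "reciprocal_mono"
    if fw_ok:
        return "fw_ibd"
    if m_ok:
        return "marine_mono"
    return "none"


def mst_weight(seqs: list[str]) -> int:
    """Minimum spanning tree weight over distinct haplotypes via networkx."""
    haps = sorted(set(seqs))
    if len(haps) < 2:
        return 0
    g = nx.Graph()
    for i, j in itertools.combinations(range(len(haps)), 2):
        w = sum(a != b for a, b in zip(haps[i], haps[j]))
        g.add_edge(i, j, weight=w)
    t = nx.minimum_spanning_tree(g)
    return int(sum(d["weight"] for _, _, d in t.edges(data=True)))


def exact_permutation_p(a: list[float], b: list[float]) -> float:
    """Exact two-sided permutation p-value by full enumeration of splits."""
    pooled = list(a) + list(b)
    na = len(a)
    obs = abs(sum(a) / na - sum(b) / len(b))
    hits = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), na):
        total += 1
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        diff = abs(sum(ga) / na - sum(gb) / len(gb))
        if diff >= obs - 1e-12:
            hits += 1
    return hits / total
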