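"""Structured-coalescent simulator for RAD-locus datasets with ground truth.

Emulates the study design the analysis assumes: three stickleback
populations (one marine, RS; two freshwater ponds, BL and BP) genotyped at
696-bp PstI RAD loci, a fraction of which carry ancient habitat-associated
haplogroups, plus a single outgroup lineage (the ninespine stickleback)
splitting exactly 15 Mya that calibrates node ages.

At a non-divergent locus all ingroup haplotypes follow a panmictic Kingman
coalescent.  At a divergent locus haplotypes first coalesce within their
habitat haplogroup (marine = RS copies, freshwater = BL+BP copies), and the
two haplogroup ancestors merge no earlier than the haplogroup divergence
time ``t_split_years``.  Mutations follow the infinite-sites model over the
690 mutable positions; the 6-bp PstI motif never mutates.  Time is in years
throughout, with the per-pair coalescence timescale 2 * ne_diploid *
generation_time_years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import geometry
from .genealogy import GeneTree, OUTGROUP_POP, build_tree_from_merges

BASES = "ACGT"
HAPLOGROUP_MARINE = "marine"
HAPLOGROUP_FRESHWATER = "freshwater"
HAPLOGROUP_PANMICTIC = "panmictic"


class InfiniteSitesExhausted(RuntimeError):
    """More mutations than mutable sites at a locus under infinite sites."""


@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults describe the study conditions: 5/5/4 diploids in RS/BL/BP,
    theta = 4*Ne*mu_gen = 2.8e-3 per site (median ~7 segregating sites per
    696-bp locus), ~2% of loci carrying habitat haplogroups that diverged
    6 Mya, and the outgroup split fixed at 15 Mya.
    """

    n_loci: int = 200
    samples_per_pop: dict[str, int] = field(
        default_factory=lambda: {"RS": 5, "BL": 5, "BP": 4}
    )
    chrom: str = "chrSim"
    chrom_length_bp: int = 25_000_000
    frac_divergent: float = 0.02
    t_split_years: float = 6e6
    t_outgroup_years: float = 15e6
    ne_diploid: float = 140_000.0
    mu_per_site_per_year: float = 2.5e-9
    generation_time_years: float = 2.0
    marine_contamination: float = 0.0
    divergence_regions: list[tuple[int, int]] | None = None
    seed: int = 0
    locus_len: int = geometry.LOCUS_LEN
    mutable_sites: int = geometry.N_MUTABLE
    motif: str = geometry.MOTIF

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_divergent <= 1.0:
            raise ValueError("frac_divergent must be in [0, 1]")
        if not self.t_split_years < self.t_outgroup_years:
            raise ValueError("t_split_years must be < t_outgroup_years")
        if self.ne_diploid <= 0 or self.mu_per_site_per_year <= 0:
            raise ValueError("ne_diploid and mu_per_site_per_year must be positive")
        if self.generation_time_years <= 0:
            raise ValueError("generation_time_years must be positive")
        if self.locus_len != 2 * geometry.TAG_LEN - geometry.OVERHANG_LEN:
            raise ValueError("locus_len must equal 2*350 - 4")
        if self.mutable_sites != self.locus_len - len(self.motif):
            raise ValueError("mutable_sites must equal locus_len - motif length")

    @property
    def pair_coalescence_years(self) -> float:
        """Mean coalescence time of two lineages: 2 * Ne * generation time."""
        return 2.0 * self.ne_diploid * self.generation_time_years

    def haplotype_labels(self) -> dict[str, str]:
        """All ingroup tip labels -> population, in deterministic order."""
        labels: dict[str, str] = {}
        for pop in ("RS", "BL", "BP"):
            for i in range(1, self.samples_per_pop.get(pop, 0) + 1):
                for h in (1, 2):
                    labels[f"{pop}{i}_{pop}_hap{h}"] = pop
        return labels


@dataclass
class LocusTruth:
    """Ground truth for one simulated locus."""

    locus_id: str
    chrom: str
    pos: int
    divergent: bool
    tmrca_ingroup_years: float
    tmrca_mf_join_years: float | None
    haplogroup: dict[str, str]
    true_phases: dict[str, tuple[str, str]]


@dataclass
class SimulatedLocus:
    locus_id: str
    chrom: str
    pos: int
    tree: GeneTree  # node ages in years; includes the outgroup tip
    alignment: dict[str, str]  # tip label -> 696-bp sequence (incl. "outgroup")
    truth: LocusTruth


def _locus_rng(config: SimConfig, locus_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(locus_index,))
    )


def _kingman_merges(
    lineages: dict[frozenset, float],
    rate_scale: float,
    t_start: float,
    rng: np.random.Generator,
    merges: list,
) -> tuple[frozenset, float]:
    """Coalesce lineages (cluster -> availability time) to a single ancestor.

    ``rate_scale`` is the mean pairwise coalescence time in years.  Returns
    the final cluster and its coalescence time.
    """
    active = sorted(lineages, key=lambda c: sorted(c))
    t = max([t_start] + [lineages[c] for c in active])
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(rate_scale / (k * (k - 1) / 2.0))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[min(i, j)], active[max(i, j)]
        merges.append((a, b, t))
        active = [c for c in active if c is not a and c is not b] + [a | b]
    return active[0], t


def assign_haplogroups(config: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    """Habitat haplogroup per haplotype at a divergent locus.

    Freshwater individuals (BL, BP) draw from the freshwater haplogroup,
    optionally carrying a marine allele with probability
    ``marine_contamination``; marine individuals (RS) draw marine alleles.
    """
    groups: dict[str, str] = {}
    for label, pop in config.haplotype_labels().items():
        if pop == "RS":
            groups[label] = HAPLOGROUP_MARINE
        elif rng.random() < config.marine_contamination:
            groups[label] = HAPLOGROUP_MARINE
        else:
            groups[label] = HAPLOGROUP_FRESHWATER
    return groups


def simulate_genealogy(
    config: SimConfig,
    locus_index: int,
    divergent: bool | None = None,
    rng: np.random.Generator | None = None,
    max_tries: int = 1000,
) -> tuple[GeneTree, dict[str, str]]:
    """Simulate the rooted genealogy of one locus, outgroup included.

    Returns the tree (node ages in years; the outgroup joins at exactly
    ``t_outgroup_years``) and the haplogroup label per ingroup haplotype.
    Genealogies whose ingroup TMRCA would exceed the outgroup split are
    redrawn (they violate the calibration anchor); this is vanishingly rare
    under realistic parameters.
    """
    if rng is None:
        rng = _locus_rng(config, locus_index)
    if divergent is None:
        divergent = bool(rng.random() < config.frac_divergent)
    pops = config.haplotype_labels()
    if len(pops) < 2:
        raise ValueError("need at least one diploid individual")
    scale = config.pair_coalescence_years

    for _ in range(max_tries):
        merges: list = []
        if divergent:
            groups = assign_haplogroups(config, rng)
            marine = {frozenset([l]): 0.0 for l, g in groups.items() if g == HAPLOGROUP_MARINE}
            fresh = {frozenset([l]): 0.0 for l, g in groups.items() if g == HAPLOGROUP_FRESHWATER}
            roots: dict[frozenset, float] = {}
            for grp in (marine, fresh):
                if grp:
                    c, t = _kingman_merges(grp, scale, 0.0, rng, merges)
                    roots[c] = t
            if len(roots) == 2:
                (ca, ta), (cb, tb) = roots.items()
                t_join = max(config.t_split_years, ta, tb) + rng.exponential(scale)
                merges.append((ca, cb, t_join))
                ingroup_root, t_ingroup = ca | cb, t_join
            else:
                ((ingroup_root, t_ingroup),) = roots.items()
        else:
            groups = {l: HAPLOGROUP_PANMICTIC for l in pops}
            lineages = {frozenset([l]): 0.0 for l in pops}
            ingroup_root, t_ingroup = _kingman_merges(lineages, scale, 0.0, rng, merges)
        if t_ingroup < config.t_outgroup_years:
            break
    else:
        raise RuntimeError(
            "could not draw an ingroup genealogy younger than the outgroup split; "
            "check ne_diploid / t_split_years against t_outgroup_years"
        )

    merges.append((ingroup_root, frozenset(["outgroup"]), config.t_outgroup_years))
    labels = list(pops) + ["outgroup"]
    populations = dict(pops, outgroup=OUTGROUP_POP)
    gtree = build_tree_from_merges(labels, merges, populations=populations, time_units="years")
    return gtree, groups


def drop_mutations(
    gtree: GeneTree, config: SimConfig, rng: np.random.Generator
) -> dict[str, str]:
    """Place infinite-sites mutations on a tree with branch lengths in years.

    Per branch the mutation count is Poisson(mu * branch_years * 690 mutable
    sites); each mutation takes a distinct site, sampled without replacement
    among the mutable positions, and a uniformly random base different from
    the ancestral one.  The shared ancestral sequence is random with equal
    base frequencies, with the PstI motif fixed at its recognition sequence.
    """
    if gtree.time_units != "years":
        raise ValueError("tree branch lengths must be in years")
    ancestral = rng.choice(list(BASES), size=config.locus_len)
    ancestral[geometry.MOTIF_START : geometry.MOTIF_START + geometry.MOTIF_LEN] = list(
        config.motif
    )
    branches = [
        node
        for node in gtree.tree.preorder_node_iter()
        if node.parent_node is not None
    ]
    counts = rng.poisson(
        [
            config.mu_per_site_per_year * node.edge.length * config.mutable_sites
            for node in branches
        ]
    )
    total = int(counts.sum())
    if total > config.mutable_sites:
        raise InfiniteSitesExhausted(
            f"{total} mutations for {config.mutable_sites} mutable sites at one "
            "locus; lower mu_per_site_per_year or resample this locus"
        )
    sites = rng.choice(geometry.MUTABLE_POSITIONS, size=total, replace=False)
    seqs = {
        lf.taxon.label: ancestral.copy() for lf in gtree.tree.leaf_node_iter()
    }
    k = 0
    for node, cnt in zip(branches, counts):
        if cnt == 0:
            continue
        below = [lf.taxon.label for lf in node.leaf_iter()]
        for site in sites[k : k + cnt]:
            old = ancestral[site]
            new = BASES[(BASES.index(old) + rng.integers(1, 4)) % 4]
            for label in below:
                seqs[label][site] = new
        k += cnt
    return {label: "".join(arr) for label, arr in seqs.items()}


def emit_rad_observables(
    alignment: dict[str, str],
    config: SimConfig,
    with_reads: bool = False,
    read_len: int = 250,
) -> tuple[dict[str, dict[str, list[str]]], dict[str, dict[str, list[tuple[str, str]]]] | None]:
    """Cut phased locus haplotypes into unphased per-sample tag observations.

    Each 696-bp haplotype splits into a left and a right 350-bp tag that
    overlap across the re-duplicated 4-bp PstI overhang.  Per diploid the
    two tags per side are returned as a sorted multiset (phase erased).
    Optionally emits pre-oriented synthetic read pairs per tag whose exact
    merge reconstructs the tag.
    """
    tags: dict[str, dict[str, list[str]]] = {}
    reads: dict[str, dict[str, list[tuple[str, str]]]] | None = {} if with_reads else None
    for label, seq in alignment.items():
        if label == "outgroup":
            continue
        sample = label.rsplit("_", 2)[0]
        left, right = geometry.split_locus(seq)
        entry = tags.setdefault(sample, {"left": [], "right": []})
        entry["left"].append(left)
        entry["right"].append(right)
        if with_reads:
            rentry = reads.setdefault(sample, {"left": [], "right": []})
            for side, tag in (("left", left), ("right", right)):
                rentry[side].append((tag[:read_len], tag[-read_len:]))
    for entry in tags.values():
        entry["left"].sort()
        entry["right"].sort()
    return tags, reads


def true_phases(alignment: dict[str, str]) -> dict[str, tuple[str, str]]:
    """Unordered true haplotype pair per diploid sample."""
    phases: dict[str, list[str]] = {}
    for label, seq in alignment.items():
        if label == "outgroup":
            continue
        phases.setdefault(label.rsplit("_", 2)[0], []).append(seq)
    return {s: tuple(sorted(v)) for s, v in phases.items()}


def _draw_positions(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo = geometry.MOTIF_START
    hi = config.chrom_length_bp - (geometry.LOCUS_LEN - geometry.MOTIF_START)
    if hi <= lo:
        raise ValueError("chrom_length_bp too small for any locus")
    positions: set[int] = set()
    while len(positions) < config.n_loci:
        positions.update(
            int(p) for p in rng.integers(lo, hi, size=config.n_loci - len(positions))
        )
    return np.array(sorted(positions))


def _in_regions(pos: int, regions: Sequence[tuple[int, int]]) -> bool:
    return any(start <= pos < end for start, end in regions)


def simulate_locus(
    config: SimConfig, locus_index: int, pos: int, divergent: bool | None = None
) -> SimulatedLocus:
    """Simulate one locus end to end: genealogy, mutations, truth record."""
    rng = _locus_rng(config, locus_index)
    if divergent is None:
        if config.divergence_regions is not None:
            divergent = _in_regions(pos, config.divergence_regions)
        else:
            divergent = bool(rng.random() < config.frac_divergent)
    gtree, groups = simulate_genealogy(config, locus_index, divergent=divergent, rng=rng)
    alignment = drop_mutations(gtree, config, rng)
    ingroup = gtree.ingroup_labels()
    t_ingroup = gtree.mrca_age(ingroup)
    t_join = None
    if divergent:
        marine = [l for l in ingroup if groups[l] == HAPLOGROUP_MARINE]
        fresh = [l for l in ingroup if groups[l] == HAPLOGROUP_FRESHWATER]
        if marine and fresh:
            t_join = gtree.mrca_age(marine + fresh)
    locus_id = f"L{locus_index:05d}"
    truth = LocusTruth(
        locus_id=locus_id,
        chrom=config.chrom,
        pos=pos,
        divergent=divergent,
        tmrca_ingroup_years=t_ingroup,
        tmrca_mf_join_years=t_join,
        haplogroup=groups,
        true_phases=true_phases(alignment),
    )
    return SimulatedLocus(
        locus_id=locus_id,
        chrom=config.chrom,
        pos=pos,
        tree=gtree,
        alignment=alignment,
        truth=truth,
    )


def simulate_dataset(config: SimConfig) -> list[SimulatedLocus]:
    """Simulate ``config.n_loci`` loci placed on one synthetic chromosome.

    Loci are placed uniformly (or classified as divergent inside the
    configured divergence regions, emulating regional clustering of ancient
    haplogroups).  Byte-identical output is guaranteed for identical
    (config, seed).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(2**31,))
    )
    positions = _draw_positions(config, rng)
    return [
        simulate_locus(config, i, int(pos)) for i, pos in enumerate(positions)
    ]
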