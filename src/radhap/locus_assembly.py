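"""Assembly of 696-bp RAD loci from overlapping reads and 350-bp tags.

The processing chain mirrors a paired-end RAD protocol in which both
reads of a pair cover one side of a PstI restriction site: read pairs are
merged on their exact overlap, merged contigs are trimmed to a uniform
350 bp anchored at the restriction site (shorter contigs discarded), and
the left/right tags at one site are joined into a single 696-bp locus by
collapsing the shared 4-bp overhang.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import geometry

LEFT = "left"
RIGHT = "right"


class OverhangMismatchError(ValueError):
    """Left and right tags disagree in the 4-bp PstI overhang they share."""


@dataclass(frozen=True)
class RadTag:
    """One 350-bp tag: sequence from a single end of a restriction site."""

    site_id: str
    side: str  # LEFT or RIGHT
    sample_id: str
    sequence: str
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.side not in (LEFT, RIGHT):
            raise ValueError(f"side must be {LEFT!r} or {RIGHT!r}")
        if len(self.sequence) != geometry.TAG_LEN:
            raise ValueError(
                f"tag must be {geometry.TAG_LEN} bp after trimming, got {len(self.sequence)}"
            )


@dataclass
class RadLocusUnphased:
    """Called tag genotypes at one restriction site, before phasing.

    ``genotypes[side][sample]`` is an unordered pair of allele indices into
    ``alleles[side]``.  Samples with a called genotype at only one tag are
    recorded in ``excluded`` and take no further part in the locus.
    """

    locus_id: str
    chrom: str
    pos: int
    alleles: dict[str, list[str]] = field(default_factory=lambda: {LEFT: [], RIGHT: []})
    genotypes: dict[str, dict[str, tuple[int, int]]] = field(
        default_factory=lambda: {LEFT: {}, RIGHT: {}}
    )
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        """Samples genotyped at both tags."""
        return sorted(set(self.genotypes[LEFT]) & set(self.genotypes[RIGHT]))


def merge_read_pair(read1: str, read2: str, min_overlap: int = 20) -> str | None:
    """Merge two reads on their unique exact suffix(read1)/prefix(read2) overlap.

    Returns the merged contig, or ``None`` when no overlap of at least
    ``min_overlap`` bases exists or when several distinct overlap lengths
    are possible (ambiguous pairs are removed from analysis, as are pairs
    that fail to merge).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    hits = [
        k
        for k in range(min_overlap, min(len(read1), len(read2)) + 1)
        if read1[-k:] == read2[:k]
    ]
    if len(hits) != 1:
        return None
    k = hits[0]
    return read1 + read2[k:]


def trim_contig(contig: str, side: str, target_len: int = geometry.TAG_LEN) -> str | None:
    """Trim a merged contig to ``target_len`` bases anchored at the restriction site.

    Contigs are in forward locus orientation, so the restriction-site anchor
    is the 3' end of left-side contigs and the 5' end of right-side contigs.
    Contigs shorter than ``target_len`` are discarded (``None``).
    """
    if side not in (LEFT, RIGHT):
        raise ValueError(f"side must be {LEFT!r} or {RIGHT!r}")
    if len(contig) < target_len:
        return None
    return contig[-target_len:] if side == LEFT else contig[:target_len]


def assemble_locus(left_hap: str, right_hap: str, locus_id: str = "?") -> str:
    """Join a left and a right 350-bp tag haplotype into one 696-bp locus.

    The tags overlap across the 4-bp PstI overhang; the overlap is collapsed
    once, giving 350 + 350 - 4 = 696 bases with the 6-bp motif intact.
    """
    if len(left_hap) != geometry.TAG_LEN or len(right_hap) != geometry.TAG_LEN:
        raise ValueError("both tags must be exactly 350 bp")
    if left_hap[-geometry.OVERHANG_LEN :] != right_hap[: geometry.OVERHANG_LEN]:
        raise OverhangMismatchError(
            f"locus {locus_id}: left tag overhang {left_hap[-4:]!r} != "
            f"right tag overhang {right_hap[:4]!r}"
        )
    return left_hap + right_hap[geometry.OVERHANG_LEN :]


def tags_to_locus(
    locus_id: str,
    chrom: str,
    pos: int,
    tags_by_sample: Mapping[str, Mapping[str, Sequence[str]]],
) -> RadLocusUnphased:
    """Call per-sample tag alleles at one site from observed tag multisets.

    ``tags_by_sample[sample][side]`` is the (unphased) multiset of tag
    sequences observed for that diploid.  Distinct sequences per side become
    alleles; a sample showing more than two distinct sequences at one side,
    or sequences at only one side, is excluded with a logged reason.
    """
    locus = RadLocusUnphased(locus_id=locus_id, chrom=chrom, pos=pos)
    allele_index: dict[str, dict[str, int]] = {LEFT: {}, RIGHT: {}}
    for sample in sorted(tags_by_sample):
        sides = tags_by_sample[sample]
        if not sides.get(LEFT) or not sides.get(RIGHT):
            locus.excluded[sample] = "genotype called at only one tag"
            continue
        geno: dict[str, tuple[int, int]] = {}
        for side in (LEFT, RIGHT):
            distinct = sorted(set(sides[side]))
            if len(distinct) > 2:
                locus.excluded[sample] = f">2 distinct {side}-tag sequences"
                break
            idx = []
            for seq in distinct:
                if seq not in allele_index[side]:
                    allele_index[side][seq] = len(locus.alleles[side])
                    locus.alleles[side].append(seq)
                idx.append(allele_index[side][seq])
            geno[side] = (idx[0], idx[0]) if len(idx) == 1 else (idx[0], idx[1])
        else:
            locus.genotypes[LEFT][sample] = geno[LEFT]
            locus.genotypes[RIGHT][sample] = geno[RIGHT]
    return locus


def filter_loci(
    loci: Iterable[RadLocusUnphased],
    populations: Mapping[str, str],
    min_individuals_per_pop: int = 4,
) -> tuple[list[RadLocusUnphased], list[dict]]:
    """Drop loci genotyped in fewer than ``min_individuals_per_pop`` per population.

    Per-locus sample exclusions (one-tag genotypes, >2 alleles) have already
    been applied by :func:`tags_to_locus`; this adds the population-level
    completeness filter and returns an exclusion log (one record per dropped
    sample or locus, with reasons).
    """
    pops = sorted(set(populations.values()))
    kept: list[RadLocusUnphased] = []
    log: list[dict] = []
    for locus in loci:
        for sample, reason in locus.excluded.items():
            if sample not in populations:
                raise KeyError(f"sample {sample!r} has no population label")
            log.append(
                {"locus_id": locus.locus_id, "sample": sample, "reason": reason}
            )
        counts = {p: 0 for p in pops}
        for sample in locus.samples:
            try:
                counts[populations[sample]] += 1
            except KeyError:
                raise KeyError(f"sample {sample!r} has no population label") from None
        short = [p for p in pops if counts[p] < min_individuals_per_pop]
        if short:
            log.append(
                {
                    "locus_id": locus.locus_id,
                    "sample": "*",
                    "reason": "fewer than {} genotyped individuals in {}".format(
                        min_individuals_per_pop, ",".join(short)
                    ),
                }
            )
        else:
            kept.append(locus)
    return kept, log
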