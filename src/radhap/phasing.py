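"""Two-marker EM phasing of RAD tag genotypes into full-locus haplotypes.

The two RAD tags at a restriction site are coded as two multiallelic
markers (each distinct tag sequence is one allele).  With no recombination
within a 696-bp locus, phasing reduces to the classical two-locus
haplotype-frequency EM under a multinomial model: only samples
heterozygous at both markers are phase-ambiguous, and their two possible
configurations receive posterior weights proportional to the products of
the current haplotype frequencies.  Each sample is assigned its
maximum-posterior configuration, with ties broken deterministically in
favour of the lexicographically smallest haplotype pair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import locus_assembly
from .locus_assembly import LEFT, RIGHT, RadLocusUnphased

#: haplotype = (left allele index, right allele index)
Hap = tuple[int, int]


@dataclass
class TwoMarkerGenotypes:
    """Per-sample unordered allele pairs at the left and right markers."""

    locus_id: str
    genotypes: dict[str, tuple[tuple[int, int], tuple[int, int]]]
    n_alleles: tuple[int, int]

    @classmethod
    def from_locus(cls, locus: RadLocusUnphased) -> "TwoMarkerGenotypes":
        geno = {
            s: (locus.genotypes[LEFT][s], locus.genotypes[RIGHT][s])
            for s in locus.samples
        }
        return cls(
            locus_id=locus.locus_id,
            genotypes=geno,
            n_alleles=(len(locus.alleles[LEFT]), len(locus.alleles[RIGHT])),
        )


@dataclass
class PhasedSample:
    haplotypes: tuple[Hap, Hap]  # sorted pair
    confidence: float  # posterior of the chosen configuration
    ambiguous: bool  # True iff heterozygous at both markers
    resolved_by: str = "forced"  # forced | em | compatibility


@dataclass
class PhasedLocus:
    locus_id: str
    samples: dict[str, PhasedSample]
    hap_freqs: dict[Hap, float]
    converged: bool = True

    def rendered(
        self, left_alleles: Sequence[str], right_alleles: Sequence[str]
    ) -> dict[str, tuple[str, str]]:
        """Per-sample 696-bp haplotype pair from the tag allele sequences."""
        out = {}
        for sample, ph in self.samples.items():
            seqs = tuple(
                locus_assembly.assemble_locus(
                    left_alleles[l], right_alleles[r], locus_id=self.locus_id
                )
                for l, r in ph.haplotypes
            )
            out[sample] = tuple(sorted(seqs))
        return out


def _configurations(
    gl: tuple[int, int], gr: tuple[int, int]
) -> list[tuple[Hap, Hap]]:
    """Possible phase configurations (unordered haplotype pairs) of a sample."""
    a1, a2 = gl
    b1, b2 = gr
    c1 = tuple(sorted(((a1, b1), (a2, b2))))
    c2 = tuple(sorted(((a1, b2), (a2, b1))))
    return [c1] if c1 == c2 else [c1, c2]


def em_phase(
    genotypes: TwoMarkerGenotypes,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> PhasedLocus:
    """EM estimation of two-marker haplotype frequencies and MAP phases.

    Initialization assigns equal weight to every haplotype compatible with
    some sample; forced-phase samples (homozygous at one or both markers)
    contribute fixed counts.  Non-convergence after ``max_iter`` returns the
    current assignment flagged unconverged (low confidence).
    """
    if not genotypes.genotypes:
        raise ValueError("no samples to phase")
    configs = {
        s: _configurations(gl, gr) for s, (gl, gr) in genotypes.genotypes.items()
    }
    haps = sorted({h for cfgs in configs.values() for cfg in cfgs for h in cfg})
    idx = {h: i for i, h in enumerate(haps)}
    n = len(genotypes.genotypes)
    freqs = np.full(len(haps), 1.0 / len(haps))

    converged = False
    weights: dict[str, np.ndarray] = {}
    for _ in range(max_iter):
        counts = np.zeros(len(haps))
        for s, cfgs in configs.items():
            if len(cfgs) == 1:
                w = np.array([1.0])
            else:
                lik = np.array(
                    [freqs[idx[c[0]]] * freqs[idx[c[1]]] for c in cfgs]
                )
                total = lik.sum()
                w = lik / total if total > 0 else np.full(len(cfgs), 0.5)
            weights[s] = w
            for cfg, wi in zip(cfgs, w):
                counts[idx[cfg[0]]] += wi
                counts[idx[cfg[1]]] += wi
        new = counts / (2.0 * n)
        delta = float(np.abs(new - freqs).max())
        freqs = new
        if delta < tol:
            converged = True
            break

    samples: dict[str, PhasedSample] = {}
    for s, cfgs in configs.items():
        w = weights[s]
        if len(cfgs) == 1:
            samples[s] = PhasedSample(haplotypes=cfgs[0], confidence=1.0, ambiguous=False)
        else:
            # on equal posterior prefer the lexicographically smallest pair
            order = sorted(range(len(cfgs)), key=lambda i: (-w[i], cfgs[i]))
            best = order[0]
            samples[s] = PhasedSample(
                haplotypes=cfgs[best],
                confidence=float(w[best]),
                ambiguous=True,
                resolved_by="em",
            )
    return PhasedLocus(
        locus_id=genotypes.locus_id,
        samples=samples,
        hap_freqs={h: float(freqs[idx[h]]) for h in haps},
        converged=converged,
    )


def concat_invariant(genotypes: TwoMarkerGenotypes) -> PhasedLocus:
    """Trivial phasing when one marker carries a single allele.

    With an invariant side every configuration is forced; equivalent to
    (and cross-checked against) :func:`em_phase` on the same input.
    """
    if 1 not in genotypes.n_alleles:
        raise ValueError("concat_invariant requires an invariant marker side")
    samples = {}
    counts: dict[Hap, float] = {}
    for s, (gl, gr) in genotypes.genotypes.items():
        cfgs = _configurations(gl, gr)
        if len(cfgs) != 1:
            raise ValueError("phase not forced despite invariant side")
        samples[s] = PhasedSample(haplotypes=cfgs[0], confidence=1.0, ambiguous=False)
        for h in cfgs[0]:
            counts[h] = counts.get(h, 0.0) + 1.0
    total = sum(counts.values())
    return PhasedLocus(
        locus_id=genotypes.locus_id,
        samples=samples,
        hap_freqs={h: c / total for h, c in sorted(counts.items())},
    )


def _four_gamete_compatible(sequences: Sequence[str]) -> bool:
    """True iff the haplotype set passes the four-gamete test at every site pair.

    Under infinite sites without recombination every column is biallelic and
    any two columns show at most three of the four allele combinations; a
    violation proves the set cannot descend from a single genealogy.
    """
    arr = np.frombuffer("".join(sequences).encode(), dtype=np.uint8).reshape(
        len(sequences), -1
    )
    seg = (arr != arr[0]).any(axis=0)
    if seg.sum() < 2:
        return True
    B = (arr[:, seg] == arr[0, seg]).astype(float)  # n x S binary
    notB = 1.0 - B
    c11 = (B.T @ B) > 0
    c10 = (B.T @ notB) > 0
    c01 = (notB.T @ B) > 0
    c00 = (notB.T @ notB) > 0
    viol = c11 & c10 & c01 & c00
    np.fill_diagonal(viol, False)
    return not viol.any()


def resolve_by_compatibility(
    result: PhasedLocus,
    genotypes: TwoMarkerGenotypes,
    left_alleles: Sequence[str],
    right_alleles: Sequence[str],
) -> PhasedLocus:
    """Resolve ambiguous phases by infinite-sites tree compatibility.

    The true haplotype set at a non-recombining locus descends from one
    genealogy, so the true configuration of every sample is four-gamete
    compatible with every other true haplotype.  Starting from the forced
    (unambiguous) haplotypes as reference, any ambiguous sample with exactly
    one compatible configuration is therefore resolved correctly; resolved
    haplotypes extend the reference and the pass repeats to a fixed point.
    Samples with both configurations compatible keep their EM assignment.
    Only forced and compatibility-resolved haplotypes ever enter the
    reference, so EM guesses cannot propagate errors into it.
    """

    def render(hap: Hap) -> str:
        return locus_assembly.assemble_locus(
            left_alleles[hap[0]], right_alleles[hap[1]], locus_id=result.locus_id
        )

    reference = [
        render(h)
        for s, ph in result.samples.items()
        if not ph.ambiguous
        for h in ph.haplotypes
    ]
    pending = sorted(s for s, ph in result.samples.items() if ph.ambiguous)
    changed = True
    while changed and pending:
        changed = False
        still = []
        for s in pending:
            cfgs = _configurations(*genotypes.genotypes[s])
            ok = [
                c
                for c in cfgs
                if _four_gamete_compatible(reference + [render(h) for h in c])
            ]
            if len(ok) == 1:
                result.samples[s] = PhasedSample(
                    haplotypes=ok[0],
                    confidence=1.0,
                    ambiguous=True,
                    resolved_by="compatibility",
                )
                reference.extend(render(h) for h in ok[0])
                changed = True
            else:
                still.append(s)
        pending = still

    # joint pass: individually both configurations may be compatible while
    # only some joint assignments of the remaining samples are.  The true
    # joint assignment is always compatible, so any sample whose
    # configuration is constant across all compatible joint assignments is
    # resolved correctly.  Enumeration is capped to keep the worst case cheap.
    if pending and 2 ** len(pending) <= 4096:
        cfg_lists = [_configurations(*genotypes.genotypes[s]) for s in pending]
        survivors: list[tuple[int, ...]] = []
        for combo in itertools.product(*(range(len(c)) for c in cfg_lists)):
            seqs = list(reference)
            for cfgs, pick in zip(cfg_lists, combo):
                seqs.extend(render(h) for h in cfgs[pick])
            if _four_gamete_compatible(seqs):
                survivors.append(combo)
        if survivors:
            for k, s in enumerate(pending):
                picks = {combo[k] for combo in survivors}
                if len(picks) == 1:
                    cfg = cfg_lists[k][picks.pop()]
                    result.samples[s] = PhasedSample(
                        haplotypes=cfg,
                        confidence=1.0,
                        ambiguous=True,
                        resolved_by="compatibility",
                    )
    return result


def phase_locus(
    locus: RadLocusUnphased,
    use_compatibility: bool = True,
    **em_kwargs,
) -> PhasedLocus:
    """Phase one locus end to end.

    Concatenation when a tag side is invariant; otherwise the two-marker EM,
    optionally followed by the infinite-sites compatibility resolution of
    ambiguous samples.
    """
    genotypes = TwoMarkerGenotypes.from_locus(locus)
    if 1 in genotypes.n_alleles:
        return concat_invariant(genotypes)
    result = em_phase(genotypes, **em_kwargs)
    if use_compatibility:
        result = resolve_by_compatibility(
            result,
            genotypes,
            locus.alleles[locus_assembly.LEFT],
            locus.alleles[locus_assembly.RIGHT],
        )
    return result


@dataclass
class PhaseAccuracy:
    """Phasing validation against simulator truth.

    ``accuracy`` is the proportion of correctly phased samples among the
    phase-ambiguous ones only; forced phases are reported separately (they
    are correct by construction whenever the genotype data are).
    """

    n_ambiguous: int
    n_ambiguous_correct: int
    n_forced: int
    n_forced_correct: int

    @property
    def accuracy(self) -> float:
        if self.n_ambiguous == 0:
            return 1.0
        return self.n_ambiguous_correct / self.n_ambiguous


def phase_accuracy(
    inferred: Mapping[str, tuple[str, str]],
    truth: Mapping[str, tuple[str, str]],
    ambiguous: Mapping[str, bool],
) -> PhaseAccuracy:
    """Compare inferred unordered haplotype pairs with the true pairs.

    ``inferred`` and ``truth`` map sample -> rendered haplotype pair;
    ``ambiguous`` marks the samples whose phase was not forced.
    """
    if set(inferred) - set(truth):
        raise ValueError("inferred samples missing from truth")
    acc = PhaseAccuracy(0, 0, 0, 0)
    for sample, pair in inferred.items():
        correct = tuple(sorted(pair)) == tuple(sorted(truth[sample]))
        if ambiguous[sample]:
            acc.n_ambiguous += 1
            acc.n_ambiguous_correct += int(correct)
        else:
            acc.n_forced += 1
            acc.n_forced_correct += int(correct)
    return acc
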