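import numpy as np
import pytest

from radhap import geometry
from radhap.locus_assembly import LEFT, RIGHT, tags_to_locus
from radhap.phasing import (
    PhasedSample,
    TwoMarkerGenotypes,
    concat_invariant,
    em_phase,
    phase_accuracy,
    phase_locus,
)
from radhap.simulate import SimConfig, emit_rad_observables, simulate_locus

from conftest import random_locus_seq


def geno(locus_id="L1", **samples):
    """Shorthand: samples as sample=(left pair, right pair)."""
    n_l = 1 + max(max(g[0]) for g in samples.values())
    n_r = 1 + max(max(g[1]) for g in samples.values())
    return TwoMarkerGenotypes(
        locus_id=locus_id, genotypes=dict(samples), n_alleles=(n_l, n_r)
    )


class TestEmPhase:
    def test_homozygous_left_forces_phase(self):
        g = geno(S1=((0, 0), (0, 1)))
        out = em_phase(g)
        assert out.samples["S1"].haplotypes == ((0, 0), (0, 1))
        assert out.samples["S1"].confidence == 1.0
        assert not out.samples["S1"].ambiguous

    def test_double_het_resolved_by_homozygote_support(self):
        """Four samples pin haplotypes A-x and B-y; the double het follows."""
        g = geno(
            S1=((0, 0), (0, 0)),  # A/A x/x -> A-x
            S2=((1, 1), (1, 1)),  # B/B y/y -> B-y
            S3=((0, 0), (0, 0)),
            S4=((1, 1), (1, 1)),
            S5=((0, 1), (0, 1)),  # A/B x/y: true phase A-x | B-y
        )
        out = em_phase(g)
        assert out.samples["S5"].haplotypes == ((0, 0), (1, 1))
        assert out.samples["S5"].confidence > 0.9

    def test_symmetric_double_hets_tie_break_lexicographic(self):
        g = geno(S1=((0, 1), (0, 1)), S2=((0, 1), (0, 1)))
        out = em_phase(g)
        for s in ("S1", "S2"):
            assert out.samples[s].confidence == pytest.approx(0.5)
            assert out.samples[s].haplotypes == ((0, 0), (1, 1))

    def test_frequencies_sum_to_one(self):
        g = geno(
            S1=((0, 1), (0, 1)), S2=((0, 0), (0, 1)), S3=((0, 1), (1, 1))
        )
        out = em_phase(g)
        assert sum(out.hap_freqs.values()) == pytest.approx(1.0)

    def test_sample_order_invariance(self):
        samples = {
            "S1": ((0, 0), (0, 0)),
            "S2": ((1, 1), (1, 1)),
            "S3": ((0, 1), (0, 1)),
        }
        a = em_phase(geno(**samples))
        b = em_phase(geno(**dict(reversed(list(samples.items())))))
        assert {s: p.haplotypes for s, p in a.samples.items()} == {
            s: p.haplotypes for s, p in b.samples.items()
        }

    def test_matches_exhaustive_likelihood_on_small_instance(self):
        """EM MAP equals the global maximum-likelihood phasing found by
        enumerating every joint configuration and maximizing the multinomial
        likelihood at its analytic optimum (haplotype counting)."""
        import itertools

        g = geno(
            S1=((0, 0), (0, 1)),
            S2=((0, 1), (0, 1)),
            S3=((0, 1), (1, 1)),
            S4=((0, 0), (0, 0)),
        )
        from radhap.phasing import _configurations

        cfg_lists = {s: _configurations(*gg) for s, gg in g.genotypes.items()}
        best = None
        for combo in itertools.product(*cfg_lists.values()):
            counts = {}
            for pair in combo:
                for h in pair:
                    counts[h] = counts.get(h, 0) + 1
            n = sum(counts.values())
            ll = sum(c * np.log(c / n) for c in counts.values())
            # multiplicity: unordered double-het configs carry factor 2
            ll += sum(np.log(2) for pair in combo if pair[0] != pair[1])
            if best is None or ll > best[0]:
                best = (ll, combo)
        em = em_phase(g)
        for s, pair in zip(cfg_lists, best[1]):
            assert em.samples[s].haplotypes == pair


class TestConcatInvariant:
    def test_invariant_left_forces_het_right(self):
        g = geno(S1=((0, 0), (0, 1)), S2=((0, 0), (1, 1)))
        out = concat_invariant(g)
        assert out.samples["S1"].haplotypes == ((0, 0), (0, 1))
        assert all(p.confidence == 1.0 for p in out.samples.values())

    def test_both_sides_invariant(self):
        g = geno(S1=((0, 0), (0, 0)))
        out = concat_invariant(g)
        assert out.samples["S1"].haplotypes == ((0, 0), (0, 0))

    def test_matches_em_phase(self):
        g = geno(S1=((0, 0), (0, 1)), S2=((0, 0), (1, 1)), S3=((0, 0), (0, 0)))
        a = concat_invariant(g)
        b = em_phase(g)
        assert {s: p.haplotypes for s, p in a.samples.items()} == {
            s: p.haplotypes for s, p in b.samples.items()
        }

    def test_requires_invariant_side(self):
        with pytest.raises(ValueError):
            concat_invariant(geno(S1=((0, 1), (0, 1))))


class TestCompatibilityResolution:
    def test_resolutions_always_match_truth(self, sim_loci):
        """Samples resolved by four-gamete compatibility are always correct."""
        cfg, loci = sim_loci
        n_resolved = 0
        for locus in loci:
            tags, _ = emit_rad_observables(locus.alignment, cfg)
            unphased = tags_to_locus(locus.locus_id, locus.chrom, locus.pos, tags)
            res = phase_locus(unphased)
            rendered = res.rendered(unphased.alleles[LEFT], unphased.alleles[RIGHT])
            for s, pair in rendered.items():
                if res.samples[s].resolved_by == "compatibility":
                    n_resolved += 1
                    assert tuple(sorted(pair)) == tuple(
                        sorted(locus.truth.true_phases[s])
                    )
        assert n_resolved > 0


class TestPhaseAccuracy:
    def test_all_forced_vacuous(self):
        inferred = {"S1": ("AA", "AA")}
        acc = phase_accuracy(inferred, {"S1": ("AA", "AA")}, {"S1": False})
        assert acc.accuracy == 1.0
        assert acc.n_ambiguous == 0
        assert acc.n_forced == 1

    def test_one_swapped_het_reduces_by_one_over_n(self):
        truth = {f"S{i}": ("AC", "GT") for i in range(4)}
        inferred = dict(truth)
        inferred["S0"] = ("AT", "GC")  # wrong pairing
        amb = {s: True for s in truth}
        acc = phase_accuracy(inferred, truth, amb)
        assert acc.accuracy == pytest.approx(3 / 4)

    def test_unknown_sample_raises(self):
        with pytest.raises(ValueError):
            phase_accuracy({"S9": ("A", "A")}, {"S1": ("A", "A")}, {"S9": True})


def test_end_to_end_phasing_accuracy_is_high(sim_loci):
    """Simulate -> cut -> rephase recovers nearly all ambiguous phases."""
    cfg, loci = sim_loci
    amb = correct = 0
    for locus in loci:
        tags, _ = emit_rad_observables(locus.alignment, cfg)
        unphased = tags_to_locus(locus.locus_id, locus.chrom, locus.pos, tags)
        res = phase_locus(unphased)
        rendered = res.rendered(unphased.alleles[LEFT], unphased.alleles[RIGHT])
        acc = phase_accuracy(
            rendered,
            locus.truth.true_phases,
            {s: res.samples[s].ambiguous for s in rendered},
        )
        amb += acc.n_ambiguous
        correct += acc.n_ambiguous_correct
        assert acc.n_forced_correct == acc.n_forced
    assert amb > 0
    assert correct / amb > 0.9
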