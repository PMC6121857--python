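# radhap

Phased RAD-locus haplotypes for ancestry-aware population genomics.

## The problem

Restriction site-associated DNA sequencing (RAD-seq) ordinarily yields short
unphased fragments, which makes per-locus estimates of sequence diversity and
divergence noisy and makes genealogical analysis impossible. When the two
350-bp RAD tags flanking one PstI restriction site are sequenced with
overlapping read pairs and phased against each other, every site yields a
696-bp haplotype (350 × 2 − 4 bp of shared PstI overhang, with the 6-bp
CTGCAG motif invariant and 690 potentially variable sites). Haplotypes of
this length support per-locus gene trees, absolute divergence measures and
divergence-time estimates with only a handful of diploids per population.

`radhap` implements that pipeline for the classic three-population
stickleback design — one marine population (RS) and two freshwater ponds
(BL, BP) — where the question is how old the marine/freshwater allelic
divergence is and how much of the genome it affects: ancient standing
genetic variation maintained across the metapopulation versus recent
mutation. A ninespine-stickleback outgroup splitting 15 Mya calibrates every
gene tree. A structured-coalescent simulator with full ground truth (true
phases, true haplogroups, true node times) makes every stage testable
without any sequencing data.

## What it computes

- **Locus assembly** — merge overlapping read pairs on exact overlap, trim
  contigs to 350 bp anchored at the restriction site, assemble left/right
  tags into 696-bp loci, and filter loci genotyped in fewer than four
  individuals in any population.
- **Phasing** — tag haplotypes are coded as two multiallelic markers; the
  classical two-marker EM estimates haplotype frequencies
  (E-step weights for a double heterozygote's two configurations
  ∝ products of haplotype frequencies), followed by an infinite-sites
  resolution step: a configuration is rejected if the implied haplotype set
  fails the four-gamete test, which resolves most ambiguous samples exactly.
- **Genealogies** — per-locus UPGMA clock trees from per-site distance
  matrices; outgroup monophyly check; node ages in years by proportional
  calibration, age(v) = 15 My × h(v)/h(root); lineage-sorting classes
  (`fw_ibd`, `marine_mono`, `reciprocal_mono`, `none`), where reciprocal
  monophyly of marine and freshwater haplotypes defines a divergent locus;
  infinite-sites haplotype networks (minimum-spanning, ties retained).
- **Statistics** — nucleotide diversity π (mean pairwise per-site
  differences), between-group divergence d_XY, haplotype-based Hudson
  F_ST = 1 − H_w/H_b, predicted sampling variances of π and d_XY as a
  function of sequence length and sample size, and label-permutation tests.
- **Genome scan** — Gaussian-kernel smoothing of per-locus TMRCA along the
  chromosome (500-kb windows) and outlier windows where the observed
  smoothed value exceeds 99.9% of position-preserving permutations.

## Worked example

`examples/diversity_and_trees.py` simulates one locus whose marine and
freshwater haplogroups split 8 Mya and runs the full per-locus analysis:

```text
locus L00000: 28 segregating sites
  pi    RS=0.00255  BL=0.00077  BP=0.00077  FW=0.00072
  dXY(marine, freshwater) = 0.03360
  Hudson FST: RS-BL=0.951  RS-BP=0.951  BL-BP=-0.125
  lineage sorting: reciprocal_mono
  outgroup monophyletic: True
  calibrated ingroup TMRCA: 7.74 My (truth 8.09 My)

haplotype network: 5 distinct haplotypes, 4 edges, MST weight 28 steps
```

Within-group diversity is an order of magnitude below the between-habitat
divergence d_XY, the marine-pond comparisons are near-fixed (F_ST ≈ 0.95)
while the two ponds are undifferentiated, the locus is reciprocally
monophyletic, and the outgroup-calibrated ingroup TMRCA recovers the true
8.1-My split within 5%. The other example scripts cover dataset simulation
(`simulate_dataset.py`), the simulate–cut–rephase phasing validation
(`phase_validation.py`, accuracy 0.975 on ambiguous samples) and the
end-to-end pipeline with a TMRCA outlier scan (`tmrca_scan.py`).

The same pipeline runs from the shell:

```bash
radhap all --config config.yaml --out results/ --seed 7
```

writing tag/phased FASTA, locus-summary TSV, newick trees, the smoothed
TMRCA track, outlier BED files and a bookkeeping manifest.

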