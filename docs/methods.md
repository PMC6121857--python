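# Methods

## The simulator

The synthetic-data generator draws, per locus, a genealogy for the 2×14
haplotypes of the study design (5 marine RS, 5 + 4 freshwater BL/BP
diploids) plus one outgroup lineage.

**Non-divergent loci** follow a panmictic Kingman coalescent over all
ingroup haplotypes: with k lineages the waiting time to the next coalescence
is exponential with mean 2·N_e·g / C(k,2) years, where N_e is the diploid
effective size and g the generation time.

**Divergent loci** carry two habitat haplogroups. Marine (RS) haplotypes
belong to the marine haplogroup; freshwater (BL, BP) haplotypes belong to
the freshwater haplogroup, except that each freshwater haplotype is
independently swapped to the marine haplogroup with probability
`marine_contamination` (default 0 — complete sorting). Each haplogroup
coalesces internally as above; the two haplogroup ancestors then coalesce at
max(t_split, both group TMRCAs) plus an exponential waiting time, so every
marine–freshwater pair diverges at least `t_split_years` ago.

**Calibration anchor.** The outgroup tip always joins the ingroup root at
exactly `t_outgroup_years` = 15 My. Genealogies whose ingroup TMRCA would
exceed that (vanishingly rare at the defaults) are redrawn.

**Mutation** is infinite-sites: per branch, Poisson(μ · branch_years · 690)
mutations, each assigned a distinct position drawn without replacement among
the 690 mutable sites (the 6-bp PstI motif never mutates; exhausting the 690
sites raises an error rather than silently recycling positions). The
ancestral sequence is random with equal base frequencies and each mutation
substitutes a uniformly chosen different base.

### Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `samples_per_pop` | RS 5, BL 5, BP 4 | diploids | the study design |
| `t_outgroup_years` | 15e6 | years | threespine/ninespine split used as clock anchor |
| `t_split_years` | 6e6 | years | mid-range of the ancient haplogroup ages under study |
| `ne_diploid` | 140,000 | diploids | see below |
| `generation_time_years` | 2 | years | typical stickleback generation |
| `mu_per_site_per_year` | 2.5e-9 | /site/year | vertebrate nuclear point-substitution rate |
| `frac_divergent` | 0.02 | — | ≈2% of loci are reciprocally monophyletic in data of this design |
| `locus_len` / `mutable_sites` | 696 / 690 | bp | 350×2 − 4, minus the invariant 6-bp motif |

The coalescent parameters are not observable separately at a single locus;
what matters is θ = 4·N_e·μ·g = 2.8×10⁻³ per site, chosen once so that a
simulated 28-haplotype locus segregates a median of ~7 sites — the observed
median for this kind of dataset. With μ and g fixed at literature values
this gives N_e = 140,000.

### What the simulator does and does not emulate

It reproduces the genealogical structure the analysis assumes: an exact
15-My outgroup anchor, habitat-associated haplogroups of configurable age,
optional incomplete lineage sorting via `marine_contamination`, clustered
divergent loci via `divergence_regions`, and the tag/read observables of the
laboratory protocol (phase erasure, 4-bp overhang duplication, mergeable
250-bp read pairs).

It does **not** model: recombination within a 696-bp locus (none is
expected at that scale); genealogical correlation between loci (loci are
independent, so regional signals exist only where planted — in real genomes
physically linked loci share old genealogies, which is why outlier regions
can survive the removal of divergent loci while here they generally do not);
population structure at non-divergent loci (panmixia, whereas real
populations show background F_ST ≈ 0.1–0.2 — phasing is if anything easier
under structure, so the phasing validation here is conservative in that
respect); sequencing or genotyping error; selection dynamics (habitat
association is imposed structurally). Passing tests therefore validate the
estimators under the stated genealogical model, not robustness to
data-quality pathologies.

## Locus geometry

A locus spans 696 bp with the PstI motif CTGCAG at 0-based offsets 344–349.
The left tag is `locus[:350]` and ends with the full motif; the right tag is
`locus[346:]` and begins with the motif's last four bases — the 4-bp
overhang both tags share, collapsed once at assembly. Genomic coordinates:
`pos` is the forward-strand position of the motif's first base and a locus
covers `[pos−344, pos+352)` (0-based half-open). Note the two tags cannot
*both* contain the full 6-bp motif at a 4-bp overlap (the motif cannot
overlap itself at shift 2); anchoring the full motif at the end of the left
tag is the convention used throughout.

## Phasing

Tag haplotypes are coded as alleles of two multiallelic markers. With no
recombination inside a locus, phasing is the classical two-marker
multinomial EM: only samples heterozygous at both markers are ambiguous
(two configurations), the E-step weights configurations by the product of
current haplotype frequencies, the M-step re-estimates frequencies from
expected counts (initialisation uniform over compatible haplotypes,
tolerance 1e-8 on the frequency sup-norm, at most 500 iterations;
non-convergence returns the current assignment flagged unconverged). Each
sample takes its maximum-posterior configuration; exact posterior ties go to
the lexicographically smallest haplotype pair.

EM alone plateaus near 94% accuracy on ambiguous samples at the default
diversity, because ~20% of ambiguous samples involve singleton haplotypes
for which the two configurations are exactly symmetric in frequency space.
A second, deterministic step therefore exploits the infinite-sites model:
the true haplotype set descends from a single genealogy, so the true
configuration always passes the four-gamete test against any subset of true
haplotypes. Starting from the forced (homozygote-containing) haplotypes, any
ambiguous sample with exactly one compatible configuration is resolved — 
provably correctly, given error-free genotypes — and extends the reference;
after the fixed point, remaining samples are resolved jointly (exhaustive
enumeration of their configuration combinations, capped at 4096, keeping
samples whose configuration is constant across all compatible joint
assignments). Unresolved samples keep the EM assignment. Only forced and
compatibility-resolved haplotypes enter the reference, so EM guesses never
contaminate it. In validation this step resolves ~85% of ambiguous samples
with zero observed errors, lifting aggregate accuracy to 0.96–0.97.

Accuracy is always reported on ambiguous samples only; forced phases are
counted separately. Samples with a genotype at only one tag are excluded at
that locus, never imputed.

## Gene trees, calibration, classification

Trees are UPGMA on per-site pairwise distance matrices: deterministic,
ultrametric by construction, with node height equal to half the merge
distance and average-linkage updates. Ties on the minimal distance merge the
pair with the lexicographically smallest representative tip labels. UPGMA
replaces a Bayesian clock-tree estimator deliberately: the downstream logic
(monophyly tests and proportional node-age calibration) is
estimator-agnostic, and `io.newick_to_genetree` accepts externally estimated
clock trees for the same classification/calibration path. Point estimates
replace posterior summaries; no per-locus credibility intervals are
produced.

Calibration requires the ingroup to be monophyletic to the exclusion of the
single outgroup tip (checked by bipartition). Ages are then
age(v) = 15 My × h(v)/h(root), which is invariant to any rescaling of the
distance matrix. Loci with zero root height are flagged uninformative.

Lineage-sorting classes test whether the freshwater haplotypes (BL ∪ BP,
required to include both ponds) and the marine haplotypes each form a clade.
Monophyly requires a strictly positive stem branch (tolerance 1e-12), so
groups separated only by zero-length branches — no fixed difference — do not
count; consequently a reciprocally monophyletic locus always has d_XY > 0.
Classes: both → `reciprocal_mono` (the operational definition of a divergent
locus), one → `fw_ibd` or `marine_mono`, neither → `none`; any population
missing at the locus → undefined.

Haplotype networks collapse identical sequences and connect them by a
minimum-spanning network on Hamming distances (mutational steps, valid under
infinite sites): an edge is retained iff it occurs in *some* minimum
spanning tree, so tied alternatives appear as reticulations.

## Statistics

π is the mean per-site difference over unordered pairs; d_XY the same over
cross-group pairs only; Hudson's haplotype F_ST is 1 − H_w/H_b with H_w the
*unweighted* mean of the two within-group mean pairwise difference counts
(sample sizes are nearly equal in this design) and H_b the between-group
mean; H_b = 0 returns NaN. Sites with non-ACGT characters are handled by
pairwise deletion with per-pair effective lengths. Permutation tests permute
group labels for a difference in means with p = (1 + #hits)/(n_perm + 1).

Predicted sampling variances: for π the standard no-recombination result

V(π̂) = (n+1)/(3(n−1)L) · π + 2(n²+n+3)/(9n(n−1)) · π²,

whose first (mutational) term shrinks with sequence length L and second
(genealogical) term with sample size n; it is exact for the simulated
panmictic model and is verified empirically against 2000 simulated loci.
For d_XY the package uses the net-divergence decomposition
d_XY = d_A + (π_X + π_Y)/2 and combines binomial site-sampling variance of
the between component, d(1−d)/L, with a quarter of each within-group π
variance. This captures the L- and n-dependence relevant for study design
(a 700-bp locus at n = 5 outperforms a 100-bp locus at any n ≤ 50) but omits
ancestral-coalescent contributions to the between-population term, so it is
treated as a design heuristic rather than an exact variance.

## Genome scan

Per-locus TMRCA values are smoothed with a Nadaraya–Watson estimator under a
Gaussian kernel. "Window size" 500 kb is interpreted as the total kernel
support: truncation at ±250 kb and σ = window/6 (configurable, since a
window size does not define σ by itself). The track is evaluated on a 10-kb
grid; grid points with total kernel weight below 1e-8 (no locus within the
truncated window) are masked. The smoother is linear in the values.

Outliers: the values are permuted across the fixed locus positions
genome-wide (position preservation controls for local locus density — 
sparsely sampled regions get wider permutation envelopes), each permutation
is re-smoothed, and a grid point is flagged when the observed smoothed value
exceeds the chosen fraction (default 99.9%) of permuted values by exact rank
count (at most ⌊(1−q)·n_perm⌋ permuted values ≥ observed). Adjacent flagged
grid points merge into half-open bp intervals (BED). A two-sided option
flags both tails. `remove_and_rescan` drops reciprocally monophyletic loci
and loci with marine–freshwater F_ST above a threshold (default 0.5), rescans,
and reports the fraction of the original outlier span that persists.

## Pipeline and reproducibility

`run_pipeline` chains simulate → build-loci → phase → trees/classify →
stats → scan, writing plain-text artifacts (FASTA/TSV/BED/newick) and a
manifest of per-stage counts (loci simulated, retained after the
four-individuals-per-population filter, phased, outgroup-monophyletic, per
lineage-sorting class). All randomness derives from the configured seed
(per-locus substreams via seed sequences), and identical configuration
yields byte-identical outputs. Validation experiments in the test suite use
200-locus batches (2000 for the variance check) — sizes at which the
Monte-Carlo error of every checked quantity is several times smaller than
its acceptance margin.

## Known limitations

- Real-data ingestion enters at the "called tag alleles per sample" level;
  SNP calling, demultiplexing, reference alignment and reverse-strand
  normalisation are upstream of this package.
- The four-gamete resolution step assumes error-free genotypes and an
  infinite-sites locus; with genotyping error it could reject the true
  configuration and fall back to EM (confidence reported either way).
- The d_XY variance formula is a design heuristic (above).
- Independent loci mean the scan's planted-signal experiments model regional
  structure only through locus placement, not through linkage.
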