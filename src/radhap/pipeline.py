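"""End-to-end pipeline driver: simulate -> build loci -> phase -> trees ->
classify -> stats -> scan, with per-stage artifacts and a bookkeeping
manifest (loci in, loci filtered, loci outgroup-monophyletic, loci per
lineage-sorting class)."""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, io, locus_assembly, phasing, popgen, scan as scan_mod
from .genealogy import (
    CLASS_RECIPROCAL,
    GeneTree,
    LocusSummary,
    calibrate_tmrca,
    check_outgroup_monophyly,
    classify_lineage_sorting,
    pairwise_diff_matrix,
    upgma_tree,
)
from .simulate import (
    SimConfig,
    SimulatedLocus,
    emit_rad_observables,
    simulate_dataset,
)


@dataclass
class PipelineConfig:
    """Configuration for a full synthetic-mode run."""

    sim: SimConfig = field(default_factory=SimConfig)
    min_individuals_per_pop: int = 4
    calib_years: float = 15e6
    fst_threshold: float = 0.5
    quantile: float = 0.999
    window_bp: float = scan_mod.DEFAULT_WINDOW_BP
    grid_step: float = scan_mod.DEFAULT_GRID_STEP
    n_perm: int = 1000
    scan_two_sided: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.quantile < 1.0:
            raise ValueError("quantile must be in (0.5, 1)")
        if self.min_individuals_per_pop < 1:
            raise ValueError("min_individuals_per_pop must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            sim = dict(sim)
            if "samples_per_pop" in sim:
                sim["samples_per_pop"] = dict(sim["samples_per_pop"])
            sim.setdefault("seed", d.get("seed", 0))
            sim = SimConfig(**sim)
        return cls(sim=sim, **d)


def summarize_locus(
    locus_id: str,
    chrom: str,
    pos: int,
    haplotypes: dict[str, str],
    outgroup_seq: str | None,
    calib_years: float = 15e6,
) -> tuple[LocusSummary, GeneTree]:
    """Statistics, gene tree, lineage class and calibrated ages for one locus.

    ``haplotypes`` maps ``sample_pop_hapN`` labels to 696-bp ingroup
    sequences; the outgroup haplotype (when available) is added as tip
    ``outgroup`` before tree building.
    """
    from .genealogy import population_of

    pops: dict[str, list[str]] = {}
    for label, seq in haplotypes.items():
        pops.setdefault(population_of(label), []).append(seq)
    rs = pops.get("RS", [])
    bl = pops.get("BL", [])
    bp = pops.get("BP", [])
    fw = bl + bp
    ingroup = rs + fw
    arr = np.frombuffer("".join(ingroup).encode(), dtype=np.uint8).reshape(
        len(ingroup), -1
    )
    n_seg = int(((arr != arr[0]).any(axis=0)).sum())

    summary = LocusSummary(
        locus_id=locus_id,
        chrom=chrom,
        pos=pos,
        pi_rs=popgen.nucleotide_diversity(rs) if len(rs) > 1 else float("nan"),
        pi_bl=popgen.nucleotide_diversity(bl) if len(bl) > 1 else float("nan"),
        pi_bp=popgen.nucleotide_diversity(bp) if len(bp) > 1 else float("nan"),
        pi_fw=popgen.nucleotide_diversity(fw) if len(fw) > 1 else float("nan"),
        pi_all=popgen.nucleotide_diversity(ingroup),
        dxy_mf=popgen.dxy(rs, fw),
        fst_rs_bl=popgen.hudson_fst(rs, bl),
        fst_rs_bp=popgen.hudson_fst(rs, bp),
        fst_bl_bp=popgen.hudson_fst(bl, bp),
        n_segregating_sites=n_seg,
    )

    labels = sorted(haplotypes)
    seqs = [haplotypes[l] for l in labels]
    populations = {l: population_of(l) for l in labels}
    if outgroup_seq is not None:
        labels.append("outgroup")
        seqs.append(outgroup_seq)
        populations["outgroup"] = "OUT"
    dist = pairwise_diff_matrix(seqs)
    gtree = upgma_tree(dist, labels, populations=populations)
    summary.lineage_class = classify_lineage_sorting(gtree)
    if outgroup_seq is not None:
        summary.outgroup_ok = check_outgroup_monophyly(gtree)
        if summary.outgroup_ok:
            ages = calibrate_tmrca(gtree, calib_years=calib_years)
            if ages is not None:
                summary.tmrca_ingroup_years = ages.tmrca_ingroup_years
                summary.tmrca_mf_split_years = ages.tmrca_mf_split_years
    return summary, gtree


# ---------------------------------------------------------------------------
# pipeline stages (each writes its artifacts under the output directory)
# ---------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig, out: Path) -> list[SimulatedLocus]:
    out.mkdir(parents=True, exist_ok=True)
    loci = simulate_dataset(config.sim)

    tag_records: dict[str, str] = {}
    outgroup_records: dict[str, str] = {}
    truth_rows = []
    bed_rows = []
    for locus in loci:
        tags, _ = emit_rad_observables(locus.alignment, config.sim)
        for sample, sides in tags.items():
            for side in (locus_assembly.LEFT, locus_assembly.RIGHT):
                for k, seq in enumerate(sides[side]):
                    tag_records[f"{sample}|{locus.locus_id}|{side}|{k}"] = seq
        outgroup_records[locus.locus_id] = locus.alignment["outgroup"]
        start, end = geometry.locus_interval(locus.pos)
        bed_rows.append((locus.chrom, start, end, locus.locus_id))
        truth_rows.append(
            {
                "locus_id": locus.locus_id,
                "chrom": locus.chrom,
                "pos": locus.pos,
                "divergent": int(locus.truth.divergent),
                "true_tmrca_years": locus.truth.tmrca_ingroup_years,
                "true_mf_join_years": locus.truth.tmrca_mf_join_years,
                "haplogroups": ";".join(
                    f"{k}={v}" for k, v in sorted(locus.truth.haplogroup.items())
                ),
            }
        )
    io.write_fasta(out / "tags.fasta", tag_records)
    io.write_fasta(out / "outgroup.fasta", outgroup_records)
    io.write_tsv(out / "truth.tsv", pd.DataFrame(truth_rows))
    io.write_bed(out / "loci.bed", bed_rows)
    pops = sorted(
        {label.rsplit("_", 2)[0] for l in loci for label in l.truth.true_phases}
    )
    io.write_tsv(
        out / "populations.tsv",
        pd.DataFrame(
            {"sample": pops, "population": [s.rstrip("0123456789") for s in pops]}
        ),
    )
    return loci


def stage_build_loci(
    config: PipelineConfig, out: Path
) -> tuple[list[locus_assembly.RadLocusUnphased], dict[str, str]]:
    """Group tag sequences by site, call tag alleles, apply completeness filter."""
    tags = io.read_fasta(out / "tags.fasta")
    bed = {name: (chrom, start, end) for chrom, start, end, name in io.read_bed(out / "loci.bed")}
    pop_df = io.read_tsv(out / "populations.tsv")
    populations = dict(zip(pop_df["sample"], pop_df["population"]))

    by_locus: dict[str, dict[str, dict[str, list[str]]]] = {}
    for header, seq in tags.items():
        sample, locus_id, side, _ = header.split("|")
        by_locus.setdefault(locus_id, {}).setdefault(
            sample, {locus_assembly.LEFT: [], locus_assembly.RIGHT: []}
        )[side].append(seq)

    loci = []
    for locus_id in sorted(by_locus):
        chrom, start, _end = bed[locus_id]
        pos = start + geometry.MOTIF_START
        loci.append(
            locus_assembly.tags_to_locus(locus_id, chrom, pos, by_locus[locus_id])
        )
    kept, log = locus_assembly.filter_loci(
        loci, populations, min_individuals_per_pop=config.min_individuals_per_pop
    )
    io.write_tsv(
        out / "exclusions.tsv",
        pd.DataFrame(log, columns=["locus_id", "sample", "reason"]),
    )
    return kept, populations


def stage_phase(
    config: PipelineConfig,
    loci: list[locus_assembly.RadLocusUnphased],
    populations: dict[str, str],
    out: Path,
) -> dict[str, dict[str, str]]:
    """Phase every retained locus; returns locus_id -> {tip label: 696-bp seq}."""
    phased_records: dict[str, str] = {}
    report = []
    alignments: dict[str, dict[str, str]] = {}
    for locus in loci:
        result = phasing.phase_locus(locus)
        rendered = result.rendered(
            locus.alleles[locus_assembly.LEFT], locus.alleles[locus_assembly.RIGHT]
        )
        aln: dict[str, str] = {}
        for sample, pair in rendered.items():
            pop = populations[sample]
            ph = result.samples[sample]
            for k, seq in enumerate(pair, start=1):
                label = f"{sample}_{pop}_hap{k}"
                aln[label] = seq
                phased_records[f"{label}|{locus.locus_id}|conf={ph.confidence:.6f}"] = seq
            report.append(
                {
                    "locus_id": locus.locus_id,
                    "sample": sample,
                    "ambiguous": int(ph.ambiguous),
                    "confidence": ph.confidence,
                    "converged": int(result.converged),
                }
            )
        alignments[locus.locus_id] = aln
    io.write_fasta(out / "phased.fasta", phased_records)
    io.write_tsv(out / "phasing_report.tsv", pd.DataFrame(report))
    return alignments


def stage_trees_classify(
    config: PipelineConfig,
    alignments: dict[str, dict[str, str]],
    loci_meta: dict[str, tuple[str, int]],
    out: Path,
) -> list[LocusSummary]:
    outgroup = io.read_fasta(out / "outgroup.fasta")
    summaries = []
    newick_rows = []
    for locus_id in sorted(alignments):
        chrom, pos = loci_meta[locus_id]
        summary, gtree = summarize_locus(
            locus_id,
            chrom,
            pos,
            alignments[locus_id],
            outgroup.get(locus_id),
            calib_years=config.calib_years,
        )
        summaries.append(summary)
        newick_rows.append({"locus_id": locus_id, "newick": io.tree_to_newick(gtree)})
    io.write_tsv(out / "trees.tsv", pd.DataFrame(newick_rows))
    io.write_tsv(
        out / "locus_summary.tsv",
        pd.DataFrame([dataclasses.asdict(s) for s in summaries]),
    )
    return summaries


def stage_scan(
    config: PipelineConfig, summaries: list[LocusSummary], out: Path
) -> tuple[scan_mod.ScanTrack, scan_mod.ScanTrack | None, float]:
    usable = [
        s
        for s in summaries
        if s.outgroup_ok
        and s.tmrca_ingroup_years is not None
        and np.isfinite(s.tmrca_ingroup_years)
    ]
    if len(usable) < 2:
        raise RuntimeError("scan stage: fewer than 2 loci with calibrated TMRCA")
    positions = np.array([s.pos for s in usable], dtype=float)
    values = np.array([s.tmrca_ingroup_years for s in usable])
    chrom = usable[0].chrom
    # marine-freshwater FST: mean of the two marine-pond comparisons
    pair_fst = np.array([[s.fst_rs_bl, s.fst_rs_bp] for s in usable], dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows stay NaN
        fst_mf = np.nanmean(pair_fst, axis=1)
    keep = scan_mod.fst_class_keep_mask(
        [s.lineage_class for s in usable], fst_mf, fst_threshold=config.fst_threshold
    )
    full, reduced, persist = scan_mod.remove_and_rescan(
        positions,
        values,
        keep,
        n_perm=config.n_perm,
        quantile=config.quantile,
        seed=config.seed,
        window_bp=config.window_bp,
        grid_step=config.grid_step,
        chrom=chrom,
    )
    track_df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": full.grid.astype(int),
            "smoothed_tmrca": full.values,
            "q_upper": full.upper_envelope,
        }
    )
    io.write_tsv(out / "tmrca_track.tsv", track_df)
    io.write_bed(
        out / "tmrca_outliers.bed",
        [(chrom, s, e, "tmrca_outlier") for s, e in full.outliers],
    )
    io.write_bed(
        out / "tmrca_outliers_reduced.bed",
        [(chrom, s, e, "tmrca_outlier") for s, e in (reduced.outliers if reduced else [])],
    )
    return full, reduced, persist


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage and write a manifest of per-stage counts.

    Returns the manifest dict.  Identical (config, seed) reruns regenerate
    every artifact byte-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_loci = stage_simulate(config, out)
    kept, populations = stage_build_loci(config, out)
    alignments = stage_phase(config, kept, populations, out)
    loci_meta = {l.locus_id: (l.chrom, l.pos) for l in kept}
    summaries = stage_trees_classify(config, alignments, loci_meta, out)
    full, reduced, persist = stage_scan(config, summaries, out)

    class_counts: dict[str, int] = {}
    for s in summaries:
        key = s.lineage_class or "undefined"
        class_counts[key] = class_counts.get(key, 0) + 1
    manifest = {
        "seed": config.seed,
        "n_loci_simulated": len(sim_loci),
        "n_loci_after_filter": len(kept),
        "n_loci_phased": len(alignments),
        "n_loci_outgroup_ok": sum(1 for s in summaries if s.outgroup_ok),
        "class_counts": class_counts,
        "n_divergent_true": sum(1 for l in sim_loci if l.truth.divergent),
        "outlier_span_bp": int(sum(e - s for s, e in full.outliers)),
        "outlier_span_bp_reduced": int(
            sum(e - s for s, e in reduced.outliers) if reduced else 0
        ),
        "outlier_persistence": None if persist != persist else float(persist),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
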