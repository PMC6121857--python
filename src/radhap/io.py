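"""Readers and writers for the pipeline's file formats.

FASTA via Biopython, tables via pandas (TSV), BED as 0-based half-open
intervals, newick via dendropy with branch lengths kept to 12 significant
digits.  FASTA headers carry structured metadata as ``|``-separated fields
and round-trip exactly.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genealogy import GeneTree, population_of


def write_fasta(path, records: Mapping[str, str]) -> None:
    """Write ``{header: sequence}`` records in input order."""
    recs = [
        SeqRecord(Seq(seq), id=header, description="")
        for header, seq in records.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description or rec.id
        if header in out:
            raise ValueError(f"{path}: duplicate FASTA header {header!r}")
        out[header] = str(rec.seq).upper()
    return out


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(path, intervals: Iterable[tuple]) -> None:
    """Write (chrom, start, end[, name]) rows as 0-based half-open BED."""
    with open(path, "w") as fh:
        for row in intervals:
            chrom, start, end = row[0], int(row[1]), int(row[2])
            if end < start:
                raise ValueError(f"BED interval end < start: {row}")
            rest = "\t".join(str(x) for x in row[3:])
            fh.write(f"{chrom}\t{start}\t{end}" + (f"\t{rest}" if rest else "") + "\n")


def read_bed(path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: malformed BED line")
            out.append((fields[0], int(fields[1]), int(fields[2]), *fields[3:]))
    return out


def tree_to_newick(gtree: GeneTree) -> str:
    return gtree.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".12g",
    ).strip()


def newick_to_genetree(
    newick: str,
    populations: Mapping[str, str] | None = None,
    time_units: str = "subs/site",
) -> GeneTree:
    """Parse a rooted ultrametric newick string into a :class:`GeneTree`.

    The hook for plugging externally estimated clock trees (e.g. Bayesian
    MCC trees) into classification and calibration: node ages are recovered
    from the branch lengths.
    """
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        rooting="force-rooted",
        preserve_underscores=True,
    )
    tree.is_rooted = True
    # set ages from root-to-tip depths (assumes a clock; tips at age 0)
    depths: dict = {}
    maxdepth = 0.0
    for node in tree.preorder_node_iter():
        d = 0.0 if node.parent_node is None else depths[node.parent_node] + (
            node.edge.length or 0.0
        )
        depths[node] = d
        maxdepth = max(maxdepth, d)
    for node in tree.preorder_node_iter():
        node.age = maxdepth - depths[node]
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    pops = dict(populations) if populations else {l: population_of(l) for l in labels}
    return GeneTree(tree=tree, populations=pops, time_units=time_units)
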