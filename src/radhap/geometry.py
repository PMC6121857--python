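"""Geometry of a PstI RAD locus.

A RAD locus is the pair of 350-bp RAD tags flanking one PstI restriction
site, assembled into a single haplotype of 350*2 - 4 = 696 bp.  The 6-bp
recognition motif (CTGCAG) is invariant, so 690 of the 696 positions can
vary.  The two tags share the 4-bp overhang of the PstI cut, which is the
4-base overlap collapsed at assembly.

Coordinate conventions used throughout the package:

* ``pos`` is the 0-based forward-strand genome coordinate of the first
  base of the motif.
* Within the 696-bp locus the motif occupies offsets
  ``MOTIF_START .. MOTIF_START+5`` (344..349 inclusive).
* The left tag is ``locus[:350]`` and therefore *ends* with the full
  motif; the right tag is ``locus[346:]`` and begins with the motif's
  last four bases — the overhang the two tags share.
* A locus spans the half-open genomic interval ``[pos-344, pos+352)``.
"""

from __future__ import annotations

MOTIF = "CTGCAG"
MOTIF_LEN = len(MOTIF)
TAG_LEN = 350
OVERHANG_LEN = 4
LOCUS_LEN = 2 * TAG_LEN - OVERHANG_LEN  # 696
MOTIF_START = TAG_LEN - MOTIF_LEN  # 344: motif ends the left tag
RIGHT_TAG_START = TAG_LEN - OVERHANG_LEN  # 346: right tag begins in the motif
N_MUTABLE = LOCUS_LEN - MOTIF_LEN  # 690

#: locus offsets that may carry variation (everything outside the motif)
MUTABLE_POSITIONS = tuple(
    i for i in range(LOCUS_LEN) if not (MOTIF_START <= i < MOTIF_START + MOTIF_LEN)
)


def split_locus(locus: str) -> tuple[str, str]:
    """Split a 696-bp locus haplotype into its (left, right) 350-bp tags.

    The 4-bp PstI overhang is re-duplicated so the tags overlap by 4 bases.
    """
    if len(locus) != LOCUS_LEN:
        raise ValueError(f"locus must be {LOCUS_LEN} bp, got {len(locus)}")
    return locus[:TAG_LEN], locus[RIGHT_TAG_START:]


def locus_interval(pos: int) -> tuple[int, int]:
    """Half-open genomic interval covered by the locus at motif position ``pos``."""
    return pos - MOTIF_START, pos - MOTIF_START + LOCUS_LEN
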