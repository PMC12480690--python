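"""Genomic sequence helpers and the splice-site coordinate convention.

Every splice-site is anchored at the 1-based genomic coordinate of its
intron-terminal base on the forward strand:

* donor: the "G" of the GT dinucleotide that starts the intron
  (relative position 0 on the transcribed strand, +1 is the "T");
* acceptor: the "G" of the AG dinucleotide that ends the intron
  (relative position 0, -1 is the "A").

Relative positions are always counted along the transcribed strand, so for
minus-strand sites the genomic axis is flipped.  Intronic bases sit at
positive relative positions for donors and negative ones for acceptors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DONOR = "donor"
ACCEPTOR = "acceptor"


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SpliceSite:
    """A donor or acceptor splice-site anchored at its intron-terminal base."""

    site_id: str
    chrom: str
    position: int  # 1-based forward-strand coordinate of the terminal G
    strand: str  # "+" or "-"
    site_type: str  # "donor" or "acceptor"
    gene_id: str = ""

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.site_type not in (DONOR, ACCEPTOR):
            raise ValueError(f"unknown site_type {self.site_type!r}")


def rel_to_genomic(position: int, strand: str, rel: int) -> int:
    """Map a transcribed-strand relative position to a 1-based genomic one."""
    return position + rel if strand == "+" else position - rel


def transcribed_window(
    genome: Mapping[str, str],
    chrom: str,
    position: int,
    strand: str,
    rel_start: int,
    rel_stop: int,
) -> str | None:
    """Transcribed-strand bases at relative positions rel_start..rel_stop.

    Returns None when the window runs off the contig.
    """
    seq = genome[chrom]
    if strand == "+":
        g0, g1 = position + rel_start, position + rel_stop
        if g0 < 1 or g1 > len(seq):
            return None
        return seq[g0 - 1 : g1]
    g0, g1 = position - rel_stop, position - rel_start
    if g0 < 1 or g1 > len(seq):
        return None
    return revcomp(seq[g0 - 1 : g1])


def site_hexamer(genome: Mapping[str, str], chrom: str, position: int,
                 strand: str, site_type: str, k: int = 6) -> str | None:
    """The intron-anchored k-mer of a site (donor GT[N]k-2, acceptor [N]k-2AG)."""
    if site_type == DONOR:
        return transcribed_window(genome, chrom, position, strand, 0, k - 1)
    return transcribed_window(genome, chrom, position, strand, -(k - 1), 0)
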