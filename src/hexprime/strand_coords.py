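"""Strand classification and synthesis-coordinate conversion.

In a standard (non-strand-specific) random-hexamer library, reads that map
in reverse orientation to a sense-strand reference were sequenced from
first-strand cDNA — the strand reverse-transcribed directly on the RNA —
while forward-mapping reads come from second-strand cDNA.  For error
profiling, each read base is re-expressed in *synthesis coordinates*:
position 1 is the 5' end of the synthesized strand (the hexamer priming
site; positions 1-6 are the hexamer footprint, position 7 the first
extension base), the template base is what the polymerase copied from (RNA
for first strand, first-strand cDNA for second strand) and the incorporated
base is what physically ended up in the sequenced strand.  A mismatch
against the reference then reads directly as a template x incorporated
mispair, e.g. rU-dG for an RNA uracil template opposite an incorporated
DNA guanine.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from . import _bases
from .alignment_io import AlignedColumn, AlignedRead

__all__ = [
    "StrandClass",
    "SynthesisBase",
    "MispairClass",
    "classify_strand",
    "to_synthesis_coords",
    "mispair_of",
    "all_mispair_classes",
    "synthesis_arrays",
]


class StrandClass(Enum):
    """First- vs second-strand cDNA, inferred from mapping orientation."""

    FIRST_STRAND = "first_strand"
    SECOND_STRAND = "second_strand"

    @property
    def template_alphabet(self) -> str:
        """RNA bases for first strand (RNA template), DNA for second."""
        return "ACGU" if self is StrandClass.FIRST_STRAND else "ACGT"

    @property
    def prefix(self) -> str:
        return "r" if self is StrandClass.FIRST_STRAND else "d"


def classify_strand(read: AlignedRead) -> StrandClass:
    """Reverse-mapping reads are first-strand cDNA, forward second-strand."""
    if not read.is_mapped:
        raise ValueError(f"read {read.qname!r} is unmapped and has no orientation")
    return StrandClass.FIRST_STRAND if read.is_reverse else StrandClass.SECOND_STRAND


@dataclass(frozen=True)
class SynthesisBase:
    """One read base in synthesis coordinates.

    ``position`` counts 1-based from the raw read's 5' end (the priming
    site).  ``template_base`` is in RNA space (A,C,G,U) for first-strand
    reads and DNA space for second-strand reads; ``incorporated_base`` is
    always the DNA base present in the sequenced strand.
    """

    strand: StrandClass
    position: int
    template_base: str
    incorporated_base: str
    base_qual: int
    ref_pos: int

    @property
    def is_match(self) -> bool:
        return self.incorporated_base == _bases.complement_base(self.template_base)


@dataclass(frozen=True)
class MispairClass:
    """A template x incorporated non-complementary pairing.

    There are exactly 12 classes per strand (4 templates x 3 incorporated
    bases that are not the Watson-Crick partner); rendered "rX-dY" for
    first-strand (RNA-DNA) pairs and "dX-dY" for second-strand pairs.
    """

    strand: StrandClass
    template_base: str
    incorporated_base: str

    def __post_init__(self) -> None:
        if self.incorporated_base == _bases.complement_base(self.template_base):
            raise ValueError(
                f"{self.template_base}-{self.incorporated_base} is a "
                "complementary pair, not a mispair"
            )

    @property
    def label(self) -> str:
        return f"{self.strand.prefix}{self.template_base}-d{self.incorporated_base}"


def all_mispair_classes(strand: StrandClass) -> list[MispairClass]:
    """The 12 mispair classes in canonical (template, incorporated) order."""
    out = []
    for t in strand.template_alphabet:
        for i in "ACGT":
            if i != _bases.complement_base(t):
                out.append(MispairClass(strand, t, i))
    return out


def mispair_of(base: SynthesisBase) -> MispairClass | None:
    """The mispair class of a synthesis base, or None for a match."""
    if base.is_match:
        return None
    return MispairClass(base.strand, base.template_base, base.incorporated_base)


def to_synthesis_coords(
    read: AlignedRead, columns: Sequence[AlignedColumn]
) -> list[SynthesisBase]:
    """Convert aligned columns of one read into synthesis coordinates.

    Second-strand (forward) reads keep their query position; first-strand
    (reverse) reads are flipped, position = L - query_pos + 1 over the full
    query length L, because the raw read is the reverse complement of the
    SAM-orientation sequence.  Any soft clip at the 5' end is subtracted so
    position 1 is the first observed synthesized base (with the default
    filters, 5'-clipped reads never reach this point).  Template and
    incorporated bases:

    * second strand: template = complement(ref base) (the first-strand cDNA
      the polymerase copied), incorporated = query base;
    * first strand: template = ref base with T read as U (the reference
      forward strand is the transcript sense strand), incorporated =
      complement(query base).

    Columns containing N in either base are dropped; output is sorted by
    ascending synthesis position.
    """
    strand = classify_strand(read)
    L = read.query_length()
    clip5 = read.soft_clip5_length()
    out = []
    for col in columns:
        if col.ref_base == "N" or col.query_base == "N":
            continue
        if strand is StrandClass.SECOND_STRAND:
            position = col.query_pos_samdir - clip5
            template = _bases.complement_base(col.ref_base)
            incorporated = col.query_base
        else:
            position = (L - col.query_pos_samdir + 1) - clip5
            template = "U" if col.ref_base == "T" else col.ref_base
            incorporated = _bases.complement_base(col.query_base)
        out.append(
            SynthesisBase(
                strand=strand,
                position=position,
                template_base=template,
                incorporated_base=incorporated,
                base_qual=col.base_qual,
                ref_pos=col.ref_pos,
            )
        )
    out.sort(key=lambda b: b.position)
    return out


def synthesis_bases_to_tsv(read_bases, path) -> None:
    """Debug dump of synthesis-coordinate streams, one row per base.

    ``read_bases`` yields ``(AlignedRead, list[SynthesisBase])`` pairs.
    """
    with open(path, "w") as fh:
        fh.write("qname\tstrand\tposition\ttemplate\tincorporated\tqual\n")
        for read, bases in read_bases:
            for b in bases:
                fh.write(
                    f"{read.qname}\t{b.strand.value}\t{b.position}\t"
                    f"{b.template_base}\t{b.incorporated_base}\t{b.base_qual}\n"
                )


def synthesis_arrays(
    read: AlignedRead,
    q_idx: np.ndarray,
    ref_pos: np.ndarray,
    q_codes: np.ndarray,
    r_codes: np.ndarray,
) -> tuple[StrandClass, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised synthesis-coordinate transform over aligned-column arrays.

    Input arrays are the output of :func:`hexprime.alignment_io.aligned_arrays`.
    Returns ``(strand, positions, template_codes, incorporated_codes)`` with
    N-containing columns removed.  Template codes use A=0,C=1,G=2,(T|U)=3;
    first-strand template code 3 denotes uracil.
    """
    strand = classify_strand(read)
    keep = (q_codes < 4) & (r_codes < 4)
    q_idx = q_idx[keep]
    q = q_codes[keep].astype(np.int64)
    r = r_codes[keep].astype(np.int64)
    clip5 = read.soft_clip5_length()
    if strand is StrandClass.SECOND_STRAND:
        positions = q_idx + 1 - clip5
        template = 3 - r
        incorporated = q
    else:
        positions = read.query_length() - q_idx - clip5
        template = r
        incorporated = 3 - q
    return strand, positions, template, incorporated
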