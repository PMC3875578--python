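"""Reference FASTA and SAM alignment input, per-base column reconstruction.

This module turns aligned reads back into per-base read-vs-reference
columns.  Reference bases are recovered either from the alignment's MD tag
(reference-free, the route a profiling script takes on a mapped BAM/SAM) or
by direct lookup in the reference FASTA; when both are available they are
cross-checked and any disagreement is treated as corrupt input.

SAM text is the canonical alignment format here.  Lines with malformed
mandatory fields are skipped individually and counted in a rejects log
rather than aborting the run; BAM input is supported through pysam.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
from Bio import SeqIO

from . import _bases
from ._bases import encode

__all__ = [
    "ReferenceSet",
    "AlignedRead",
    "AlignedColumn",
    "FilterConfig",
    "FilterStats",
    "SamFormatError",
    "MdError",
    "load_references",
    "parse_sam",
    "write_sam",
    "reconstruct_columns",
    "aligned_arrays",
    "filter_reads",
]

_VALID_REF_RE = re.compile(r"^[ACGTN]+$")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_MD_RE = re.compile(r"(\d+)|(\^[ACGTN]+)|([ACGTN])")
_MD_WELLFORMED_RE = re.compile(r"^\d+(?:(?:[ACGTN]|\^[ACGTN]+)\d+)*$")

QUERY_CONSUMING = frozenset("MIS=X")
REF_CONSUMING = frozenset("MDN=X")
ALIGN_OPS = frozenset("M=X")


class SamFormatError(ValueError):
    """A SAM record violates the format (malformed mandatory field)."""


class MdError(ValueError):
    """MD tag inconsistent with the CIGAR/sequence or the reference."""


class ReferenceSet:
    """Known reference sequences keyed by id (e.g. the ERCC spike set).

    Sequences are uppercase DNA over {A,C,G,T,N}; ids are unique and
    non-empty.  Encoded arrays are cached for fast per-read slicing.
    """

    def __init__(self, entries: dict[str, str]):
        if not entries:
            raise ValueError("reference set is empty")
        self.entries: dict[str, str] = {}
        self._codes: dict[str, np.ndarray] = {}
        for rid, seq in entries.items():
            if not rid:
                raise ValueError("empty reference id")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"reference {rid!r} has empty sequence")
            if not _VALID_REF_RE.match(seq):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ValueError(f"reference {rid!r} contains invalid characters {bad}")
            self.entries[rid] = seq
            self._codes[rid] = encode(seq)

    def __getitem__(self, rid: str) -> str:
        return self.entries[rid]

    def __contains__(self, rid: str) -> bool:
        return rid in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def codes(self, rid: str) -> np.ndarray:
        """Encoded sequence (A=0,C=1,G=2,T=3,N=4) for one reference."""
        return self._codes[rid]

    def lengths(self) -> dict[str, int]:
        return {rid: len(seq) for rid, seq in self.entries.items()}

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.entries.items():
                fh.write(f">{rid}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def load_references(path: str | Path) -> ReferenceSet:
    """Load a FASTA file into a :class:`ReferenceSet`.

    The header token up to the first whitespace is the reference id.
    Duplicate ids and empty files are hard errors.
    """
    entries: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in entries:
            raise ValueError(f"duplicate reference id {rid!r} in {path}")
        entries[rid] = str(rec.seq).upper()
    if not entries:
        raise ValueError(f"no FASTA records found in {path}")
    return ReferenceSet(entries)


@dataclass
class AlignedRead:
    """One parsed SAM record with decomposed flags, CIGAR, MD and NM.

    ``seq`` is stored in reference-forward orientation exactly as in the
    SAM file; ``ref_start`` is the 1-based leftmost aligned reference
    coordinate.  ``qual`` keeps the raw SAM QUAL string ("*" allowed).
    """

    qname: str
    flag: int
    reference_id: str
    ref_start: int
    mapq: int
    cigar: list[tuple[str, int]]
    rnext: str
    pnext: int
    tlen: int
    seq: str
    qual: str
    md: str | None = None
    nm: int | None = None
    line_number: int | None = None

    # -- flag decomposition (SAM spec bit meanings) --
    @property
    def is_paired(self) -> bool:
        return bool(self.flag & 0x1)

    @property
    def is_proper_pair(self) -> bool:
        return bool(self.flag & 0x2)

    @property
    def is_mapped(self) -> bool:
        return not self.flag & 0x4

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & 0x10)

    @property
    def is_secondary_or_supplementary(self) -> bool:
        return bool(self.flag & 0x100 or self.flag & 0x800)

    @property
    def mate_index(self) -> int:
        return 2 if (self.flag & 0x80 and not self.flag & 0x40) else 1

    def base_qualities(self) -> np.ndarray:
        """Phred scores per base; 255 (i.e. "unknown") when QUAL is '*'."""
        if self.qual == "*" or not self.qual:
            return np.full(len(self.seq), 255, dtype=np.int16)
        return (
            np.frombuffer(self.qual.encode("ascii"), dtype=np.uint8).astype(np.int16)
            - 33
        )

    def query_length(self) -> int:
        return len(self.seq)

    def cigar_string(self) -> str:
        if not self.cigar:
            return "*"
        return "".join(f"{ln}{op}" for op, ln in self.cigar)

    def clip5_length(self) -> int:
        """Soft/hard clip length at the synthesis-start (5') end of the read.

        The 5' end of the sequenced strand is the leading CIGAR end for
        forward reads and the trailing end for reverse reads.
        """
        ops = self.cigar if not self.is_reverse else self.cigar[::-1]
        n = 0
        for op, ln in ops:
            if op in "SH":
                n += ln
            else:
                break
        return n

    def soft_clip5_length(self) -> int:
        """Like :meth:`clip5_length` but counting soft clips only."""
        ops = self.cigar if not self.is_reverse else self.cigar[::-1]
        n = 0
        for op, ln in ops:
            if op == "H":
                continue
            if op == "S":
                n += ln
            break
        return n

    def to_sam_line(self) -> str:
        """Re-serialise as one SAM line (NM then MD among optional tags)."""
        cols = [
            self.qname,
            str(self.flag),
            self.reference_id,
            str(self.ref_start),
            str(self.mapq),
            self.cigar_string(),
            self.rnext,
            str(self.pnext),
            str(self.tlen),
            self.seq or "*",
            self.qual or "*",
        ]
        if self.nm is not None:
            cols.append(f"NM:i:{self.nm}")
        if self.md is not None:
            cols.append(f"MD:Z:{self.md}")
        return "\t".join(cols)


@dataclass(frozen=True)
class AlignedColumn:
    """One aligned read base against its reference base.

    ``query_pos_samdir`` is the 1-based index into the SAM-orientation
    ``seq``; soft-clipped and inserted bases yield no column.
    """

    query_pos_samdir: int
    ref_pos: int
    ref_base: str
    query_base: str
    base_qual: int
    is_mismatch: bool


def _parse_cigar(text: str) -> list[tuple[str, int]]:
    if text == "*":
        return []
    out = []
    pos = 0
    for m in _CIGAR_RE.finditer(text):
        if m.start() != pos:
            raise SamFormatError(f"malformed CIGAR {text!r}")
        out.append((m.group(2), int(m.group(1))))
        pos = m.end()
    if pos != len(text) or not out:
        raise SamFormatError(f"malformed CIGAR {text!r}")
    return out


def _parse_sam_line(line: str, line_number: int) -> AlignedRead:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 11:
        raise SamFormatError(f"{len(cols)} fields (11 required)")
    qname, flag_s, rname, pos_s, mapq_s, cigar_s, rnext, pnext_s, tlen_s = cols[:9]
    seq, qual = cols[9], cols[10]
    try:
        flag = int(flag_s)
        pos = int(pos_s)
        mapq = int(mapq_s)
        pnext = int(pnext_s)
        tlen = int(tlen_s)
    except ValueError as exc:
        raise SamFormatError(f"non-integer mandatory field: {exc}") from None
    if flag < 0 or pos < 0:
        raise SamFormatError("negative FLAG or POS")
    cigar = _parse_cigar(cigar_s)
    if seq == "*":
        seq = ""
    if seq and cigar:
        qlen = sum(ln for op, ln in cigar if op in QUERY_CONSUMING)
        if qlen != len(seq):
            raise SamFormatError(
                f"CIGAR consumes {qlen} query bases but SEQ has {len(seq)}"
            )
    md: str | None = None
    nm: int | None = None
    for tag in cols[11:]:
        if tag.startswith("MD:Z:"):
            md = tag[5:]
            if not _MD_WELLFORMED_RE.match(md):
                raise SamFormatError(f"malformed MD tag {md!r}")
        elif tag.startswith("NM:i:"):
            try:
                nm = int(tag[5:])
            except ValueError:
                raise SamFormatError(f"malformed NM tag {tag!r}") from None
    return AlignedRead(
        qname=qname,
        flag=flag,
        reference_id=rname,
        ref_start=pos,
        mapq=mapq,
        cigar=cigar,
        rnext=rnext,
        pnext=pnext,
        tlen=tlen,
        seq=seq,
        qual=qual,
        md=md,
        nm=nm,
        line_number=line_number,
    )


_PYSAM_CIGAR_OPS = "MIDNSHP=X"


def _from_pysam(seg) -> AlignedRead:
    cigar = [(_PYSAM_CIGAR_OPS[op], ln) for op, ln in (seg.cigartuples or [])]
    qual = seg.qual if seg.qual is not None else "*"
    return AlignedRead(
        qname=seg.query_name,
        flag=seg.flag,
        reference_id=seg.reference_name or "*",
        ref_start=(seg.reference_start + 1) if seg.reference_start is not None else 0,
        mapq=seg.mapping_quality,
        cigar=cigar,
        rnext="*" if seg.next_reference_name is None else seg.next_reference_name,
        pnext=(seg.next_reference_start + 1) if seg.next_reference_start >= 0 else 0,
        tlen=seg.template_length,
        seq=seg.query_sequence or "",
        qual=qual,
        md=seg.get_tag("MD") if seg.has_tag("MD") else None,
        nm=int(seg.get_tag("NM")) if seg.has_tag("NM") else None,
    )


def parse_sam(
    source: str | Path | IO[str] | Iterable[str],
    *,
    on_error: str = "skip",
    rejects: list | None = None,
) -> Iterator[AlignedRead]:
    """Iterate :class:`AlignedRead` records from SAM text (or a BAM file).

    Parameters
    ----------
    source
        Path to a ``.sam`` (or ``.bam``, read via pysam) file, an open
        text stream, or any iterable of SAM lines.
    on_error
        ``"skip"`` (default) records malformed lines in ``rejects`` as
        ``(line_number, message)`` and continues; ``"raise"`` aborts.
    rejects
        Optional list collecting the rejects log.
    """
    if on_error not in ("skip", "raise"):
        raise ValueError("on_error must be 'skip' or 'raise'")
    if isinstance(source, (str, Path)) and str(source).endswith(".bam"):
        import pysam

        with pysam.AlignmentFile(str(source), "rb", check_sq=False) as bam:
            for seg in bam:
                yield _from_pysam(seg)
        return

    if isinstance(source, (str, Path)):
        fh: Iterable[str] = open(source)
        close = True
    else:
        fh = source
        close = False
    try:
        for line_number, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("@"):
                continue
            try:
                yield _parse_sam_line(line, line_number)
            except SamFormatError as exc:
                if on_error == "raise":
                    raise SamFormatError(f"line {line_number}: {exc}") from None
                if rejects is not None:
                    rejects.append((line_number, str(exc)))
    finally:
        if close:
            fh.close()  # type: ignore[union-attr]


def write_sam(
    reads: Iterable[AlignedRead],
    path: str | Path,
    references: ReferenceSet | dict[str, int] | None = None,
) -> None:
    """Write reads as SAM text with an @SQ header derived from references."""
    lengths = (
        references.lengths() if isinstance(references, ReferenceSet) else references
    )
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        if lengths:
            for rid, ln in lengths.items():
                fh.write(f"@SQ\tSN:{rid}\tLN:{ln}\n")
        for read in reads:
            fh.write(read.to_sam_line() + "\n")


# ---------------------------------------------------------------------------
# Column reconstruction
# ---------------------------------------------------------------------------


def _aligned_segments(read: AlignedRead) -> list[tuple[int, int, int]]:
    """(query0, ref0, length) for each M/=/X CIGAR segment (0-based)."""
    segs = []
    q = 0
    r = read.ref_start - 1
    for op, ln in read.cigar:
        if op in ALIGN_OPS:
            segs.append((q, r, ln))
            q += ln
            r += ln
        elif op in ("I", "S"):
            q += ln
        elif op in ("D", "N"):
            r += ln
        # H, P consume nothing
    return segs


def _md_ref_codes(read: AlignedRead, q_idx: np.ndarray, q_codes: np.ndarray) -> np.ndarray:
    """Reconstruct aligned-column reference codes from the MD tag.

    MD match-run numbers count aligned (M/=/X) columns; deletion runs
    (``^...``) consume no column.  The tag must land exactly on the number
    of aligned columns or the input is inconsistent.
    """
    r_codes = q_codes.copy()
    n = len(q_idx)
    cursor = 0
    for m in _MD_RE.finditer(read.md or ""):
        if m.group(1) is not None:
            cursor += int(m.group(1))
        elif m.group(3) is not None:
            if cursor >= n:
                raise MdError(f"MD tag runs off the read for {read.qname!r}")
            r_codes[cursor] = _bases.ENCODE[ord(m.group(3))]
            cursor += 1
        # deletion group: no aligned column consumed
    if cursor != n:
        raise MdError(
            f"MD tag covers {cursor} aligned bases but CIGAR has {n} "
            f"for {read.qname!r}"
        )
    return r_codes


def aligned_arrays(
    read: AlignedRead, refs: ReferenceSet | None = None, *, prefer: str = "auto"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised column reconstruction.

    Returns ``(query_idx0, ref_pos, query_codes, ref_codes)`` over the
    aligned (M/=/X) columns, in read order.  ``query_idx0`` is 0-based into
    ``read.seq``; ``ref_pos`` is 1-based.  ``prefer`` selects the reference
    base source: ``"md"``, ``"refs"`` or ``"auto"`` (MD when present, with
    a cross-check against ``refs`` whenever both are available).
    """
    if not read.is_mapped:
        raise ValueError(f"read {read.qname!r} is unmapped")
    if not read.cigar:
        raise ValueError(f"read {read.qname!r} has no CIGAR")
    segs = _aligned_segments(read)
    if not segs:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, empty.astype(np.uint8), empty.astype(np.uint8)
    q_idx = np.concatenate([np.arange(q, q + ln) for q, _, ln in segs])
    ref_pos = np.concatenate([np.arange(r + 1, r + 1 + ln) for _, r, ln in segs])
    q_codes = encode(read.seq)[q_idx]

    use_md = read.md is not None and prefer in ("auto", "md")
    use_ref = refs is not None and read.reference_id in refs and prefer in ("auto", "refs")
    if prefer == "md" and read.md is None:
        raise ValueError(f"read {read.qname!r} has no MD tag")
    if prefer == "refs" and not use_ref:
        raise ValueError(f"reference {read.reference_id!r} not available")
    if not use_md and not use_ref:
        raise ValueError(
            f"read {read.qname!r}: no MD tag and reference "
            f"{read.reference_id!r} not in the reference set"
        )

    r_md = _md_ref_codes(read, q_idx, q_codes) if use_md else None
    r_ref = None
    if use_ref:
        codes = refs.codes(read.reference_id)
        if ref_pos[-1] > len(codes):
            raise ValueError(
                f"read {read.qname!r} aligns past the end of {read.reference_id!r}"
            )
        r_ref = codes[ref_pos - 1]
    if r_md is not None and r_ref is not None and not np.array_equal(r_md, r_ref):
        raise MdError(
            f"MD tag disagrees with the reference sequence for {read.qname!r}"
        )
    r_codes = r_md if r_md is not None else r_ref
    return q_idx, ref_pos, q_codes, r_codes


def reconstruct_columns(
    read: AlignedRead, refs: ReferenceSet | None = None, *, prefer: str = "auto"
) -> list[AlignedColumn]:
    """Per-base read-vs-reference columns for one mapped read.

    One column per aligned (M/=/X) base; insertions, soft clips and
    deletions yield no column.  A base pair counts as a mismatch only when
    the bases differ and neither is N.
    """
    q_idx, ref_pos, q_codes, r_codes = aligned_arrays(read, refs, prefer=prefer)
    quals = read.base_qualities()
    cols = []
    for qi, rp, qc, rc in zip(q_idx, ref_pos, q_codes, r_codes):
        mism = bool(qc != rc) and qc != _bases.N and rc != _bases.N
        cols.append(
            AlignedColumn(
                query_pos_samdir=int(qi) + 1,
                ref_pos=int(rp),
                ref_base=_bases.DECODE_DNA[rc : rc + 1].tobytes().decode(),
                query_base=_bases.DECODE_DNA[qc : qc + 1].tobytes().decode(),
                base_qual=int(quals[qi]),
                is_mismatch=mism,
            )
        )
    return cols


# ---------------------------------------------------------------------------
# Read-level filters
# ---------------------------------------------------------------------------


@dataclass
class FilterConfig:
    """Read-level filters applied before profiling.

    Pairs whose insert size falls outside ``[min_insert, max_insert]`` are
    excluded: inserts at or below the read length imply the read runs into
    the 3' adapter, whose bases would be scored as spurious mismatches.
    Reads soft-clipped at the 5' (synthesis-start) end are dropped because
    the priming site itself was not observed.
    """

    require_paired: bool = True
    require_proper_pair: bool = True
    min_insert: int = 101
    max_insert: int = 1000
    drop_secondary: bool = True
    drop_5prime_softclip: bool = True
    min_base_quality: int = 0

    def __post_init__(self) -> None:
        if self.min_insert > self.max_insert:
            raise ValueError("min_insert must be <= max_insert")
        if self.min_base_quality < 0:
            raise ValueError("min_base_quality must be >= 0")

    @classmethod
    def for_read_length(cls, read_length: int, **kw) -> "FilterConfig":
        kw.setdefault("min_insert", read_length + 1)
        return cls(**kw)


REJECT_REASONS = (
    "unmapped",
    "secondary_or_supplementary",
    "unpaired",
    "not_proper_pair",
    "insert_size",
    "5prime_clip",
)


@dataclass
class FilterStats:
    """Counts per rejection reason; conservation: n_in = n_out + sum(rejected)."""

    n_in: int = 0
    n_out: int = 0
    rejected: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: str) -> None:
        self.rejected[reason] = self.rejected.get(reason, 0) + 1

    def total_rejected(self) -> int:
        return sum(self.rejected.values())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("reason\tcount\n")
            for reason in REJECT_REASONS:
                fh.write(f"{reason}\t{self.rejected.get(reason, 0)}\n")
            fh.write(f"passed\t{self.n_out}\n")


def filter_reads(
    reads: Iterable[AlignedRead],
    cfg: FilterConfig | None = None,
    stats: FilterStats | None = None,
) -> Iterator[AlignedRead]:
    """Yield reads passing the configured filters, tallying rejections.

    Filtering is total: every input read is either emitted or counted
    under exactly one rejection reason (the first that applies).
    """
    if cfg is None:
        cfg = FilterConfig()
    if stats is None:
        stats = FilterStats()
    for read in reads:
        stats.n_in += 1
        if not read.is_mapped:
            stats.reject("unmapped")
            continue
        if cfg.drop_secondary and read.is_secondary_or_supplementary:
            stats.reject("secondary_or_supplementary")
            continue
        if cfg.require_paired and not read.is_paired:
            stats.reject("unpaired")
            continue
        if cfg.require_proper_pair and read.is_paired and not read.is_proper_pair:
            stats.reject("not_proper_pair")
            continue
        if read.is_paired and not (cfg.min_insert <= abs(read.tlen) <= cfg.max_insert):
            stats.reject("insert_size")
            continue
        if cfg.drop_5prime_softclip and read.clip5_length() > 0:
            stats.reject("5prime_clip")
            continue
        stats.n_out += 1
        yield read
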