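"""FASTA/SAM input, MD-based column reconstruction, read filters."""
from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hexprime as hx
from hexprime.alignment_io import (
    MdError,
    SamFormatError,
    aligned_arrays,
    parse_sam,
    reconstruct_columns,
)
from hexprime.synthetic_data import _md_string

from conftest import make_read


class TestLoadReferences:
    def test_single_record(self, tmp_path):
        p = tmp_path / "one.fa"
        p.write_text(">ERCC-0001\nACGT\n")
        refs = hx.load_references(p)
        assert refs.entries == {"ERCC-0001": "ACGT"}

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "dup.fa"
        p.write_text(">a\nACGT\n>a\nGGGG\n")
        with pytest.raises(ValueError, match="duplicate"):
            hx.load_references(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(ValueError, match="no FASTA"):
            hx.load_references(p)

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="invalid characters"):
            hx.ReferenceSet({"x": "ACGTX"})

    def test_simulator_roundtrip_identity(self, small_refs, tmp_path):
        """Write-then-read of a simulated reference set is the identity."""
        p = tmp_path / "refs.fa"
        small_refs.to_fasta(p)
        again = hx.load_references(p)
        assert again.entries == small_refs.entries


class TestParseSam:
    def test_flag_decoding_reverse(self):
        r = make_read(flag=16)
        assert r.is_reverse and r.is_mapped and not r.is_paired

    def test_flag_decoding_unmapped(self):
        r = make_read(flag=4)
        assert not r.is_mapped

    def test_flag_decoding_pair_bits(self):
        r = make_read(flag=99)
        assert r.is_paired and r.is_proper_pair and r.mate_index == 1
        assert make_read(flag=147).mate_index == 2
        assert make_read(flag=0x100).is_secondary_or_supplementary
        assert make_read(flag=0x800).is_secondary_or_supplementary

    def test_malformed_line_goes_to_rejects_log(self):
        lines = [
            "@HD\tVN:1.6",
            "ok\t0\tR\t1\t60\t4M\t*\t0\t0\tACGT\tIIII",
            "bad\t0\tR\tnotanint\t60\t4M\t*\t0\t0\tACGT\tIIII",
            "short\t0\tR",
            "badcigar\t0\tR\t1\t60\t5M\t*\t0\t0\tACGT\tIIII",
        ]
        rejects = []
        reads = list(parse_sam(lines, rejects=rejects))
        assert [r.qname for r in reads] == ["ok"]
        assert [ln for ln, _ in rejects] == [3, 4, 5]

    def test_on_error_raise(self):
        with pytest.raises(SamFormatError, match="line 1"):
            list(parse_sam(["oops\t0\tR"], on_error="raise"))

    def test_simulator_file_parses_with_zero_rejects(self, small_sim):
        rejects = []
        reads = list(parse_sam(small_sim["sam"], rejects=rejects))
        assert len(reads) == 2 * small_sim["cfg"].n_read_pairs
        assert rejects == []

    def test_reserialization_preserves_fields(self, small_sim):
        """FLAG, POS, CIGAR, MD, NM survive a parse/serialise round-trip."""
        with open(small_sim["sam"]) as fh:
            originals = [ln.rstrip("\n") for ln in fh if not ln.startswith("@")]
        reads = list(parse_sam(small_sim["sam"]))
        for orig, read in zip(originals[:500], reads):
            assert read.to_sam_line() == orig


class TestReconstructColumns:
    def test_perfect_match(self):
        r = make_read(seq="ACGT", cigar="4M", md="4")
        cols = reconstruct_columns(r)
        assert len(cols) == 4
        assert not any(c.is_mismatch for c in cols)
        assert [c.ref_pos for c in cols] == [1, 2, 3, 4]

    def test_single_mismatch_md(self):
        r = make_read(seq="ACGT", cigar="4M", md="2T1")
        cols = reconstruct_columns(r)
        mism = [c for c in cols if c.is_mismatch]
        assert len(mism) == 1
        col = mism[0]
        assert (col.query_pos_samdir, col.ref_base, col.query_base) == (3, "T", "G")
        # oracle: direct comparison against the explicit reference ACTT
        refs = hx.ReferenceSet({"R": "ACTT"})
        assert reconstruct_columns(r, refs, prefer="refs") == cols

    def test_soft_clip_skipped(self):
        r = make_read(seq="AACCGGTT", cigar="2S6M", md="6")
        cols = reconstruct_columns(r)
        assert [c.query_pos_samdir for c in cols] == [3, 4, 5, 6, 7, 8]
        refs = hx.ReferenceSet({"R": "CCGGTT"})
        assert reconstruct_columns(r, refs, prefer="refs") == cols

    def test_insertion_yields_no_column(self):
        r = make_read(seq="ACGTACGT", cigar="3M2I3M", md="6")
        cols = reconstruct_columns(r)
        assert [c.query_pos_samdir for c in cols] == [1, 2, 3, 6, 7, 8]
        assert [c.ref_pos for c in cols] == [1, 2, 3, 4, 5, 6]

    def test_deletion_yields_no_column(self):
        r = make_read(seq="ACGGGG", cigar="3M2D3M", md="3^CA3")
        cols = reconstruct_columns(r)
        assert [c.ref_pos for c in cols] == [1, 2, 3, 6, 7, 8]
        assert not any(c.is_mismatch for c in cols)

    def test_md_running_off_read_is_error(self):
        r = make_read(seq="ACGT", cigar="4M", md="4T1")
        with pytest.raises(MdError, match="r1"):
            reconstruct_columns(r)

    def test_md_reference_disagreement_is_error(self):
        r = make_read(seq="ACGT", cigar="4M", md="4")
        refs = hx.ReferenceSet({"R": "ACTT"})
        with pytest.raises(MdError, match="disagrees"):
            reconstruct_columns(r, refs)

    def test_n_bases_never_count_as_mismatch(self):
        r = make_read(seq="ANGT", cigar="4M", md="1C2")
        cols = reconstruct_columns(r)
        assert [c.is_mismatch for c in cols] == [False, False, False, False]

    @given(
        ref=st.text(alphabet="ACGT", min_size=20, max_size=60),
        errs=st.lists(
            st.tuples(st.integers(0, 59), st.integers(1, 3)), max_size=6
        ),
    )
    def test_md_reconstruction_matches_direct_comparison(self, ref, errs):
        """Fuzz: MD built from a mutated read always reconstructs the reference."""
        codes = np.frombuffer(ref.encode(), dtype=np.uint8).copy()
        enc = {65: 0, 67: 1, 71: 2, 84: 3}
        dec = "ACGT"
        ref_codes = np.array([enc[c] for c in codes])
        read_codes = ref_codes.copy()
        for pos, shift in errs:
            if pos < len(read_codes):
                read_codes[pos] = (read_codes[pos] + shift) % 4
        md, nm = _md_string(read_codes, ref_codes)
        seq = "".join(dec[c] for c in read_codes)
        r = make_read(seq=seq, cigar=f"{len(seq)}M", md=md, nm=nm)
        refs = hx.ReferenceSet({"R": ref})
        _, _, _, r_md = aligned_arrays(r, prefer="md")
        _, _, _, r_ref = aligned_arrays(r, refs, prefer="refs")
        assert np.array_equal(r_md, r_ref)
        cols = reconstruct_columns(r, refs)
        assert sum(c.is_mismatch for c in cols) == nm

    def test_mismatch_count_equals_nm_minus_indels(self, small_sim):
        reads = itertools.islice(parse_sam(small_sim["sam"]), 500)
        for r in reads:
            cols = reconstruct_columns(r, small_sim["refs"])
            assert sum(c.is_mismatch for c in cols) == r.nm

    def test_pysam_oracle_agreement(self, small_sim):
        """Independent oracle: pysam's MD-based aligned pairs give the same
        mismatch positions and reference bases as our reconstruction."""
        pysam = pytest.importorskip("pysam")
        ours = {}
        for r in itertools.islice(parse_sam(small_sim["sam"]), 300):
            cols = reconstruct_columns(r, small_sim["refs"])
            key = (r.qname, r.flag)
            ours[key] = [
                (c.query_pos_samdir - 1, c.ref_pos - 1, c.ref_base)
                for c in cols
                if c.is_mismatch
            ]
        with pysam.AlignmentFile(str(small_sim["sam"]), "r", check_sq=False) as sam:
            for seg, key in zip(sam, list(ours)):
                theirs = [
                    (q, rp, rb.upper())
                    for q, rp, rb in seg.get_aligned_pairs(with_seq=True)
                    if q is not None and rp is not None and rb.islower()
                ]
                assert theirs == ours[(seg.query_name, seg.flag)]


class TestFilterReads:
    @pytest.mark.parametrize(
        "read,reason",
        [
            (make_read(flag=4), "unmapped"),
            (make_read(flag=0x100), "secondary_or_supplementary"),
            (make_read(flag=0), "unpaired"),
            (make_read(flag=1), "not_proper_pair"),
            (make_read(flag=99, tlen=50), "insert_size"),
            (make_read(flag=99, tlen=2000), "insert_size"),
            (make_read(flag=99, seq="AAACGT", cigar="3S3M", tlen=200), "5prime_clip"),
        ],
    )
    def test_rejection_reasons(self, read, reason):
        stats = hx.FilterStats()
        out = list(hx.filter_reads([read], hx.FilterConfig(), stats))
        assert out == []
        assert stats.rejected == {reason: 1}

    def test_reverse_read_5prime_clip_is_trailing(self):
        """The 5' end of a reverse read is the right-hand CIGAR end."""
        fwd_trailing = make_read(flag=99, seq="ACGTAA", cigar="4M2S", tlen=200)
        rev_trailing = make_read(flag=147, seq="ACGTAA", cigar="4M2S", tlen=-200)
        rev_leading = make_read(flag=147, seq="AAACGT", cigar="2S4M", tlen=-200)
        stats = hx.FilterStats()
        out = list(
            hx.filter_reads([fwd_trailing, rev_trailing, rev_leading],
                            hx.FilterConfig(), stats)
        )
        assert [r.flag for r in out] == [99, 147]
        assert out[1].cigar_string() == "2S4M"
        assert stats.rejected == {"5prime_clip": 1}

    def test_conservation(self, small_sim):
        """Input count equals output count plus the sum of rejections."""
        stats = hx.FilterStats()
        cfg = hx.FilterConfig(min_insert=320)  # force insert-size rejections
        n_out = sum(1 for _ in hx.filter_reads(
            parse_sam(small_sim["sam"]), cfg, stats))
        assert stats.n_in == 2 * small_sim["cfg"].n_read_pairs
        assert stats.n_in == n_out + stats.total_rejected()
        assert stats.rejected.get("insert_size", 0) > 0

    def test_simulator_passes_default_filters(self, small_sim):
        stats = hx.FilterStats()
        n = sum(1 for _ in hx.filter_reads(
            parse_sam(small_sim["sam"]), hx.FilterConfig(), stats))
        assert n == stats.n_in and stats.rejected == {}

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            hx.FilterConfig(min_insert=10, max_insert=5)


def test_bam_input_matches_sam_input(small_sim, tmp_path):
    """Reading the same alignments through the BAM route gives identical
    records (BAM generated on the fly from the simulator SAM)."""
    pysam = pytest.importorskip("pysam")
    bam_path = tmp_path / "reads.bam"
    with pysam.AlignmentFile(str(small_sim["sam"]), "r") as sam_in:
        with pysam.AlignmentFile(str(bam_path), "wb", template=sam_in) as bam_out:
            for seg in sam_in:
                bam_out.write(seg)
    from_sam = list(parse_sam(small_sim["sam"]))
    from_bam = list(parse_sam(bam_path))
    assert len(from_bam) == len(from_sam)
    for a, b in zip(from_sam[:500], from_bam):
        assert (a.qname, a.flag, a.reference_id, a.ref_start) == (
            b.qname, b.flag, b.reference_id, b.ref_start)
        assert (a.cigar, a.seq, a.md, a.nm, a.tlen) == (
            b.cigar, b.seq, b.md, b.nm, b.tlen)


def test_md_only_equals_reference_only_small(small_sim):
    """Dual-route check: MD- and reference-based reconstruction agree."""
    for r in itertools.islice(parse_sam(small_sim["sam"]), 1000):
        _, _, _, r_md = aligned_arrays(r, prefer="md")
        _, _, _, r_ref = aligned_arrays(r, small_sim["refs"], prefer="refs")
        assert np.array_equal(r_md, r_ref)
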