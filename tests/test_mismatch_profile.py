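"""Profile accumulation, rates, distributions, headline statistics, TSV IO."""
from __future__ import annotations

import collections

import numpy as np
import pytest

import hexprime as hx
from hexprime.alignment_io import parse_sam
from hexprime.mismatch_profile import (
    headline_stats,
    mispair_distribution,
    per_template_distribution,
    position_mismatch_rate,
    profile_from_tsv,
    profile_to_tsv,
)
from hexprime.strand_coords import StrandClass
from hexprime.synthetic_data import uniform_mispriming

FIRST = StrandClass.FIRST_STRAND
SECOND = StrandClass.SECOND_STRAND


def sb(strand=FIRST, position=1, template="U", incorporated="A", qual=40, ref_pos=1):
    return hx.SynthesisBase(strand, position, template, incorporated, qual, ref_pos)


class TestAccumulate:
    def test_empty_stream(self):
        p = hx.accumulate([])
        assert position_mismatch_rate(p, FIRST, 1) is None
        assert mispair_distribution(p, FIRST, 1) is None
        s = headline_stats(p)
        assert s.at_start_rate_pos1 is None and s.stable_frac_pos2_6 is None

    def test_matching_bases_give_coverage_no_mismatches(self):
        bases = [sb(position=i, template="U", incorporated="A") for i in range(1, 11)]
        p = hx.accumulate(bases)
        total_cov = sum(int(p.coverage(FIRST, i).sum()) for i in range(1, 11))
        total_mm = sum(int(p.mismatch_counts(FIRST, i).sum()) for i in range(1, 11))
        assert (total_cov, total_mm) == (10, 0)

    def test_min_base_quality_excludes_entirely(self):
        bases = [sb(qual=10), sb(qual=30, incorporated="G")]
        p = hx.accumulate(bases, min_base_quality=20)
        assert int(p.coverage(FIRST, 1).sum()) == 1
        assert int(p.mismatch_counts(FIRST, 1).sum()) == 1

    def test_profile_counts_equal_truth_tallies(self, small_sim, small_profile):
        """Simulator run with a known event log: the profile's mismatch
        cells equal independent tallies of the truth log, cell by cell."""
        tally = collections.Counter(
            (t.strand, t.position, t.template_base, t.incorporated_base)
            for t in small_sim["truth"]
        )
        for strand in (FIRST, SECOND):
            for pos in range(1, 101):
                mm = small_profile.mismatch_counts(strand, pos)
                for t, letter in enumerate(strand.template_alphabet):
                    for i, inc in enumerate("ACGT"):
                        if i == 3 - t:
                            continue
                        assert mm[t, i] == tally.get((strand, pos, letter, inc), 0)


class TestPositionMismatchRate:
    def test_simple_fraction(self):
        bases = [sb(incorporated="A")] * 9 + [sb(incorporated="G")]
        p = hx.accumulate(bases)
        assert position_mismatch_rate(p, FIRST, 1) == pytest.approx(0.1)

    def test_template_subset(self):
        bases = [sb(template="U", incorporated="G"), sb(template="C", incorporated="G")]
        p = hx.accumulate(bases)
        assert position_mismatch_rate(p, FIRST, 1, templates=["U"]) == 1.0
        assert position_mismatch_rate(p, FIRST, 1, templates=["C"]) == 0.0

    def test_error_free_simulation_is_zero_everywhere(self, small_refs, tmp_path):
        model = hx.ErrorModel(
            first_strand=uniform_mispriming(0.0),
            second_strand=uniform_mispriming(0.0),
            background_error=0.0,
        )
        cfg = hx.LibraryConfig(n_read_pairs=300, references=small_refs, model=model)
        truth = hx.simulate_library(cfg, tmp_path / "clean.sam", seed=5)
        assert truth == []
        reads = list(parse_sam(tmp_path / "clean.sam"))
        assert all(r.md == "100" and r.nm == 0 for r in reads)
        p = hx.profile_reads(iter(reads), small_refs)
        for strand in (FIRST, SECOND):
            for pos in range(1, 101):
                assert position_mismatch_rate(p, strand, pos) in (0.0, None)

    def test_hexamer_positions_exceed_downstream(self, small_profile):
        """Under the default model, first-strand rates at positions 1-7 all
        exceed the mean downstream rate."""
        down = [
            position_mismatch_rate(small_profile, FIRST, p) for p in range(8, 101)
        ]
        down_mean = np.mean([d for d in down if d is not None])
        for pos in range(1, 8):
            assert position_mismatch_rate(small_profile, FIRST, pos) > down_mean


class TestMispairDistribution:
    def test_simple_percentages(self):
        bases = [sb(template="U", incorporated="G")] * 3 + [
            sb(template="G", incorporated="T")
        ]
        p = hx.accumulate(bases)
        dist = mispair_distribution(p, FIRST, 1)
        assert dist["rU-dG"] == pytest.approx(75.0)
        assert dist["rG-dT"] == pytest.approx(25.0)
        assert sum(v for k, v in dist.items() if k not in ("rU-dG", "rG-dT")) == 0

    def test_zero_mismatch_position_undefined(self):
        p = hx.accumulate([sb(incorporated="A")])
        assert mispair_distribution(p, FIRST, 1) is None

    def test_every_distribution_sums_to_100(self, small_profile):
        for strand in (FIRST, SECOND):
            for pos in range(1, small_profile.max_position(strand) + 1):
                dist = mispair_distribution(small_profile, strand, pos)
                if dist is not None:
                    assert len(dist) == 12
                    assert sum(dist.values()) == pytest.approx(100.0, abs=1e-9)

    def test_uniform_injection_recovers_uniform_distribution(self, small_refs, tmp_path):
        """Uniform mispriming over all 12 classes comes back ~8.33% each,
        within 3 binomial standard errors."""
        model = hx.ErrorModel(
            first_strand=uniform_mispriming(0.12),
            second_strand=uniform_mispriming(0.0),
            background_error=0.0,
        )
        cfg = hx.LibraryConfig(n_read_pairs=10_000, references=small_refs, model=model)
        hx.simulate_library(cfg, tmp_path / "u.sam", seed=3)
        p = hx.profile_reads(parse_sam(tmp_path / "u.sam"), small_refs)
        for pos in (1, 4, 7):
            n = int(p.mismatch_counts(FIRST, pos).sum())
            dist = mispair_distribution(p, FIRST, pos)
            se = 100 * np.sqrt((1 / 12) * (11 / 12) / n)
            # class shares track template composition; composition is near
            # uniform (GC 0.5) so each class sits near 100/12
            for label, pct in dist.items():
                assert abs(pct - 100 / 12) < 5 * se + 1.0


class TestPerTemplateDistribution:
    def test_zero_mismatch_template(self):
        p = hx.accumulate([sb(template="C", incorporated="G")] * 5)
        panel = per_template_distribution(p, FIRST, 1)
        assert panel["C"]["rate"] == 0.0
        assert panel["C"]["distribution"] is None
        assert panel["A"]["rate"] is None  # never covered

    def test_single_class_distribution_is_100(self):
        p = hx.accumulate(
            [sb(position=3, template="U", incorporated="G")]
            + [sb(position=3, template="U", incorporated="A")] * 9
        )
        panel = per_template_distribution(p, FIRST, 3)
        assert panel["U"]["distribution"] == {"C": 0.0, "G": 100.0, "T": 0.0}
        assert panel["U"]["rate"] == pytest.approx(0.1)

    def test_template_c_rate_lowest_in_hexamer(self, small_profile):
        """Cytosine templates misprime least: strictly lowest at each of
        the well-separated positions 1-6, and lowest pooled over 1-7 (at
        position 7 alone the injected per-template rates are too close to
        resolve at unit-test depth)."""
        for pos in range(1, 7):
            panel = per_template_distribution(small_profile, FIRST, pos)
            rates = {t: cell["rate"] for t, cell in panel.items()}
            assert rates["C"] == min(rates.values())
        pooled_mm = np.zeros(4)
        pooled_cov = np.zeros(4)
        for pos in range(1, 8):
            pooled_mm += small_profile.mismatch_counts(FIRST, pos).sum(axis=1)
            pooled_cov += small_profile.coverage(FIRST, pos)
        pooled = pooled_mm / pooled_cov
        assert pooled[1] == min(pooled)  # template C


class TestHeadlineStats:
    def test_undefined_on_empty(self):
        s = headline_stats(hx.accumulate([]))
        assert s.at_start_rate_pos1 is None
        assert s.uG_frac_pos3_4 is None
        assert s.hexamer_region_rate is None

    def test_at_start_pools_a_and_u_templates(self):
        bases = (
            [sb(template="U", incorporated="G")]  # mispriming at a U start
            + [sb(template="A", incorporated="T")] * 3
            + [sb(template="C", incorporated="G")] * 10  # ignored templates
        )
        s = headline_stats(hx.accumulate(bases))
        assert s.at_start_rate_pos1 == pytest.approx(0.25)
        assert s.at_start_n == 4

    def test_stable_and_uG_fractions(self):
        bases = []
        for pos in (2, 3, 4, 5, 6):
            bases += [sb(position=pos, template="U", incorporated="G")] * 2
            bases += [sb(position=pos, template="A", incorporated="C")]
        bases += [sb(position=3, template="U", incorporated="T")]
        s = headline_stats(hx.accumulate(bases))
        assert s.stable_frac_pos2_6 == pytest.approx(10 / 16)
        assert s.uG_frac_pos3_4 == pytest.approx(4 / 5)

    def test_start_by_read_uses_incorporated_base(self):
        # one read base observed as G at position 1 from template U: under
        # reference-start pooling it is an A/U-start mispriming event, under
        # read-start pooling it does not count (observed base is G)
        p = hx.accumulate([sb(template="U", incorporated="G")])
        by_ref = headline_stats(p, start_by="reference")
        by_read = headline_stats(p, start_by="read")
        assert by_ref.at_start_rate_pos1 == 1.0
        assert by_read.at_start_rate_pos1 is None


class TestMergeAndIO:
    def test_merge_associative_and_equals_pooled(self, small_sim):
        reads = list(parse_sam(small_sim["sam"]))
        refs = small_sim["refs"]
        chunks = [reads[0::3], reads[1::3], reads[2::3]]
        parts = [hx.profile_reads(iter(c), refs) for c in chunks]
        pooled = hx.profile_reads(iter(reads), refs)
        left = hx.merge(hx.merge(parts[0], parts[1]), parts[2])
        right = hx.merge(parts[0], hx.merge(parts[1], parts[2]))
        assert left == right == pooled
        assert left.n_reads == pooled.n_reads

    def test_tsv_roundtrip_exact(self, small_profile, tmp_path):
        path = tmp_path / "profile.tsv"
        profile_to_tsv(small_profile, path)
        again = profile_from_tsv(path)
        assert again == small_profile
        assert again.n_reads == small_profile.n_reads

    def test_tsv_rejects_inconsistent_counts(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "strand\tposition\ttemplate\tincorporated\tmismatches\tcoverage\n"
            "first_strand\t1\tU\tG\t5\t3\n"
        )
        with pytest.raises(ValueError, match="exceed"):
            profile_from_tsv(path)
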