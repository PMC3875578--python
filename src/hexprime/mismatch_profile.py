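"""Per-position, per-nucleotide mismatch profiles and summary statistics.

The central container is :class:`PositionProfileSet`: for each strand class
and synthesis position, a 4x4 template x incorporated count tensor.  Every
observed base increments its (template, incorporated) cell; the
Watson-Crick cell of each template row holds the matches, the three other
cells the mispair counts.  All rates and distributions are derived from
this tensor, carry their denominators, and report "undefined" explicitly
(never 0) when a denominator is empty.

Rates of interest for hexamer-mispriming analysis:

* the per-position mismatch rate, which is elevated across the hexamer
  footprint and first extension base (positions 1-7) of first-strand reads;
* the 12-class mispair distribution at a position (4 templates x 3
  non-complementary incorporated bases, summing to 100%);
* headline first-strand statistics: the pooled mispriming rate of A/U
  templates at position 1, the fraction of position 2-6 events that are the
  thermodynamically stable rU-dG / rG-dT pairs, and the fraction of
  template-U events at positions 3-4 that incorporate G.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .alignment_io import AlignedRead, ReferenceSet, aligned_arrays
from .strand_coords import (
    StrandClass,
    SynthesisBase,
    all_mispair_classes,
    synthesis_arrays,
)

__all__ = [
    "PositionProfileSet",
    "HeadlineStats",
    "accumulate",
    "profile_reads",
    "merge",
    "position_mismatch_rate",
    "mispair_distribution",
    "per_template_distribution",
    "headline_stats",
    "profile_to_tsv",
    "profile_from_tsv",
]

MAX_POSITION = 4096

# complement cell of template code t is incorporated code 3 - t
_COMP_IDX = np.array([3, 2, 1, 0])
_MISPAIR_MASK = np.ones((4, 4), dtype=bool)
_MISPAIR_MASK[np.arange(4), _COMP_IDX] = False

_STRANDS = (StrandClass.FIRST_STRAND, StrandClass.SECOND_STRAND)


class PositionProfileSet:
    """Count tensors per strand: shape (positions, 4 templates, 4 incorporated).

    ``counts[s][p-1, t, i]`` is the number of observed bases at synthesis
    position ``p`` with template code ``t`` and incorporated code ``i``
    (A=0, C=1, G=2, T/U=3).  Coverage of a template at a position is the
    row sum; mismatches are the off-complement cells.  Merging two profile
    sets is element-wise addition.
    """

    def __init__(self) -> None:
        self._counts: dict[StrandClass, np.ndarray] = {
            s: np.zeros((0, 4, 4), dtype=np.int64) for s in _STRANDS
        }
        self.n_reads: dict[StrandClass, int] = {s: 0 for s in _STRANDS}

    # -- storage ---------------------------------------------------------
    def _grow(self, strand: StrandClass, n_positions: int) -> np.ndarray:
        arr = self._counts[strand]
        if n_positions > arr.shape[0]:
            if n_positions > MAX_POSITION:
                raise ValueError(f"synthesis position beyond {MAX_POSITION}")
            new = np.zeros((n_positions, 4, 4), dtype=np.int64)
            new[: arr.shape[0]] = arr
            self._counts[strand] = new
        return self._counts[strand]

    def counts(self, strand: StrandClass) -> np.ndarray:
        """The (positions, 4, 4) tensor for one strand (a view)."""
        return self._counts[strand]

    def add_base(self, base: SynthesisBase) -> None:
        t = base.strand.template_alphabet.index(base.template_base)
        i = "ACGT".index(base.incorporated_base)
        arr = self._grow(base.strand, base.position)
        arr[base.position - 1, t, i] += 1

    def add_arrays(
        self,
        strand: StrandClass,
        positions: np.ndarray,
        template: np.ndarray,
        incorporated: np.ndarray,
    ) -> None:
        if positions.size == 0:
            return
        arr = self._grow(strand, int(positions.max()))
        flat = (positions - 1) * 16 + template * 4 + incorporated
        np.add.at(arr.reshape(-1), flat, 1)

    # -- queries ---------------------------------------------------------
    def max_position(self, strand: StrandClass) -> int:
        arr = self._counts[strand]
        nz = np.nonzero(arr.sum(axis=(1, 2)))[0]
        return int(nz[-1]) + 1 if nz.size else 0

    def coverage(self, strand: StrandClass, position: int) -> np.ndarray:
        """Per-template coverage (length-4 vector) at one position."""
        arr = self._counts[strand]
        if position < 1 or position > arr.shape[0]:
            return np.zeros(4, dtype=np.int64)
        return arr[position - 1].sum(axis=1)

    def mismatch_counts(self, strand: StrandClass, position: int) -> np.ndarray:
        """4x4 mismatch counts at one position (complement cells zeroed)."""
        arr = self._counts[strand]
        if position < 1 or position > arr.shape[0]:
            return np.zeros((4, 4), dtype=np.int64)
        return np.where(_MISPAIR_MASK, arr[position - 1], 0)

    def merge(self, other: "PositionProfileSet") -> "PositionProfileSet":
        out = PositionProfileSet()
        for s in _STRANDS:
            n = max(self._counts[s].shape[0], other._counts[s].shape[0])
            out._grow(s, n)
            out._counts[s][: self._counts[s].shape[0]] += self._counts[s]
            out._counts[s][: other._counts[s].shape[0]] += other._counts[s]
            out.n_reads[s] = self.n_reads[s] + other.n_reads[s]
        return out

    def __add__(self, other: "PositionProfileSet") -> "PositionProfileSet":
        return self.merge(other)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PositionProfileSet):
            return NotImplemented
        for s in _STRANDS:
            a, b = self._counts[s], other._counts[s]
            n = max(a.shape[0], b.shape[0])
            pa = np.zeros((n, 4, 4), dtype=np.int64)
            pb = np.zeros((n, 4, 4), dtype=np.int64)
            pa[: a.shape[0]] = a
            pb[: b.shape[0]] = b
            if not np.array_equal(pa, pb):
                return False
        return True


def accumulate(
    bases: Iterable[SynthesisBase], min_base_quality: int = 0
) -> PositionProfileSet:
    """Tally a stream of synthesis bases into a fresh profile set.

    Bases below ``min_base_quality`` are ignored entirely (they appear in
    neither the coverage denominator nor the mismatch numerator).
    """
    profile = PositionProfileSet()
    for base in bases:
        if base.base_qual >= min_base_quality:
            profile.add_base(base)
    return profile


def profile_reads(
    reads: Iterable[AlignedRead],
    refs: ReferenceSet | None = None,
    *,
    min_base_quality: int = 0,
    mates: str = "both",
    prefer: str = "auto",
) -> PositionProfileSet:
    """Profile an iterable of (already filtered) mapped reads.

    This is the vectorised equivalent of running ``reconstruct_columns``,
    ``to_synthesis_coords`` and :func:`accumulate` read by read; the two
    routes produce identical tensors.  ``mates`` restricts profiling to
    mate 1, mate 2 or both ("1" | "2" | "both").
    """
    if mates not in ("1", "2", "both"):
        raise ValueError("mates must be '1', '2' or 'both'")
    profile = PositionProfileSet()
    for read in reads:
        if mates != "both" and read.mate_index != int(mates):
            continue
        q_idx, ref_pos, q_codes, r_codes = aligned_arrays(read, refs, prefer=prefer)
        if min_base_quality > 0:
            keep = read.base_qualities()[q_idx] >= min_base_quality
            q_idx, q_codes, r_codes = q_idx[keep], q_codes[keep], r_codes[keep]
            ref_pos = ref_pos[keep]
        strand, positions, template, incorporated = synthesis_arrays(
            read, q_idx, ref_pos, q_codes, r_codes
        )
        valid = positions >= 1
        profile.add_arrays(
            strand, positions[valid], template[valid], incorporated[valid]
        )
        profile.n_reads[strand] += 1
    return profile


def merge(a: PositionProfileSet, b: PositionProfileSet) -> PositionProfileSet:
    """Element-wise sum of two profiles (associative and commutative)."""
    return a.merge(b)


# ---------------------------------------------------------------------------
# Rates and distributions
# ---------------------------------------------------------------------------


def _template_indices(strand: StrandClass, templates: Sequence[str] | None) -> list[int]:
    if templates is None:
        return [0, 1, 2, 3]
    alphabet = strand.template_alphabet
    return [alphabet.index("U" if t == "T" and "U" in alphabet else t) for t in templates]


def position_mismatch_rate(
    profile: PositionProfileSet,
    strand: StrandClass,
    position: int,
    templates: Sequence[str] | None = None,
) -> float | None:
    """Mismatches / coverage at one position, optionally over a template subset.

    Returns None (undefined) when the coverage denominator is zero.
    """
    idx = _template_indices(strand, templates)
    cov = int(profile.coverage(strand, position)[idx].sum())
    if cov == 0:
        return None
    mm = int(profile.mismatch_counts(strand, position)[idx].sum())
    return mm / cov


def pooled_mismatch_rate(
    profile: PositionProfileSet,
    strand: StrandClass,
    positions: Iterable[int],
) -> tuple[float | None, int, int]:
    """(rate, mismatches, coverage) pooled over a set of positions."""
    mm = cov = 0
    for p in positions:
        cov += int(profile.coverage(strand, p).sum())
        mm += int(profile.mismatch_counts(strand, p).sum())
    return (mm / cov if cov else None), mm, cov


def mispair_distribution(
    profile: PositionProfileSet, strand: StrandClass, position: int
) -> dict[str, float] | None:
    """Percentage of each of the 12 mispair classes at one position.

    The 12 entries sum to 100; undefined (None) when the position has no
    mismatches at all.
    """
    mm = profile.mismatch_counts(strand, position)
    total = mm.sum()
    if total == 0:
        return None
    out = {}
    for cls in all_mispair_classes(strand):
        t = strand.template_alphabet.index(cls.template_base)
        i = "ACGT".index(cls.incorporated_base)
        out[cls.label] = 100.0 * mm[t, i] / total
    return out


def mispair_counts(
    profile: PositionProfileSet, strand: StrandClass, position: int
) -> dict[str, int]:
    """Raw per-class mismatch counts at one position (all 12 classes)."""
    mm = profile.mismatch_counts(strand, position)
    out = {}
    for cls in all_mispair_classes(strand):
        t = strand.template_alphabet.index(cls.template_base)
        i = "ACGT".index(cls.incorporated_base)
        out[cls.label] = int(mm[t, i])
    return out


def per_template_distribution(
    profile: PositionProfileSet, strand: StrandClass, position: int
) -> dict[str, dict]:
    """Per-template mismatch rate and 3-way incorporated-base distribution.

    For each template base: its coverage, mismatch count, mismatch rate
    (None when uncovered) and the percentage split of its mismatches over
    the three non-complementary incorporated bases (None when the template
    has no mismatches).
    """
    cov = profile.coverage(strand, position)
    mm = profile.mismatch_counts(strand, position)
    out = {}
    for t, letter in enumerate(strand.template_alphabet):
        t_cov = int(cov[t])
        t_mm = int(mm[t].sum())
        rate = t_mm / t_cov if t_cov else None
        if t_mm:
            dist = {
                "ACGT"[i]: 100.0 * mm[t, i] / t_mm
                for i in range(4)
                if _MISPAIR_MASK[t, i]
            }
        else:
            dist = None
        out[letter] = {
            "coverage": t_cov,
            "mismatches": t_mm,
            "rate": rate,
            "distribution": dist,
        }
    return out


@dataclass
class HeadlineStats:
    """Headline first-strand mispriming statistics (fractions in [0, 1]).

    Each field is None when its denominator is zero; ``*_n`` carries the
    denominator so exact binomial intervals can be computed downstream.
    """

    at_start_rate_pos1: float | None
    stable_frac_pos2_6: float | None
    uG_frac_pos3_4: float | None
    hexamer_region_rate: float | None
    downstream_rate: float | None
    at_start_n: int = 0
    stable_n: int = 0
    uG_n: int = 0
    hexamer_n: int = 0
    downstream_n: int = 0

    def to_dict(self) -> dict:
        return {
            "at_start_rate_pos1": self.at_start_rate_pos1,
            "stable_frac_pos2_6": self.stable_frac_pos2_6,
            "uG_frac_pos3_4": self.uG_frac_pos3_4,
            "hexamer_region_rate": self.hexamer_region_rate,
            "downstream_rate": self.downstream_rate,
            "denominators": {
                "at_start_n": self.at_start_n,
                "stable_n": self.stable_n,
                "uG_n": self.uG_n,
                "hexamer_n": self.hexamer_n,
                "downstream_n": self.downstream_n,
            },
        }


def headline_stats(
    profile: PositionProfileSet,
    hexamer_region: tuple[int, int] = (1, 7),
    downstream_from: int = 8,
    start_by: str = "reference",
) -> HeadlineStats:
    """Compute the headline first-strand statistics from a profile.

    * ``at_start_rate_pos1``: pooled mispriming rate at position 1 of reads
      starting with A or T.  By default the start base is the *reference*
      (template A or U) — the read's own first base is corrupted by the
      very errors being measured, so the reference keeps the denominator
      error-independent.  ``start_by="read"`` pools by the observed
      (incorporated) first base instead.
    * ``stable_frac_pos2_6``: fraction of all position 2-6 mispriming
      events that are rU-dG or rG-dT, the most stable RNA-DNA mispairs.
    * ``uG_frac_pos3_4``: of template-U mispriming events at positions 3-4,
      the fraction incorporating G.
    * pooled rates over the hexamer region and the downstream window.
    """
    if start_by not in ("reference", "read"):
        raise ValueError("start_by must be 'reference' or 'read'")
    s = StrandClass.FIRST_STRAND
    U, G = 3, 2  # template codes; incorporated codes G=2, T=3

    cov1 = profile.coverage(s, 1)
    mm1 = profile.mismatch_counts(s, 1)
    if start_by == "reference":
        at_n = int(cov1[0] + cov1[U])
        at_mm = int(mm1[0].sum() + mm1[U].sum())
    else:
        arr = profile.counts(s)
        cell = arr[0] if arr.shape[0] else np.zeros((4, 4), dtype=np.int64)
        at_n = int(cell[:, [0, 3]].sum())  # observed first base A or T
        at_mm = int(mm1[:, [0, 3]].sum())
    at_rate = at_mm / at_n if at_n else None

    stable = total = 0
    for p in range(2, 7):
        mm = profile.mismatch_counts(s, p)
        stable += int(mm[U, 2] + mm[G, 3])  # rU-dG + rG-dT
        total += int(mm.sum())
    stable_frac = stable / total if total else None

    uG = u_all = 0
    for p in (3, 4):
        mm = profile.mismatch_counts(s, p)
        uG += int(mm[U, 2])
        u_all += int(mm[U].sum())
    uG_frac = uG / u_all if u_all else None

    hex_rate, _, hex_n = pooled_mismatch_rate(
        profile, s, range(hexamer_region[0], hexamer_region[1] + 1)
    )
    max_p = profile.max_position(s)
    down_rate, _, down_n = pooled_mismatch_rate(
        profile, s, range(downstream_from, max_p + 1)
    )

    return HeadlineStats(
        at_start_rate_pos1=at_rate,
        stable_frac_pos2_6=stable_frac,
        uG_frac_pos3_4=uG_frac,
        hexamer_region_rate=hex_rate,
        downstream_rate=down_rate,
        at_start_n=at_n,
        stable_n=total,
        uG_n=u_all,
        hexamer_n=hex_n,
        downstream_n=down_n,
    )


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------


def profile_to_tsv(profile: PositionProfileSet, path: str | Path) -> None:
    """Write the profile: one row per strand x position x template x incorporated.

    Only off-complement (mispair) incorporated bases get rows; the
    ``coverage`` column repeats the template's total coverage so the full
    tensor round-trips (matches = coverage - sum of mismatches).
    """
    with open(path, "w") as fh:
        for s in _STRANDS:
            fh.write(f"# n_reads\t{s.value}\t{profile.n_reads[s]}\n")
        fh.write("strand\tposition\ttemplate\tincorporated\tmismatches\tcoverage\n")
        for s in _STRANDS:
            arr = profile.counts(s)
            for p in range(1, arr.shape[0] + 1):
                cov = profile.coverage(s, p)
                if cov.sum() == 0:
                    continue
                mm = profile.mismatch_counts(s, p)
                for t, letter in enumerate(s.template_alphabet):
                    for i in range(4):
                        if not _MISPAIR_MASK[t, i]:
                            continue
                        fh.write(
                            f"{s.value}\t{p}\t{letter}\t{'ACGT'[i]}\t"
                            f"{mm[t, i]}\t{cov[t]}\n"
                        )


def profile_from_tsv(path: str | Path) -> PositionProfileSet:
    """Read a profile TSV written by :func:`profile_to_tsv`."""
    profile = PositionProfileSet()
    strand_by_value = {s.value: s for s in _STRANDS}
    seen_cov: dict[tuple, int] = {}
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line.lstrip("# ").split("\t")
                if parts[0] == "n_reads" and len(parts) == 3:
                    profile.n_reads[strand_by_value[parts[1]]] = int(parts[2])
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                expected = [
                    "strand",
                    "position",
                    "template",
                    "incorporated",
                    "mismatches",
                    "coverage",
                ]
                for col in expected:
                    if col not in header:
                        raise ValueError(f"profile TSV missing column {col!r}")
                idx = {c: header.index(c) for c in expected}
                continue
            s = strand_by_value[parts[idx["strand"]]]
            p = int(parts[idx["position"]])
            t = s.template_alphabet.index(parts[idx["template"]])
            i = "ACGT".index(parts[idx["incorporated"]])
            mm = int(parts[idx["mismatches"]])
            cov = int(parts[idx["coverage"]])
            arr = profile._grow(s, p)
            arr[p - 1, t, i] += mm
            seen_cov[(s, p, t)] = cov
    # fill the complement (match) cells from coverage - mismatches
    for (s, p, t), cov in seen_cov.items():
        arr = profile.counts(s)
        mm_sum = int(np.where(_MISPAIR_MASK[t], arr[p - 1, t], 0).sum())
        if mm_sum > cov:
            raise ValueError(
                f"profile TSV inconsistent at {s.value} position {p}: "
                f"mismatches {mm_sum} exceed coverage {cov}"
            )
        arr[p - 1, t, _COMP_IDX[t]] = cov - mm_sum
    return profile


def _fmt(x: float | None, scale: float = 1.0, digits: int = 6) -> str:
    return "NA" if x is None else f"{x * scale:.{digits}g}"


def rates_to_tsv(profile: PositionProfileSet, path: str | Path) -> None:
    """Per-position mismatch rate table for both strands (rate-vs-position)."""
    with open(path, "w") as fh:
        fh.write("strand\tposition\tmismatches\tcoverage\trate\n")
        for s in _STRANDS:
            for p in range(1, profile.max_position(s) + 1):
                cov = int(profile.coverage(s, p).sum())
                mm = int(profile.mismatch_counts(s, p).sum())
                rate = mm / cov if cov else None
                fh.write(f"{s.value}\t{p}\t{mm}\t{cov}\t{_fmt(rate)}\n")


def distributions_to_tsv(
    profile: PositionProfileSet, path: str | Path, positions: Iterable[int] | None = None
) -> None:
    """12-class mispair distribution per strand and position."""
    with open(path, "w") as fh:
        fh.write("strand\tposition\tclass_label\tpercent\tn_mismatches\n")
        for s in _STRANDS:
            plist = positions if positions is not None else range(
                1, profile.max_position(s) + 1
            )
            for p in plist:
                dist = mispair_distribution(profile, s, p)
                counts = mispair_counts(profile, s, p)
                for cls in all_mispair_classes(s):
                    pct = "NA" if dist is None else f"{dist[cls.label]:.6g}"
                    fh.write(
                        f"{s.value}\t{p}\t{cls.label}\t{pct}\t{counts[cls.label]}\n"
                    )


def per_template_to_tsv(
    profile: PositionProfileSet,
    path: str | Path,
    positions: Sequence[int] = (1, 3, 15, 50),
) -> None:
    """Per-template panels (default positions 1, 3, 15, 50), first strand."""
    s = StrandClass.FIRST_STRAND
    with open(path, "w") as fh:
        fh.write(
            "position\ttemplate\tcoverage\tmismatches\trate\t"
            "pct_to_A\tpct_to_C\tpct_to_G\tpct_to_T\n"
        )
        for p in positions:
            panel = per_template_distribution(profile, s, p)
            for letter, cell in panel.items():
                dist = cell["distribution"]
                pcts = []
                for i in "ACGT":
                    if dist is not None and i in dist:
                        pcts.append(f"{dist[i]:.6g}")
                    else:
                        pcts.append("NA")
                fh.write(
                    f"{p}\t{letter}\t{cell['coverage']}\t{cell['mismatches']}\t"
                    f"{_fmt(cell['rate'])}\t" + "\t".join(pcts) + "\n"
                )


def headline_to_json(stats: HeadlineStats, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(stats.to_dict(), fh, indent=2)
        fh.write("\n")
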