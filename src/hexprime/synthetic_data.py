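"""Synthetic ERCC-like references and hexamer-primed paired-end libraries.

The simulator emulates the parts of RNA-seq library preparation that
matter for per-position error profiling: fragmentation of known reference
transcripts, first-strand cDNA synthesis primed by a random hexamer on the
RNA (with a position-specific template x incorporated mispriming matrix
over synthesis positions 1-7), second-strand synthesis on the first-strand
cDNA (its own matrix), and a flat downstream substitution rate standing in
for sequencing error.  Each fragment yields one reverse-mapping
(first-strand) and one forward-mapping (second-strand) 100 bp read as a
proper pair, written as valid SAM records with FLAG, POS, CIGAR, MD, NM
and TLEN consistent with the reference — plus a ground-truth event log of
every injected non-complementary base, so every upstream analysis stage
can be tested by exact parameter recovery.

Errors are injected in synthesis coordinates *before* the first-strand
read is reverse-complemented into SAM orientation, so coordinate
round-trips through the profiler are meaningful.  Everything is
deterministic given a seed.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from . import _bases
from .alignment_io import ReferenceSet
from .mismatch_profile import HeadlineStats, PositionProfileSet
from .strand_coords import StrandClass

__all__ = [
    "ErrorModel",
    "TruthRecord",
    "LibraryConfig",
    "simulate_references",
    "simulate_library",
    "default_error_model",
    "uniform_mispriming",
    "expected_headline_stats",
    "truth_to_tsv",
    "truth_from_tsv",
]

HEXAMER_POSITIONS = 7  # hexamer footprint (6) plus the first extension base
_DNA = "ACGT"
_RNA = "ACGU"


def _rows_to_matrix(rows: dict[str, dict[str, float]], alphabet: str) -> np.ndarray:
    """One position's 4x4 row-stochastic matrix from off-complement entries."""
    m = np.zeros((4, 4))
    for t, letter in enumerate(alphabet):
        off = rows.get(letter, {})
        comp = 3 - t
        s = 0.0
        for inc, p in off.items():
            i = _DNA.index(inc)
            if i == comp:
                raise ValueError(
                    f"row {letter}: {inc} is the complement, not a mispair"
                )
            if p < 0:
                raise ValueError(f"negative probability in row {letter}")
            m[t, i] = p
            s += p
        if s > 1.0 + 1e-12:
            raise ValueError(f"row {letter}: off-complement mass {s} exceeds 1")
        m[t, comp] = 1.0 - s
    return m


@dataclass
class ErrorModel:
    """Position-specific mispriming matrices plus a downstream error rate.

    ``first_strand[p-1, t, i]`` is the probability that a first-strand
    synthesis base at position p (1..7) with RNA template code t (A,C,G,U)
    incorporates DNA base i; the Watson-Crick cell holds the no-error
    probability and every row sums to 1.  ``second_strand`` is the same
    shape over DNA templates.  ``background_error`` is the flat per-base
    substitution probability (uniform over the 3 alternatives) applied at
    positions > 7.
    """

    first_strand: np.ndarray
    second_strand: np.ndarray
    background_error: float = 0.001
    seed: int | None = None

    def __post_init__(self) -> None:
        self.first_strand = np.asarray(self.first_strand, dtype=float)
        self.second_strand = np.asarray(self.second_strand, dtype=float)
        for name, m in (("first_strand", self.first_strand),
                        ("second_strand", self.second_strand)):
            if m.shape != (HEXAMER_POSITIONS, 4, 4):
                raise ValueError(f"{name} must have shape (7, 4, 4), got {m.shape}")
            if (m < 0).any():
                raise ValueError(f"{name} has negative entries")
            if not np.allclose(m.sum(axis=2), 1.0, atol=1e-12):
                raise ValueError(f"{name} rows must sum to 1")
        if not 0.0 <= self.background_error <= 0.25:
            raise ValueError("background_error must be in [0, 0.25]")

    def off_complement_mass(self, strand: StrandClass) -> np.ndarray:
        """(7, 4) total mispriming probability per position and template."""
        m = self.matrix(strand)
        out = m.sum(axis=2) - m[:, np.arange(4), 3 - np.arange(4)]
        return out

    def matrix(self, strand: StrandClass) -> np.ndarray:
        return (
            self.first_strand
            if strand is StrandClass.FIRST_STRAND
            else self.second_strand
        )

    # -- serialisation ---------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict, seed: int | None = None) -> "ErrorModel":
        def build(key: str, alphabet: str) -> np.ndarray:
            by_pos: dict[int, dict] = {}
            for k, rows in d[key].items():
                if isinstance(k, int):
                    pos_range = [k]
                else:
                    a, _, b = str(k).partition("-")
                    pos_range = list(range(int(a), int(b or a) + 1))
                for p in pos_range:
                    if not 1 <= p <= HEXAMER_POSITIONS:
                        raise ValueError(f"position {p} outside 1..7")
                    if p in by_pos:
                        raise ValueError(f"position {p} specified twice in {key}")
                    by_pos[p] = rows
            mats = []
            for p in range(1, HEXAMER_POSITIONS + 1):
                mats.append(_rows_to_matrix(by_pos.get(p, {}), alphabet))
            return np.stack(mats)

        return cls(
            first_strand=build("first_strand", _RNA),
            second_strand=build("second_strand", _DNA),
            background_error=float(d.get("background_error", 0.001)),
            seed=seed,
        )

    def to_dict(self) -> dict:
        def dump(m: np.ndarray, alphabet: str) -> dict:
            out = {}
            for p in range(HEXAMER_POSITIONS):
                rows = {}
                for t, letter in enumerate(alphabet):
                    off = {
                        _DNA[i]: float(m[p, t, i])
                        for i in range(4)
                        if i != 3 - t and m[p, t, i] > 0
                    }
                    if off:
                        rows[letter] = off
                out[p + 1] = rows
            return out

        return {
            "first_strand": dump(self.first_strand, _RNA),
            "second_strand": dump(self.second_strand, _DNA),
            "background_error": float(self.background_error),
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ErrorModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def uniform_mispriming(rate: float) -> np.ndarray:
    """(7, 4, 4) matrix with off-complement mass ``rate`` spread uniformly."""
    m = np.full((HEXAMER_POSITIONS, 4, 4), rate / 3.0)
    for t in range(4):
        m[:, t, 3 - t] = 1.0 - rate
    return m


def default_error_model(
    seed: int | None = None, second_strand: str = "default"
) -> ErrorModel:
    """The packaged default mispriming model (see data/default_model.yaml).

    ``second_strand="background"`` replaces the second-strand matrix with a
    uniform matrix whose off-complement mass equals the downstream error
    rate — i.e. first-strand mispriming only, the second strand carrying
    nothing beyond the flat error floor.
    """
    text = (
        resources.files("hexprime").joinpath("data/default_model.yaml").read_text()
    )
    model = ErrorModel.from_dict(yaml.safe_load(text), seed=seed)
    if second_strand == "background":
        model = ErrorModel(
            first_strand=model.first_strand,
            second_strand=uniform_mispriming(model.background_error),
            background_error=model.background_error,
            seed=seed,
        )
    elif second_strand != "default":
        raise ValueError("second_strand must be 'default' or 'background'")
    return model


def expected_headline_stats(
    model: ErrorModel,
    base_freq: np.ndarray | None = None,
    read_length: int = 100,
) -> HeadlineStats:
    """Analytic headline expectations under given template base frequencies.

    Computed directly from the matrices, no simulation: what the profiler
    should recover, in expectation, from a library with i.i.d. template
    bases at frequencies ``base_freq`` (A, C, G, U; default uniform).
    """
    f = np.full(4, 0.25) if base_freq is None else np.asarray(base_freq, float)
    m = model.first_strand
    off = model.off_complement_mass(StrandClass.FIRST_STRAND)
    A, G, U = 0, 2, 3

    at_start = (f[A] * off[0, A] + f[U] * off[0, U]) / (f[A] + f[U])
    stable = sum(f[U] * m[p, U, 2] + f[G] * m[p, G, 3] for p in range(1, 6))
    total = sum(float(f @ off[p]) for p in range(1, 6))
    stable_frac = stable / total if total else None
    uG = (m[2, U, 2] + m[3, U, 2]) / (off[2, U] + off[3, U])
    hex_rate = float(np.mean([f @ off[p] for p in range(HEXAMER_POSITIONS)]))
    return HeadlineStats(
        at_start_rate_pos1=float(at_start),
        stable_frac_pos2_6=float(stable_frac) if stable_frac is not None else None,
        uG_frac_pos3_4=float(uG),
        hexamer_region_rate=hex_rate,
        downstream_rate=model.background_error,
    )


def expected_stats_given_coverage(
    model: ErrorModel, profile: PositionProfileSet
) -> HeadlineStats:
    """Headline expectations conditional on the observed template coverage.

    Replaces the i.i.d. base-frequency assumption with the per-position
    template counts actually present in a profile, removing reference
    base-composition wobble from the expectation.
    """
    m = model.first_strand
    off = model.off_complement_mass(StrandClass.FIRST_STRAND)
    s = StrandClass.FIRST_STRAND
    A, G, U = 0, 2, 3

    cov1 = profile.coverage(s, 1).astype(float)
    at_n = cov1[A] + cov1[U]
    at_start = (
        (cov1[A] * off[0, A] + cov1[U] * off[0, U]) / at_n if at_n else None
    )
    stable = total = 0.0
    for p in range(2, 7):
        cov = profile.coverage(s, p).astype(float)
        stable += cov[U] * m[p - 1, U, 2] + cov[G] * m[p - 1, G, 3]
        total += float(cov @ off[p - 1])
    uG_num = uG_den = 0.0
    for p in (3, 4):
        covU = float(profile.coverage(s, p)[U])
        uG_num += covU * m[p - 1, U, 2]
        uG_den += covU * off[p - 1, U]
    hex_num = hex_den = 0.0
    for p in range(1, HEXAMER_POSITIONS + 1):
        cov = profile.coverage(s, p).astype(float)
        hex_num += float(cov @ off[p - 1])
        hex_den += cov.sum()
    return HeadlineStats(
        at_start_rate_pos1=at_start,
        stable_frac_pos2_6=stable / total if total else None,
        uG_frac_pos3_4=uG_num / uG_den if uG_den else None,
        hexamer_region_rate=hex_num / hex_den if hex_den else None,
        downstream_rate=model.background_error,
        at_start_n=int(at_n),
        stable_n=int(round(total)),
        uG_n=int(round(uG_den)),
        hexamer_n=int(hex_den),
    )


# ---------------------------------------------------------------------------
# Reference simulation
# ---------------------------------------------------------------------------


def simulate_references(
    n: int,
    length_range: tuple[int, int] = (250, 2000),
    gc: float = 0.5,
    seed: int | None = None,
    prefix: str = "SYN",
) -> ReferenceSet:
    """Generate ``n`` ERCC-like reference transcripts with i.i.d. bases.

    Synthetic stand-ins for a spike-in set of known sequences: lengths
    uniform over ``length_range``, base composition set by the requested
    GC fraction.  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("need at least one reference")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    entries = {}
    for k in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        codes = rng.choice(4, size=length, p=probs).astype(np.uint8)
        entries[f"{prefix}-{k + 1:04d}"] = _bases.decode(codes)
    return ReferenceSet(entries)


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthRecord:
    """One injected non-complementary base (the ground-truth event log)."""

    qname: str
    strand: StrandClass
    reference_id: str
    ref_pos: int
    position: int
    template_base: str
    incorporated_base: str
    origin: str  # MISPRIME (positions 1-7) or BACKGROUND


@dataclass
class LibraryConfig:
    """Simulated library parameters.

    Fragment lengths are truncated-normal (rejection-sampled within
    ``[min_fragment, reference length]``); fragment starts are uniform.
    Base qualities are a constant Phred score — misprimed bases are called
    at high confidence, so no quality model is needed.
    """

    n_read_pairs: int
    references: ReferenceSet
    model: ErrorModel
    read_length: int = 100
    fragment_mean: float = 300.0
    fragment_sd: float = 60.0
    min_fragment: int = 150
    base_quality: int = 40

    def __post_init__(self) -> None:
        if self.n_read_pairs < 0:
            raise ValueError("n_read_pairs must be >= 0")
        if self.read_length > self.min_fragment:
            raise ValueError("read_length must be <= min_fragment")


def _sample_fragments(cfg: LibraryConfig, rng: np.random.Generator):
    ids = list(cfg.references)
    lengths = np.array([len(cfg.references[r]) for r in ids])
    eligible = lengths >= cfg.min_fragment
    if not eligible.any():
        raise ValueError("no reference long enough for min_fragment")
    weights = np.where(eligible, lengths, 0).astype(float)
    weights /= weights.sum()
    n = cfg.n_read_pairs
    ref_idx = rng.choice(len(ids), size=n, p=weights)
    ref_len = lengths[ref_idx]

    frag = np.rint(rng.normal(cfg.fragment_mean, cfg.fragment_sd, size=n)).astype(int)
    bad = (frag < cfg.min_fragment) | (frag > ref_len)
    for _ in range(100):
        if not bad.any():
            break
        frag[bad] = np.rint(
            rng.normal(cfg.fragment_mean, cfg.fragment_sd, size=int(bad.sum()))
        ).astype(int)
        bad = (frag < cfg.min_fragment) | (frag > ref_len)
    if bad.any():
        # bounded retries exhausted: clamp into the feasible window
        frag = np.clip(frag, cfg.min_fragment, ref_len)
    start = 1 + np.floor(rng.random(n) * (ref_len - frag + 1)).astype(int)
    return ids, ref_idx, frag, start


def _sample_hexamer(
    matrix: np.ndarray, templates: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample incorporated codes for positions 1..7 given template codes.

    ``templates`` has shape (n, 7); rows of ``matrix`` (7, 4, 4) are
    cumulated and inverted against uniform draws.
    """
    n = templates.shape[0]
    cum = np.cumsum(matrix, axis=2)
    u = rng.random((n, HEXAMER_POSITIONS))
    out = np.empty_like(templates)
    for j in range(HEXAMER_POSITIONS):
        c = cum[j][templates[:, j]]
        out[:, j] = (c[:, :3] <= u[:, j, None]).sum(axis=1)
    return out


def _apply_background(
    inc: np.ndarray, rate: float, rng: np.random.Generator
) -> None:
    """Substitute downstream bases (columns 7..) in place with prob ``rate``."""
    tail = inc[:, HEXAMER_POSITIONS:]
    if tail.size == 0 or rate == 0:
        return
    mask = rng.random(tail.shape) < rate
    shift = rng.integers(1, 4, size=int(mask.sum()))
    tail[mask] = (tail[mask] + shift) % 4


def _md_string(read_codes: np.ndarray, ref_codes: np.ndarray) -> tuple[str, int]:
    """MD tag and NM for an all-M alignment of read vs reference slice."""
    diff = np.nonzero(read_codes != ref_codes)[0]
    if diff.size == 0:
        return str(len(read_codes)), 0
    parts = []
    prev = -1
    for d in diff:
        parts.append(str(d - prev - 1))
        parts.append(_DNA[ref_codes[d]])
        prev = d
    parts.append(str(len(read_codes) - prev - 1))
    return "".join(parts), int(diff.size)


def simulate_library(
    cfg: LibraryConfig,
    out_sam: str | Path,
    seed: int | None = None,
) -> list[TruthRecord]:
    """Simulate a paired-end library, write SAM, return the truth log.

    Every fragment yields a forward-mapping second-strand read (FLAG 99)
    starting at the fragment's 5' end and a reverse-mapping first-strand
    read (FLAG 147) whose synthesis position 1 sits at the fragment's 3'
    end (its highest reference coordinate).  Byte-identical output for
    identical (cfg, seed).
    """
    if seed is None:
        seed = cfg.model.seed
    rng = np.random.default_rng(seed)
    L = cfg.read_length
    truth: list[TruthRecord] = []
    lines: list[str] = []

    if cfg.n_read_pairs > 0:
        ids, ref_idx, frag, start = _sample_fragments(cfg, rng)
        ref_codes = {r: cfg.references.codes(r) for r in cfg.references}
        n = cfg.n_read_pairs
        col = np.arange(L)

        # sense-strand codes under each read
        fwd_slice = np.empty((n, L), dtype=np.int64)   # second-strand footprint
        rev_slice = np.empty((n, L), dtype=np.int64)   # first-strand footprint
        for k, rid in enumerate(ids):
            sel = np.nonzero(ref_idx == k)[0]
            if sel.size == 0:
                continue
            codes = ref_codes[rid].astype(np.int64)
            fwd_slice[sel] = codes[(start[sel] - 1)[:, None] + col]
            rev_slice[sel] = codes[(start[sel] + frag[sel] - L - 1)[:, None] + col]

        # --- second strand (forward-mapping): template is first-strand cDNA
        S = fwd_slice
        inc2 = S.copy()
        tmpl2 = 3 - S[:, :HEXAMER_POSITIONS]
        inc2[:, :HEXAMER_POSITIONS] = _sample_hexamer(
            cfg.model.second_strand, tmpl2, rng
        )
        _apply_background(inc2, cfg.model.background_error, rng)

        # --- first strand (reverse-mapping): template is the RNA itself,
        # synthesis runs from the fragment 3' end toward its 5' end
        T_syn = rev_slice[:, ::-1].copy()
        inc1 = 3 - T_syn
        inc1[:, :HEXAMER_POSITIONS] = _sample_hexamer(
            cfg.model.first_strand, T_syn[:, :HEXAMER_POSITIONS], rng
        )
        _apply_background(inc1, cfg.model.background_error, rng)

        qnames = [f"sim{i:08d}" for i in range(n)]

        def log_events(strand, inc, comp_of_template, template_rna, ref_pos_of_col):
            alphabet = strand.template_alphabet
            rows, cols = np.nonzero(inc != comp_of_template)
            for r, c in zip(rows, cols):
                truth.append(
                    TruthRecord(
                        qname=qnames[r],
                        strand=strand,
                        reference_id=ids[ref_idx[r]],
                        ref_pos=int(ref_pos_of_col(r, c)),
                        position=int(c) + 1,
                        template_base=alphabet[template_rna[r, c]],
                        incorporated_base=_DNA[inc[r, c]],
                        origin="MISPRIME" if c < HEXAMER_POSITIONS else "BACKGROUND",
                    )
                )

        log_events(
            StrandClass.SECOND_STRAND,
            inc2,
            S,
            3 - S,
            lambda r, c: start[r] + c,
        )
        log_events(
            StrandClass.FIRST_STRAND,
            inc1,
            3 - T_syn,
            T_syn,
            lambda r, c: start[r] + frag[r] - 1 - c,
        )

        # --- serialise
        qual = chr(cfg.base_quality + 33) * L
        cig = f"{L}M"
        rev_seq_fwd = (3 - inc1)[:, ::-1]  # SAM orientation of first-strand read
        for i in range(n):
            rid = ids[ref_idx[i]]
            pos_f = int(start[i])
            pos_r = int(start[i] + frag[i] - L)
            f = int(frag[i])
            seq_f = _bases.decode(inc2[i].astype(np.uint8))
            seq_r = _bases.decode(rev_seq_fwd[i].astype(np.uint8))
            md_f, nm_f = _md_string(inc2[i], fwd_slice[i])
            md_r, nm_r = _md_string(rev_seq_fwd[i], rev_slice[i])
            q = qnames[i]
            lines.append(
                f"{q}\t99\t{rid}\t{pos_f}\t60\t{cig}\t=\t{pos_r}\t{f}\t"
                f"{seq_f}\t{qual}\tNM:i:{nm_f}\tMD:Z:{md_f}"
            )
            lines.append(
                f"{q}\t147\t{rid}\t{pos_r}\t60\t{cig}\t=\t{pos_f}\t{-f}\t"
                f"{seq_r}\t{qual}\tNM:i:{nm_r}\tMD:Z:{md_r}"
            )

    with open(out_sam, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for rid, ln in cfg.references.lengths().items():
            fh.write(f"@SQ\tSN:{rid}\tLN:{ln}\n")
        for line in lines:
            fh.write(line + "\n")
    return truth


# ---------------------------------------------------------------------------
# Truth-log serialisation
# ---------------------------------------------------------------------------

_TRUTH_COLS = (
    "qname",
    "strand",
    "reference_id",
    "ref_pos",
    "position",
    "template_base",
    "incorporated_base",
    "origin",
)


def truth_to_tsv(records: Iterable[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TRUTH_COLS) + "\n")
        for r in records:
            fh.write(
                f"{r.qname}\t{r.strand.value}\t{r.reference_id}\t{r.ref_pos}\t"
                f"{r.position}\t{r.template_base}\t{r.incorporated_base}\t"
                f"{r.origin}\n"
            )


def truth_from_tsv(path: str | Path) -> list[TruthRecord]:
    strand_by_value = {s.value: s for s in StrandClass}
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _TRUTH_COLS:
            raise ValueError(f"unexpected truth-log header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                TruthRecord(
                    qname=f[0],
                    strand=strand_by_value[f[1]],
                    reference_id=f[2],
                    ref_pos=int(f[3]),
                    position=int(f[4]),
                    template_base=f[5],
                    incorporated_base=f[6],
                    origin=f[7],
                )
            )
    return out
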