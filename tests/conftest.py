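"""Shared fixtures: hand-built reads and cached simulator runs."""
from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

import hexprime as hx
from hexprime.alignment_io import _parse_sam_line

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# study conditions: 100 bp pairs over an ERCC-scale reference set
N_PAIRS_LARGE = 200_000
N_REFS = 92


def make_read(
    qname: str = "r1",
    flag: int = 99,
    ref: str = "R",
    pos: int = 1,
    cigar: str = "4M",
    seq: str = "ACGT",
    qual: str | None = None,
    tlen: int = 200,
    md: str | None = None,
    nm: int | None = None,
    mapq: int = 60,
) -> hx.AlignedRead:
    """Build an AlignedRead by round-tripping a hand-written SAM line."""
    if qual is None:
        qual = "I" * len(seq) if seq != "*" else "*"
    tags = []
    if nm is not None:
        tags.append(f"NM:i:{nm}")
    if md is not None:
        tags.append(f"MD:Z:{md}")
    line = "\t".join(
        [qname, str(flag), ref, str(pos), str(mapq), cigar, "=", "1", str(tlen), seq, qual]
        + tags
    )
    return _parse_sam_line(line, 1)


@pytest.fixture(scope="session")
def small_refs():
    return hx.simulate_references(12, length_range=(250, 800), seed=11)


@pytest.fixture(scope="session")
def small_sim(small_refs, tmp_path_factory):
    """A 2000-pair library under the default model (unit-test scale)."""
    out = tmp_path_factory.mktemp("small_sim")
    model = hx.default_error_model(seed=11)
    cfg = hx.LibraryConfig(n_read_pairs=2000, references=small_refs, model=model)
    truth = hx.simulate_library(cfg, out / "reads.sam", seed=11)
    return {
        "refs": small_refs,
        "model": model,
        "cfg": cfg,
        "sam": out / "reads.sam",
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_profile(small_sim):
    reads = hx.filter_reads(hx.parse_sam(small_sim["sam"]), hx.FilterConfig())
    return hx.profile_reads(reads, small_sim["refs"])


def _simulate_large(seed: int, out_dir: Path, second_strand: str = "default"):
    model = hx.default_error_model(seed=seed, second_strand=second_strand)
    refs = hx.simulate_references(N_REFS, seed=seed)
    cfg = hx.LibraryConfig(n_read_pairs=N_PAIRS_LARGE, references=refs, model=model)
    sam = out_dir / f"reads_{seed}.sam"
    truth = hx.simulate_library(cfg, sam, seed=seed)
    return {"refs": refs, "model": model, "cfg": cfg, "sam": sam, "truth": truth}


@pytest.fixture(scope="session")
def large_runs(tmp_path_factory):
    """Three independent full-scale runs of the default model, profiled."""
    out = tmp_path_factory.mktemp("large_sims")
    runs = {}
    for seed in (101, 102, 103):
        run = _simulate_large(seed, out)
        reads = hx.filter_reads(hx.parse_sam(run["sam"]), hx.FilterConfig())
        run["profile"] = hx.profile_reads(reads, run["refs"])
        runs[seed] = run
    return runs


@pytest.fixture(scope="session")
def first_strand_only_run(tmp_path_factory):
    """Full-scale run with mispriming confined to first-strand synthesis."""
    out = tmp_path_factory.mktemp("fso_sim")
    run = _simulate_large(104, out, second_strand="background")
    reads = hx.filter_reads(hx.parse_sam(run["sam"]), hx.FilterConfig())
    run["profile"] = hx.profile_reads(reads, run["refs"])
    return run
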