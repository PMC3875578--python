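"""High-level pipeline drivers and report writers.

These functions tie the stages together — parse, filter, profile,
summarise, serialise — and are exactly what the command-line interface
calls; running them directly from Python gives byte-identical outputs.
"""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .alignment_io import FilterConfig, FilterStats, filter_reads, load_references, parse_sam
from .dataset_compare import ComparisonResult, correlate_windows, distribution_matrix
from .mismatch_profile import (
    PositionProfileSet,
    distributions_to_tsv,
    headline_stats,
    headline_to_json,
    per_template_to_tsv,
    profile_from_tsv,
    profile_reads,
    profile_to_tsv,
    rates_to_tsv,
)
from .strand_coords import StrandClass

__all__ = ["ProfileRun", "run_profile", "run_compare"]

log = logging.getLogger("hexprime")


def _setup_logging(out_dir: Path, level: str = "INFO") -> None:
    log.setLevel(level.upper())
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (
        logging.StreamHandler(),
        logging.FileHandler(out_dir / "run.log", mode="w"),
    ):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def _echo_config(out_dir: Path, config: dict) -> None:
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


@dataclass
class ProfileRun:
    """Outcome of one profiling run: the profile, stats and output paths."""

    profile: PositionProfileSet
    stats: "object"
    filter_stats: FilterStats
    n_rejects: int
    out_dir: Path


def run_profile(
    sam: str | Path,
    ref: str | Path | None,
    out_dir: str | Path,
    *,
    filter_cfg: FilterConfig | None = None,
    hexamer_end: int = 7,
    downstream_from: int = 8,
    mates: str = "both",
    start_by: str = "reference",
    panel_positions: tuple[int, ...] = (1, 3, 15, 50),
    plot: bool = False,
    log_level: str = "INFO",
) -> ProfileRun:
    """Profile a SAM file against known references and write all reports.

    Writes into ``out_dir``: profile.tsv (the count tensor),
    rate_by_position.tsv, distributions.tsv, per_template_panels.tsv,
    headline.json, filter_stats.tsv, rejects.tsv, config.yaml and run.log;
    optional rate/panel figures with ``plot=True``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, log_level)
    if filter_cfg is None:
        filter_cfg = FilterConfig()
    _echo_config(
        out,
        {
            "subcommand": "profile",
            "sam": str(sam),
            "ref": str(ref) if ref else None,
            "filter": asdict(filter_cfg),
            "hexamer_region": [1, hexamer_end],
            "downstream_from": downstream_from,
            "mates": mates,
            "start_by": start_by,
        },
    )

    refs = load_references(ref) if ref else None
    rejects: list = []
    fstats = FilterStats()
    reads = filter_reads(parse_sam(sam, rejects=rejects), filter_cfg, fstats)
    profile = profile_reads(
        reads, refs, min_base_quality=filter_cfg.min_base_quality, mates=mates
    )
    stats = headline_stats(
        profile,
        hexamer_region=(1, hexamer_end),
        downstream_from=downstream_from,
        start_by=start_by,
    )

    log.info("parsed %d records (%d malformed lines skipped)", fstats.n_in, len(rejects))
    log.info(
        "filters passed %d reads (%s)",
        fstats.n_out,
        ", ".join(f"{k}={v}" for k, v in fstats.rejected.items()) or "no rejections",
    )
    for s in StrandClass:
        log.info("%s: %d reads profiled", s.value, profile.n_reads[s])
    if fstats.n_in == 0:
        log.warning("input SAM contained no alignment records")

    profile_to_tsv(profile, out / "profile.tsv")
    rates_to_tsv(profile, out / "rate_by_position.tsv")
    distributions_to_tsv(profile, out / "distributions.tsv")
    per_template_to_tsv(profile, out / "per_template_panels.tsv", panel_positions)
    headline_to_json(stats, out / "headline.json")
    fstats.to_tsv(out / "filter_stats.tsv")
    with open(out / "rejects.tsv", "w") as fh:
        fh.write("line_number\treason\n")
        for line_number, reason in rejects:
            fh.write(f"{line_number}\t{reason}\n")
    if plot:
        from . import plots

        plots.plot_rate_by_position(profile, out / "rate_by_position.png")
        plots.plot_per_template_panels(
            profile, out / "per_template_panels.png", panel_positions
        )
    return ProfileRun(
        profile=profile,
        stats=stats,
        filter_stats=fstats,
        n_rejects=len(rejects),
        out_dir=out,
    )


def run_compare(
    profile_a: str | Path,
    profile_b: str | Path,
    out_dir: str | Path,
    *,
    window_a: tuple[int, int] = (1, 6),
    window_b: tuple[int, int] = (7, 20),
    strand: StrandClass = StrandClass.FIRST_STRAND,
    log_level: str = "INFO",
) -> ComparisonResult:
    """Compare two profile TSVs and write the correlation report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, log_level)
    _echo_config(
        out,
        {
            "subcommand": "compare",
            "profile_a": str(profile_a),
            "profile_b": str(profile_b),
            "window_a": list(window_a),
            "window_b": list(window_b),
            "strand": strand.value,
        },
    )
    pa = profile_from_tsv(profile_a)
    pb = profile_from_tsv(profile_b)
    hi = max(window_a[1], window_b[1], pa.max_position(strand), pb.max_position(strand))
    ma = distribution_matrix(pa, strand, range(1, hi + 1))
    mb = distribution_matrix(pb, strand, range(1, hi + 1))
    result = correlate_windows(ma, mb, window_a, window_b)
    if result.n_a == 0 and result.n_b == 0:
        log.warning("no overlapping positions with mismatches in either window")
    log.info(
        "window %s: pearson r=%s over %d pairs; window %s: pearson r=%s over %d pairs",
        window_a,
        result.r_a,
        result.n_a,
        window_b,
        result.r_b,
        result.n_b,
    )
    result.to_json(out / "comparison.json")
    result.pairs_to_tsv(out / "pairs.tsv")
    return result
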