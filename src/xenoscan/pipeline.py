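"""End-to-end orchestration: scan → GC tiling → operons → regulon report.

Each stage writes its artifacts with the full effective configuration in the
header; timestamps go to the log only, so the data files are diffable across
reruns.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Sequence, Union

from .config import RunConfig
from .gc import low_gc_intervals, tile_gc, write_gc_tsv
from .io import read_fasta, read_gff
from .motifs import (
    MotifPattern,
    two_pass_scan,
    write_pfm_tsv,
    write_sites_bed,
    write_sites_tsv,
)
from .regulon import (
    RegulonReport,
    flag_operons,
    infer_operons,
    write_operons_gff,
    write_report_tsv,
)

__all__ = ["run_end_to_end"]

logger = logging.getLogger(__name__)


def run_end_to_end(
    config: RunConfig,
    fasta: Union[str, Path],
    outdir: Union[str, Path],
    gff: Union[str, Path, None] = None,
    skip_regulon: bool = False,
) -> RegulonReport | None:
    """Run scan, GC profiling and (optionally) the regulon stage.

    Writes sites (BED6 + TSV), the PFM count table, the refined pattern, the
    per-window GC table, low-GC interval BEDs, and — when a GFF is supplied
    and the regulon stage is not skipped — the operon GFF and the regulon
    report with its one-line summary.  Returns the report (or ``None`` when
    the regulon stage did not run).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hdr = config.header_lines()

    t0 = time.monotonic()
    genomes = read_fasta(fasta)
    logger.info("read %d sequence(s) from %s", len(genomes), fasta)

    seed = MotifPattern(config.seed_pattern, config.max_mismatches)
    refined, sites, pfm = two_pass_scan(
        genomes, seed, base_threshold=config.consensus_threshold
    )
    logger.info(
        "two-pass scan: %d first-pass sites in PFM, refined pattern %s, %d final sites (%.2fs)",
        pfm.n_sites + pfm.n_excluded, refined.iupac, len(sites), time.monotonic() - t0,
    )
    write_sites_bed(sites, outdir / "sites.bed", refined)
    write_sites_tsv(sites, outdir / "sites.tsv", refined, header_lines=hdr)
    write_pfm_tsv(pfm, outdir / "pfm.tsv")
    (outdir / "refined_pattern.txt").write_text(refined.iupac + "\n")

    all_windows = []
    low_gc_by_contig: dict[str, list[tuple[int, int]]] = {}
    for g in genomes:
        windows = tile_gc(g, width=config.gc_window, threshold=config.gc_threshold)
        all_windows.extend(windows)
        low_gc_by_contig[g.id] = low_gc_intervals(windows)
    write_gc_tsv(all_windows, outdir / "gc_windows.tsv", header_lines=hdr)
    with open(outdir / "low_gc.bed", "w") as fh:
        for cid, intervals in low_gc_by_contig.items():
            for a, b in intervals:
                fh.write(f"{cid}\t{a}\t{b}\n")
    logger.info(
        "GC tiling: %d windows, %d flagged low-GC",
        len(all_windows), sum(w.flagged_low for w in all_windows),
    )

    if skip_regulon:
        return None
    if gff is None:
        raise ValueError("regulon stage requested but no GFF given; pass gff= or skip_regulon=True")

    features = read_gff(gff)
    operons = infer_operons(features, max_gap=config.operon_max_gap)
    report = flag_operons(
        operons, sites, low_gc_by_contig, total_genes=len(features), upstream=config.upstream
    )
    write_operons_gff(operons, outdir / "operons.gff", header_lines=hdr)
    write_report_tsv(report, outdir / "regulon_report.tsv", header_lines=hdr)
    summary = (
        f"total_genes={report.total_genes} affected_genes={len(report.affected_genes)} "
        f"affected_fraction={report.affected_fraction:.1f}"
    )
    (outdir / "summary.txt").write_text(summary + "\n")
    logger.info("regulon: %s", summary)
    return report
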