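"""Operon inference and the union rule for calling putatively H-NS-affected genes.

An operon here is a run of co-directional, closely spaced genes (intergenic
gap at most ``max_gap``; overlapping same-strand genes always merge).  An
operon is called *affected* if a binding site falls within its span or
within an upstream promoter window 5' of its first gene (strand-aware), OR
if its span overlaps any low-GC interval — the union of direct-site and
compositional evidence.  The headline quantity is the affected-gene
fraction: the percentage of all annotated genes that belong to affected
operons.

Both the operon gap and the upstream window are exposed parameters and are
echoed into output headers, since affected-gene fractions are sensitive to
them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

from .io import GeneFeature
from .motifs import SiteHit

__all__ = [
    "Operon",
    "RegulonReport",
    "infer_operons",
    "flag_operons",
    "affected_gene_fraction",
    "write_operons_gff",
    "write_report_tsv",
]


@dataclass(frozen=True)
class Operon:
    id: str
    contig_id: str
    gene_ids: tuple[str, ...]
    start: int
    end: int
    strand: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class RegulonReport:
    """Per-operon affection flags and the aggregate affected-gene fraction."""

    operons: list[Operon]
    hit_by_site: dict[str, bool]
    overlaps_low_gc: dict[str, bool]
    total_genes: int
    upstream: int = 250

    @property
    def affected_operons(self) -> list[Operon]:
        return [
            op
            for op in self.operons
            if self.hit_by_site[op.id] or self.overlaps_low_gc[op.id]
        ]

    @property
    def affected_genes(self) -> list[str]:
        out: list[str] = []
        for op in self.affected_operons:
            out.extend(op.gene_ids)
        return out

    @property
    def affected_fraction(self) -> float:
        return affected_gene_fraction(self)


def infer_operons(features: Sequence[GeneFeature], max_gap: int = 100) -> list[Operon]:
    """Group consecutive co-directional genes with gaps <= ``max_gap`` into operons.

    Features are processed per contig in start order; a gene on the opposite
    strand breaks a run.  Overlapping same-strand genes merge regardless of
    the gap parameter.  Every gene lands in exactly one operon; isolated
    genes become one-gene operons.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    ordered = sorted(features, key=lambda f: (f.contig_id, f.start))
    operons: list[Operon] = []
    run: list[GeneFeature] = []

    def close_run() -> None:
        if not run:
            return
        op_id = f"operon_{len(operons) + 1:04d}"
        operons.append(
            Operon(
                id=op_id,
                contig_id=run[0].contig_id,
                gene_ids=tuple(f.id for f in run),
                start=run[0].start,
                end=max(f.end for f in run),
                strand=run[0].strand,
            )
        )
        run.clear()

    for f in ordered:
        if run and (
            f.contig_id != run[-1].contig_id
            or f.strand != run[-1].strand
            or f.start - max(g.end for g in run) > max_gap
        ):
            close_run()
        run.append(f)
    close_run()
    return operons


def flag_operons(
    operons: Sequence[Operon],
    sites: Sequence[SiteHit],
    low_gc: Sequence[tuple[int, int]] | dict[str, Sequence[tuple[int, int]]],
    total_genes: int | None = None,
    upstream: int = 250,
) -> RegulonReport:
    """Apply the union rule: site-in-span-or-promoter OR low-GC-overlap.

    A site is attributed to an operon if its start lies inside the operon
    span, or within ``upstream`` bp 5' of the first gene — upstream of the
    span start for a plus-strand operon, downstream of the span end for a
    minus-strand one.  Low-GC association is any (>= 1 bp) span overlap.
    ``low_gc`` may be a per-contig dict or a flat interval list applied to
    every contig.
    """
    if upstream < 0:
        raise ValueError(f"upstream must be >= 0, got {upstream}")
    if total_genes is None:
        total_genes = sum(len(op) for op in operons)

    if isinstance(low_gc, dict):
        intervals_for = lambda cid: low_gc.get(cid, [])
    else:
        intervals_for = lambda cid: low_gc

    sites_by_contig: dict[str, list[int]] = {}
    for s in sites:
        sites_by_contig.setdefault(s.contig_id, []).append(s.start)

    hit_by_site: dict[str, bool] = {}
    overlaps_low_gc: dict[str, bool] = {}
    for op in operons:
        if op.strand == "+":
            lo, hi = op.start - upstream, op.end
        else:
            lo, hi = op.start, op.end + upstream
        starts = sites_by_contig.get(op.contig_id, [])
        hit_by_site[op.id] = any(lo <= p < hi for p in starts)
        overlaps_low_gc[op.id] = any(
            a < op.end and op.start < b for a, b in intervals_for(op.contig_id)
        )

    return RegulonReport(
        operons=list(operons),
        hit_by_site=hit_by_site,
        overlaps_low_gc=overlaps_low_gc,
        total_genes=total_genes,
        upstream=upstream,
    )


def affected_gene_fraction(report: RegulonReport) -> float:
    """Percentage of all genes that belong to affected operons."""
    if report.total_genes <= 0:
        raise ValueError("affected fraction undefined: zero genes")
    return 100.0 * len(report.affected_genes) / report.total_genes


def write_operons_gff(
    operons: Iterable[Operon], path: Union[str, Path], header_lines: Iterable[str] = ()
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in header_lines:
            fh.write(f"#{line}\n")
        for op in operons:
            genes = ",".join(op.gene_ids)
            fh.write(
                f"{op.contig_id}\txenoscan\toperon\t{op.start + 1}\t{op.end}"
                f"\t.\t{op.strand}\t.\tID={op.id};genes={genes}\n"
            )


def write_report_tsv(
    report: RegulonReport, path: Union[str, Path], header_lines: Iterable[str] = ()
) -> None:
    """Per-operon flag table plus a one-line summary footer."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("operon\tcontig\tstart\tend\tstrand\tn_genes\thit_by_site\toverlaps_low_gc\taffected\tgenes\n")
        for op in report.operons:
            hs = report.hit_by_site[op.id]
            lg = report.overlaps_low_gc[op.id]
            fh.write(
                f"{op.id}\t{op.contig_id}\t{op.start}\t{op.end}\t{op.strand}\t{len(op)}"
                f"\t{int(hs)}\t{int(lg)}\t{int(hs or lg)}\t{','.join(op.gene_ids)}\n"
            )
        fh.write(
            f"# summary: total_genes={report.total_genes}"
            f" affected_genes={len(report.affected_genes)}"
            f" affected_fraction={report.affected_fraction:.1f}\n"
        )
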