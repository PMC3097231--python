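"""Fixed-width GC-content tiling and extraction of low-GC intervals.

H-NS silencing targets AT-rich (low-GC) DNA, so regions whose 1-kb tiles fall
below a GC threshold (default: strictly less than 55%) are candidate
silencer-associated intervals, to be combined with direct binding-site hits.

Tiles are consecutive and non-overlapping, phased at position 0.  The
trailing partial tile is retained iff it is at least half the tile width,
with its GC computed over its actual length; shorter remainders are dropped
as too noisy to call.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

from .io import GenomeRecord, gc_percent

__all__ = ["GCWindow", "tile_gc", "low_gc_intervals", "write_gc_tsv", "write_intervals_bed"]


@dataclass(frozen=True)
class GCWindow:
    """One GC tile; ``flagged_low`` iff ``gc`` is strictly below the threshold used."""

    contig_id: str
    start: int
    width: int
    gc: float
    flagged_low: bool

    @property
    def end(self) -> int:
        return self.start + self.width


def tile_gc(
    genome: GenomeRecord,
    width: int = 1000,
    threshold: float = 55.0,
    step: int | None = None,
) -> list[GCWindow]:
    """Tile a contig into GC windows and flag those below ``threshold``.

    ``step`` defaults to ``width`` (non-overlapping tiles); a smaller step
    gives sliding windows for sensitivity analysis.  With non-overlapping
    tiles, a trailing remainder of >= width/2 bp is kept as a final short
    window.  All-N windows (undefined GC) are skipped.
    """
    if width < 10:
        raise ValueError(f"window width must be >= 10 bp, got {width}")
    if step is None:
        step = width
    if step < 1 or step > width:
        raise ValueError(f"step must be in [1, width], got {step}")
    n = len(genome)
    if n < width // 2:
        raise ValueError(
            f"contig {genome.id!r} ({n} bp) shorter than half the window width ({width // 2} bp)"
        )
    windows: list[GCWindow] = []
    start = 0
    while start < n:
        end = min(start + width, n)
        w = end - start
        if w < width and (step != width or w < width // 2):
            break  # partial window: kept only for non-overlapping tiling and >= width/2
        chunk = genome.sequence[start:end]
        try:
            gc = gc_percent(chunk)
        except ValueError:
            start += step
            continue  # all-N window, GC undefined
        windows.append(
            GCWindow(genome.id, start, w, gc, flagged_low=gc < threshold)
        )
        if end == n:
            break
        start += step
    return windows


def low_gc_intervals(windows: Sequence[GCWindow]) -> list[tuple[int, int]]:
    """Merge maximal runs of flagged windows into half-open genomic intervals.

    Windows must come from one contig and be sorted by start; adjacent or
    overlapping flagged windows coalesce.
    """
    intervals: list[tuple[int, int]] = []
    for w in windows:
        if not w.flagged_low:
            continue
        if intervals and w.start <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], w.end))
        else:
            intervals.append((w.start, w.end))
    return intervals


def write_gc_tsv(
    windows: Iterable[GCWindow], path: Union[str, Path], header_lines: Iterable[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("contig\tstart\tend\tgc\tflagged_low\n")
        for w in windows:
            fh.write(f"{w.contig_id}\t{w.start}\t{w.end}\t{w.gc:.1f}\t{int(w.flagged_low)}\n")


def write_intervals_bed(
    intervals: Iterable[tuple[int, int]], contig_id: str, path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        for start, end in intervals:
            fh.write(f"{contig_id}\t{start}\t{end}\n")
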