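"""Degenerate-pattern scanning with a mismatch budget and consensus refinement.

The procedure implemented here is the two-pass search used to map putative
H-NS (heat-stable nucleoid-structuring protein) binding sites on bacterial
and phage replicons:

1. scan the genome with a *seed* pattern — a characterised high-affinity
   H-NS site from a model proteobacterium — allowing a small mismatch budget
   (default 2) on both strands;
2. stack the hit sequences into a position frequency matrix (PFM), collapse
   it to a consensus in which columns without a dominant base become ``N``,
   and rescan with that refined pattern at zero mismatches (``N`` positions
   are free).

The refined consensus obtained this way on the *Ca.* Accumulibacter
phosphatis genome has the shape ``TCGANNAATT``: fixed flanks around a
two-base degenerate core.

Matching rules: an ``N`` (or any IUPAC code covering all four bases) in the
pattern matches any window base at zero cost; an ``N`` in the *genome* never
satisfies a fixed pattern position and counts as a mismatch.  The mismatch
budget applies to fixed (non-N) positions only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

from .io import GenomeRecord, revcomp

__all__ = [
    "MotifPattern",
    "SiteHit",
    "PositionFrequencyMatrix",
    "count_mismatches",
    "scan",
    "build_pfm",
    "consensus_from_pfm",
    "two_pass_scan",
    "write_sites_bed",
    "write_sites_tsv",
    "write_pfm_tsv",
]

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

BASES = "ACGT"


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate binding-site pattern with a mismatch budget.

    ``iupac`` may use the full IUPAC ambiguity alphabet; positions covering
    all four bases (``N``) are *free* and do not count toward the budget,
    which applies to the fixed positions only.
    """

    iupac: str
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        pat = self.iupac.upper()
        bad = set(pat) - set(IUPAC)
        if bad:
            raise ValueError(f"pattern {self.iupac!r}: invalid IUPAC characters {sorted(bad)!r}")
        if len(pat) < 4:
            raise ValueError(f"pattern {self.iupac!r}: length must be >= 4")
        n_fixed = sum(1 for c in pat if IUPAC[c] != IUPAC["N"])
        if n_fixed == 0:
            raise ValueError(f"pattern {self.iupac!r}: needs at least one non-N position")
        if self.max_mismatches < 0 or self.max_mismatches >= n_fixed:
            raise ValueError(
                f"pattern {self.iupac!r}: max_mismatches must be in [0, {n_fixed}), "
                f"got {self.max_mismatches}"
            )
        object.__setattr__(self, "iupac", pat)

    def __len__(self) -> int:
        return len(self.iupac)

    @property
    def fixed_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.iupac) if IUPAC[c] != IUPAC["N"])

    def reverse_complement(self) -> "MotifPattern":
        rc = self.iupac.translate(_IUPAC_COMPLEMENT)[::-1]
        return MotifPattern(rc, self.max_mismatches)


@dataclass(frozen=True)
class SiteHit:
    """One motif occurrence on a contig.

    ``start`` is the 0-based leftmost genome-forward coordinate of the window;
    for minus-strand hits ``matched_seq`` is stored in pattern orientation
    (i.e. the reverse complement of the genome-forward window).
    """

    contig_id: str
    start: int
    strand: str
    matched_seq: str
    mismatches: int

    @property
    def end(self) -> int:
        return self.start + len(self.matched_seq)


@dataclass
class PositionFrequencyMatrix:
    """Per-column A/C/G/T counts over a stack of aligned, equal-length hits."""

    counts: np.ndarray  # shape (4, L), rows in BASES order
    n_sites: int
    n_excluded: int = 0  # hits whose matched_seq contained N, kept out of counts

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def column(self, j: int) -> Mapping[str, int]:
        return {b: int(self.counts[i, j]) for i, b in enumerate(BASES)}

    def frequencies(self) -> np.ndarray:
        if self.n_sites == 0:
            raise ValueError("PFM has no contributing sites")
        return self.counts / float(self.n_sites)


def count_mismatches(window: str, pattern: MotifPattern) -> int:
    """Number of fixed pattern positions not satisfied by ``window``.

    ``N`` in the pattern is free; ``N`` in the window fails every fixed
    position (ambiguity is treated conservatively, never as a match).
    """
    if len(window) != len(pattern):
        raise ValueError(
            f"window length {len(window)} != pattern length {len(pattern)}"
        )
    w = window.upper()
    mism = 0
    for j in pattern.fixed_positions:
        if w[j] not in IUPAC[pattern.iupac[j]]:
            mism += 1
    return mism


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _mismatch_counts(seq: str, pattern: MotifPattern) -> np.ndarray:
    """Vectorised per-start mismatch counts on the forward strand of ``seq``."""
    n, L = len(seq), len(pattern)
    codes = _encode(seq)
    n_windows = n - L + 1
    mism = np.zeros(n_windows, dtype=np.int32)
    for j in pattern.fixed_positions:
        allowed = np.zeros(256, dtype=bool)
        for b in IUPAC[pattern.iupac[j]]:
            allowed[ord(b)] = True
        mism += ~allowed[codes[j : j + n_windows]]
    return mism


def scan(
    genome: GenomeRecord,
    pattern: MotifPattern,
    both_strands: bool = True,
    dedupe: bool = False,
) -> list[SiteHit]:
    """Report every window within the pattern's mismatch budget.

    Each start position on each requested strand is tested; hits are sorted
    by ``(start, strand)``.  A window matching on both strands (a
    pattern-palindromic site) yields two hits unless ``dedupe`` is set, in
    which case only the plus-strand hit is kept.
    """
    n, L = len(genome), len(pattern)
    if n < L:
        raise ValueError(
            f"genome {genome.id!r} ({n} bp) shorter than pattern ({L} bp)"
        )
    budget = pattern.max_mismatches
    seq = genome.sequence
    hits: list[SiteHit] = []

    fwd = _mismatch_counts(seq, pattern)
    for start in np.flatnonzero(fwd <= budget):
        s = int(start)
        hits.append(SiteHit(genome.id, s, "+", seq[s : s + L], int(fwd[s])))

    if both_strands:
        rc_seq = revcomp(seq)
        rev = _mismatch_counts(rc_seq, pattern)
        for p in np.flatnonzero(rev <= budget):
            p = int(p)
            start = n - p - L  # genome-forward coordinate of the window
            hits.append(SiteHit(genome.id, start, "-", rc_seq[p : p + L], int(rev[p])))

    if dedupe:
        plus_starts = {h.start for h in hits if h.strand == "+"}
        hits = [h for h in hits if h.strand == "+" or h.start not in plus_starts]

    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def build_pfm(hits: Sequence[SiteHit]) -> PositionFrequencyMatrix:
    """Tally hit sequences column-by-column into a PFM.

    Minus-strand hits must already carry pattern-oriented sequences (as
    produced by :func:`scan`).  Hits containing ``N`` are excluded from the
    counts and tallied in ``n_excluded``.
    """
    if not hits:
        raise ValueError("cannot build a PFM from an empty hit list")
    L = len(hits[0].matched_seq)
    for h in hits:
        if len(h.matched_seq) != L:
            raise ValueError(
                f"hit at {h.contig_id}:{h.start} has length {len(h.matched_seq)}, expected {L}"
            )
    counts = np.zeros((4, L), dtype=np.int64)
    base_row = {b: i for i, b in enumerate(BASES)}
    n_sites = 0
    n_excluded = 0
    for h in hits:
        seq = h.matched_seq.upper()
        if "N" in seq:
            n_excluded += 1
            continue
        for j, b in enumerate(seq):
            counts[base_row[b], j] += 1
        n_sites += 1
    return PositionFrequencyMatrix(counts=counts, n_sites=n_sites, n_excluded=n_excluded)


def consensus_from_pfm(
    pfm: PositionFrequencyMatrix, base_threshold: float = 0.65
) -> MotifPattern:
    """Collapse a PFM to a consensus pattern.

    Each column emits its majority base if that base's frequency is at least
    ``base_threshold``, otherwise ``N``.  Only plain bases and ``N`` are
    emitted (no two-fold IUPAC codes), matching the fixed-flanks-plus-N-core
    shape of the refined H-NS pattern.
    """
    if pfm.n_sites < 1:
        raise ValueError("consensus undefined: PFM has no contributing sites")
    freqs = pfm.frequencies()
    letters = []
    for j in range(pfm.length):
        i = int(np.argmax(freqs[:, j]))
        letters.append(BASES[i] if freqs[i, j] >= base_threshold else "N")
    return MotifPattern("".join(letters), max_mismatches=0)


def two_pass_scan(
    genomes: Union[GenomeRecord, Iterable[GenomeRecord]],
    seed_pattern: MotifPattern,
    base_threshold: float = 0.65,
    both_strands: bool = True,
) -> tuple[MotifPattern, list[SiteHit], PositionFrequencyMatrix]:
    """Seed scan → PFM → consensus → zero-mismatch rescan.

    Pass 1 scans every genome with ``seed_pattern`` at its mismatch budget;
    the hits define a PFM whose consensus (``N`` where no base dominates)
    becomes the refined pattern, which pass 2 rescans at 0 mismatches.
    Returns ``(refined_pattern, final_sites, pfm)``.
    """
    if isinstance(genomes, GenomeRecord):
        genomes = [genomes]
    genomes = list(genomes)

    pass1: list[SiteHit] = []
    for g in genomes:
        pass1.extend(scan(g, seed_pattern, both_strands=both_strands))
    if not pass1:
        raise ValueError(
            "first-pass scan found no sites; increase max_mismatches on the seed pattern"
        )
    pfm = build_pfm(pass1)
    refined = consensus_from_pfm(pfm, base_threshold=base_threshold)

    final: list[SiteHit] = []
    for g in genomes:
        final.extend(scan(g, refined, both_strands=both_strands))
    return refined, final, pfm


def write_sites_bed(
    hits: Iterable[SiteHit], path: Union[str, Path], pattern: MotifPattern
) -> None:
    """BED6: chrom, start, end, pattern string, mismatch count as score, strand."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.contig_id}\t{h.start}\t{h.end}\t{pattern.iupac}\t{h.mismatches}\t{h.strand}\n"
            )


def write_sites_tsv(
    hits: Iterable[SiteHit],
    path: Union[str, Path],
    pattern: MotifPattern,
    header_lines: Iterable[str] = (),
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("contig\tstart\tend\tpattern\tmismatches\tstrand\tmatched_seq\n")
        for h in hits:
            fh.write(
                f"{h.contig_id}\t{h.start}\t{h.end}\t{pattern.iupac}"
                f"\t{h.mismatches}\t{h.strand}\t{h.matched_seq}\n"
            )


def write_pfm_tsv(pfm: PositionFrequencyMatrix, path: Union[str, Path]) -> None:
    """4 x L tab-separated count table, one row per base."""
    with open(path, "w") as fh:
        fh.write("base\t" + "\t".join(str(j + 1) for j in range(pfm.length)) + "\n")
        for i, b in enumerate(BASES):
            fh.write(b + "\t" + "\t".join(str(int(c)) for c in pfm.counts[i]) + "\n")
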