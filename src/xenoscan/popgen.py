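"""Pairwise genotype comparison: windowed SNP frequency and Nei-Gojobori dN/dS.

Two co-occurring genotypes of one phage population are compared through a
gap-free (or gapped) pairwise alignment.  Two statistics are computed:

* a per-window SNP frequency track — percent mismatching bases in
  consecutive windows (default 250 alignment columns), with gap/N columns
  and user-masked regions (e.g. a non-homologous replacement region)
  excluded from both numerator and denominator;

* per-ORF dN/dS by the Nei-Gojobori counting method: per-codon synonymous
  site fractions (the fraction of the three possible point changes at each
  position that preserve the amino acid, nonsense changes excluded from the
  fraction), sites averaged between the two sequences, differences averaged
  over all minimal mutational pathways that avoid stop codons, and
  Jukes-Cantor correction d = -3/4 ln(1 - 4p/3) applied to the proportions.
  dN/dS < 1 indicates purifying selection, ~1 neutrality, > 1 diversifying
  selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .io import GeneFeature, revcomp

__all__ = [
    "PairwiseAlignment",
    "SNPWindow",
    "SNPWindowTrack",
    "NGCounts",
    "DnDsResult",
    "snp_window_track",
    "nei_gojobori_counts",
    "dn_ds",
    "orf_dn_ds",
    "write_track_tsv",
    "write_dnds_tsv",
]

_STOPS = frozenset(standard_dna_table.stop_codons)
_CODON_AA = dict(standard_dna_table.forward_table)
_CODON_AA.update({c: "*" for c in _STOPS})

MIN_COMPARABLE = 50  # windows with fewer comparable columns are reported missing


@dataclass
class PairwiseAlignment:
    """Two aligned sequences of equal length over {A,C,G,T,N,-}.

    ``mask`` lists half-open intervals in alignment coordinates excluded from
    every statistic (regions where the genotypes are not homologous).
    """

    seq1: str
    seq2: str
    mask: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq1 = self.seq1.upper()
        self.seq2 = self.seq2.upper()
        if len(self.seq1) != len(self.seq2):
            raise ValueError(
                f"aligned sequences differ in length: {len(self.seq1)} vs {len(self.seq2)}"
            )
        alphabet = set("ACGTN-")
        for name, s in (("seq1", self.seq1), ("seq2", self.seq2)):
            bad = set(s) - alphabet
            if bad:
                raise ValueError(f"{name}: invalid characters {sorted(bad)!r}")
        for a, b in self.mask:
            if not (0 <= a <= b <= len(self.seq1)):
                raise ValueError(f"mask interval [{a}, {b}) out of alignment bounds")

    def __len__(self) -> int:
        return len(self.seq1)

    def comparable_columns(self) -> np.ndarray:
        """Boolean array: column has an unambiguous base in both sequences and is unmasked."""
        a1 = np.frombuffer(self.seq1.encode(), dtype=np.uint8)
        a2 = np.frombuffer(self.seq2.encode(), dtype=np.uint8)
        good = np.ones(256, dtype=bool)
        for ch in "N-":
            good[ord(ch)] = False
        ok = good[a1] & good[a2]
        for a, b in self.mask:
            ok[a:b] = False
        return ok

    def mismatch_columns(self) -> np.ndarray:
        a1 = np.frombuffer(self.seq1.encode(), dtype=np.uint8)
        a2 = np.frombuffer(self.seq2.encode(), dtype=np.uint8)
        return self.comparable_columns() & (a1 != a2)


@dataclass(frozen=True)
class SNPWindow:
    start: int
    end: int
    comparable: int
    mismatches: int
    percent: float | None  # None when too few comparable columns


@dataclass
class SNPWindowTrack:
    window: int
    windows: list[SNPWindow]

    @property
    def total_mismatches(self) -> int:
        return sum(w.mismatches for w in self.windows)


def snp_window_track(aln: PairwiseAlignment, window: int = 250) -> SNPWindowTrack:
    """Percent mismatching bases in consecutive non-overlapping windows.

    Windows are laid out in alignment coordinates; columns with a gap or
    ``N`` in either sequence, or inside a mask interval, count toward
    neither mismatches nor comparable columns.  Windows with fewer than
    50 comparable columns get ``percent=None``.  If ``window`` exceeds the
    alignment length, the whole alignment is a single window.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    n = len(aln)
    comparable = aln.comparable_columns()
    mismatch = aln.mismatch_columns()
    if window > n:
        window_starts = [0]
        width = n
    else:
        window_starts = list(range(0, n, window))
        width = window
    out: list[SNPWindow] = []
    for start in window_starts:
        end = min(start + width, n)
        comp = int(comparable[start:end].sum())
        mism = int(mismatch[start:end].sum())
        pct = 100.0 * mism / comp if comp >= MIN_COMPARABLE else None
        out.append(SNPWindow(start, end, comp, mism, pct))
    return SNPWindowTrack(window=window, windows=out)


@dataclass(frozen=True)
class NGCounts:
    """Nei-Gojobori site and difference counts for one sequence pair."""

    N: float  # nonsynonymous sites
    S: float  # synonymous sites
    Nd: float  # nonsynonymous differences
    Sd: float  # synonymous differences
    codons_compared: int = 0


def _codon_site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each position contributes one site, split by the fraction of its three
    possible point changes that are synonymous; changes creating a stop
    codon are excluded from the fraction (nonsense changes are ignored).
    """
    aa = _CODON_AA[codon]
    s_total = 0.0
    for i in range(3):
        syn = 0
        valid = 0
        for b in "ACGT":
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1 :]
            if mutant in _STOPS:
                continue
            valid += 1
            if _CODON_AA[mutant] == aa:
                syn += 1
        s_total += syn / valid if valid else 0.0
    return s_total, 3.0 - s_total


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaged over minimal mutational pathways.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked, all pathways are used with stop-traversing steps counted as
    nonsynonymous.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        sd = nd = 0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS and not allow_stops:
                return None
            if _CODON_AA[cur] == _CODON_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return float(sd), float(nd)

    paths = [walk(order, allow_stops=False) for order in permutations(diff)]
    valid = [p for p in paths if p is not None]
    if not valid:
        valid = [walk(order, allow_stops=True) for order in permutations(diff)]
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    return sd, nd


def _iter_codons(seq: str) -> list[str]:
    if len(seq) % 3 != 0:
        raise ValueError(f"coding sequence length {len(seq)} is not a multiple of 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def nei_gojobori_counts(codons1: str, codons2: str) -> NGCounts:
    """Nei-Gojobori site and difference counts for an aligned coding pair.

    Codon pairs where either codon contains ``N`` or ``-`` are skipped; site
    counts are averaged between the two sequences; a premature (non-terminal)
    stop codon raises, a shared terminal stop is skipped.
    """
    cs1, cs2 = _iter_codons(codons1.upper()), _iter_codons(codons2.upper())
    if len(cs1) != len(cs2):
        raise ValueError(f"coding sequences differ in codon count: {len(cs1)} vs {len(cs2)}")
    S = N = Sd = Nd = 0.0
    compared = 0
    last = len(cs1) - 1
    for i, (c1, c2) in enumerate(zip(cs1, cs2)):
        if set(c1 + c2) - set("ACGT"):
            continue  # ambiguous or gapped codon pair, skipped
        if c1 in _STOPS or c2 in _STOPS:
            if i == last:
                continue  # terminal stop codon, not part of the coding comparison
            raise ValueError(f"premature stop codon at codon index {i}")
        s1, n1 = _codon_site_fractions(c1)
        s2, n2 = _codon_site_fractions(c2)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = _pathway_differences(c1, c2)
        Sd += sd
        Nd += nd
        compared += 1
    return NGCounts(N=N, S=S, Nd=Nd, Sd=Sd, codons_compared=compared)


@dataclass(frozen=True)
class DnDsResult:
    """Corrected substitution rates and their ratio for one ORF pair.

    ``dN``, ``dS`` or ``ratio`` are ``nan`` where undefined (dS = 0, or a
    proportion at or beyond the Jukes-Cantor saturation point 3/4; the raw
    proportions are always retained).
    """

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    ratio: float
    correction: str = "jukes_cantor"


def _jc_distance(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def dn_ds(counts: NGCounts, correction: str = "jukes_cantor") -> DnDsResult:
    """Turn NG counts into (corrected) rates and the dN/dS ratio."""
    if correction not in ("none", "jukes_cantor"):
        raise ValueError(f"unknown correction {correction!r}")
    if min(counts.N, counts.S, counts.Nd, counts.Sd) < 0:
        raise ValueError("negative counts")
    if counts.S <= 0 or counts.N <= 0:
        raise ValueError("need S > 0 and N > 0 to compute rates")
    pS = counts.Sd / counts.S
    pN = counts.Nd / counts.N
    if correction == "jukes_cantor":
        dS = _jc_distance(pS)
        dN = _jc_distance(pN)
    else:
        dS, dN = pS, pN
    ratio = dN / dS if (not math.isnan(dS) and not math.isnan(dN) and dS > 0) else math.nan
    return DnDsResult(
        S=counts.S, N=counts.N, Sd=counts.Sd, Nd=counts.Nd,
        pS=pS, pN=pN, dS=dS, dN=dN, ratio=ratio, correction=correction,
    )


def orf_dn_ds(
    aln: PairwiseAlignment,
    features: Sequence[GeneFeature],
    correction: str = "jukes_cantor",
) -> list[tuple[GeneFeature, DnDsResult]]:
    """Per-ORF dN/dS over a pairwise alignment.

    Feature coordinates are taken in alignment coordinates; minus-strand
    ORFs are reverse-complemented before codon comparison.  ORFs whose
    length is not a multiple of 3, or with no countable codons, are skipped.
    """
    out: list[tuple[GeneFeature, DnDsResult]] = []
    for f in features:
        s1 = aln.seq1[f.start : f.end].replace("-", "N")
        s2 = aln.seq2[f.start : f.end].replace("-", "N")
        if f.strand == "-":
            s1 = revcomp(s1)
            s2 = revcomp(s2)
        if len(s1) % 3 != 0:
            continue
        counts = nei_gojobori_counts(s1, s2)
        if counts.S <= 0 or counts.N <= 0:
            continue
        out.append((f, dn_ds(counts, correction=correction)))
    return out


def write_track_tsv(
    track: SNPWindowTrack, path: Union[str, Path], header_lines: Iterable[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("start\tend\tcomparable\tmismatches\tpercent\n")
        for w in track.windows:
            pct = f"{w.percent:.2f}" if w.percent is not None else "NA"
            fh.write(f"{w.start}\t{w.end}\t{w.comparable}\t{w.mismatches}\t{pct}\n")


def write_dnds_tsv(
    results: Sequence[tuple[GeneFeature, DnDsResult]],
    path: Union[str, Path],
    header_lines: Iterable[str] = (),
) -> None:
    def fmt(x: float) -> str:
        return "NA" if math.isnan(x) else f"{x:.4f}"

    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("orf\tstart\tend\tstrand\tS\tN\tSd\tNd\tdS\tdN\tratio\n")
        for f, r in results:
            fh.write(
                f"{f.id}\t{f.start}\t{f.end}\t{f.strand}\t{r.S:.2f}\t{r.N:.2f}"
                f"\t{r.Sd:.2f}\t{r.Nd:.2f}\t{fmt(r.dS)}\t{fmt(r.dN)}\t{fmt(r.ratio)}\n"
            )
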