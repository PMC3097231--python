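"""Synthetic genomes, genotype pairs and contig sets with ground-truth tables.

Every stage of the pipeline can be exercised without external data: this
module generates bacterial-like genomes with a tunable background GC, embedded
AT-rich islands, planted binding-site occurrences and a strand-aware
gene/operon layout; mutated genotype pairs with exact, verified counts of
synonymous / nonsynonymous / intergenic substitutions; and contig sets drawn
from k distinct base compositions.

The base model is i.i.d. (no dinucleotide structure), so tetranucleotide
separation between composition groups comes from GC content alone — which is
all the cluster-recovery tests need.  Planted sites overwrite the background
*after* island generation, so a site inside an island is preserved verbatim.
All generators are deterministic under a fixed seed.

Each truth-table entry can be re-verified against the emitted sequences:
:func:`verify_planted_sites` re-finds sites by string comparison and
:func:`verify_substitutions` re-checks every syn/nonsyn label against the
genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import GeneFeature, GenomeRecord, revcomp
from .popgen import _CODON_AA, _STOPS, PairwiseAlignment

__all__ = [
    "IslandSpec",
    "PlantedSite",
    "GeneLayoutSpec",
    "SyntheticGenomeSpec",
    "Substitution",
    "TruthTable",
    "simulate_genome",
    "simulate_genotype_pair",
    "simulate_contig_set",
    "verify_planted_sites",
    "verify_substitutions",
]

BASES = "ACGT"
_SENSE_CODONS = sorted(set(_CODON_AA) - _STOPS)


@dataclass(frozen=True)
class IslandSpec:
    """An AT-rich (or otherwise composition-shifted) island."""

    start: int
    length: int
    gc: float  # percent

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class PlantedSite:
    position: int
    sequence: str
    strand: str = "+"

    @property
    def end(self) -> int:
        return self.position + len(self.sequence)


@dataclass(frozen=True)
class GeneLayoutSpec:
    """Operon-structured gene layout.

    Genes are laid out as operons: runs of co-directional genes separated by
    short intra-operon gaps, with larger gaps (and possible strand switches)
    between operons.  Gene lengths are rounded to codon multiples so the
    genes double as ORFs.
    """

    n_operons: int = 10
    genes_per_operon: tuple[int, int] = (1, 4)
    gene_length: tuple[int, int] = (300, 900)
    intra_gap: tuple[int, int] = (10, 60)
    inter_gap: tuple[int, int] = (150, 400)
    strand_switch_prob: float = 0.5
    margin: int = 500  # bp left gene-free at the contig start


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    length: int = 50_000
    gc: float = 60.0  # background GC percent, high-GC betaproteobacterium-like
    islands: tuple[IslandSpec, ...] = ()
    sites: tuple[PlantedSite, ...] = ()
    genes: GeneLayoutSpec | None = None
    contig_id: str = "synthetic_1"
    seed: int = 0


@dataclass(frozen=True)
class Substitution:
    position: int  # genome coordinate of the changed base
    ref: str
    alt: str
    label: str  # "synonymous" | "nonsynonymous" | "intergenic"
    gene_id: str = ""


@dataclass
class TruthTable:
    """Ground truth emitted alongside every synthetic dataset."""

    sites: list[PlantedSite] = field(default_factory=list)
    islands: list[IslandSpec] = field(default_factory=list)
    operons: list[tuple[str, ...]] = field(default_factory=list)  # gene-id runs
    substitutions: list[Substitution] = field(default_factory=list)
    contig_labels: dict[str, int] = field(default_factory=dict)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    g = gc / 200.0  # per-base probability of G (and of C)
    a = (100.0 - gc) / 200.0
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=[a, g, g, a])


def simulate_genome(
    spec: SyntheticGenomeSpec,
) -> tuple[GenomeRecord, list[GeneFeature], TruthTable]:
    """Generate a genome, its gene annotation and the matching truth table.

    Background bases are drawn i.i.d. at the background GC; island segments
    are redrawn at their own GC; gene regions are sanitised to open reading
    frames (in-frame stop codons resampled); planted sites overwrite the
    sequence last and are preserved verbatim.  Deterministic under
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.length < 100:
        raise ValueError(f"genome length must be >= 100 bp, got {spec.length}")
    seq = _random_bases(rng, spec.length, spec.gc)

    for isl in spec.islands:
        if not (0 <= isl.start < isl.end <= spec.length):
            raise ValueError(f"island [{isl.start}, {isl.end}) out of genome bounds")
        seq[isl.start : isl.end] = _random_bases(rng, isl.length, isl.gc)

    features, operons = _layout_genes(rng, spec) if spec.genes else ([], [])
    site_cover = np.zeros(spec.length, dtype=bool)
    for site in spec.sites:
        if not (0 <= site.position < site.end <= spec.length):
            raise ValueError(f"planted site at {site.position} out of genome bounds")
        if site_cover[site.position : site.end].any():
            raise ValueError(f"planted sites overlap at position {site.position}")
        site_cover[site.position : site.end] = True

    for f in features:
        _sanitize_orf(rng, seq, f, site_cover)

    for site in spec.sites:
        planted = site.sequence if site.strand == "+" else revcomp(site.sequence)
        seq[site.position : site.end] = np.frombuffer(planted.encode(), dtype=np.uint8)

    genome = GenomeRecord(
        id=spec.contig_id, sequence=seq.tobytes().decode("ascii"), description="synthetic"
    )
    truth = TruthTable(
        sites=list(spec.sites), islands=list(spec.islands), operons=operons
    )
    return genome, features, truth


def _layout_genes(
    rng: np.random.Generator, spec: SyntheticGenomeSpec
) -> tuple[list[GeneFeature], list[tuple[str, ...]]]:
    lay = spec.genes
    assert lay is not None
    features: list[GeneFeature] = []
    operons: list[tuple[str, ...]] = []
    pos = lay.margin
    strand = "+"
    gene_no = 0
    for _ in range(lay.n_operons):
        if rng.random() < lay.strand_switch_prob:
            strand = "-" if strand == "+" else "+"
        n_genes = int(rng.integers(lay.genes_per_operon[0], lay.genes_per_operon[1] + 1))
        member_ids: list[str] = []
        for gi in range(n_genes):
            length = int(rng.integers(lay.gene_length[0], lay.gene_length[1] + 1))
            length -= length % 3
            if pos + length > spec.length - lay.margin:
                break
            gene_no += 1
            gid = f"gene_{gene_no:04d}"
            features.append(
                GeneFeature(
                    contig_id=spec.contig_id, start=pos, end=pos + length,
                    strand=strand, id=gid,
                )
            )
            member_ids.append(gid)
            pos += length
            if gi < n_genes - 1:
                pos += int(rng.integers(lay.intra_gap[0], lay.intra_gap[1] + 1))
        if member_ids:
            operons.append(tuple(member_ids))
        pos += int(rng.integers(lay.inter_gap[0], lay.inter_gap[1] + 1))
        if pos >= spec.length - lay.margin:
            break
    return features, operons


def _sanitize_orf(
    rng: np.random.Generator, seq: np.ndarray, f: GeneFeature, site_cover: np.ndarray
) -> None:
    """Resample in-frame stop codons so the gene is a clean ORF.

    Codons overlapping a planted-site footprint are left alone (the site
    sequence wins).
    """
    sub = seq[f.start : f.end].tobytes().decode("ascii")
    local = revcomp(sub) if f.strand == "-" else sub
    codons = [local[i : i + 3] for i in range(0, len(local), 3)]
    for ci, codon in enumerate(codons):
        if codon not in _STOPS:
            continue
        if f.strand == "+":
            g0 = f.start + 3 * ci
        else:
            g0 = f.end - 3 * (ci + 1)
        if site_cover[g0 : g0 + 3].any():
            continue
        repl = _SENSE_CODONS[int(rng.integers(len(_SENSE_CODONS)))]
        genome_codon = repl if f.strand == "+" else revcomp(repl)
        seq[g0 : g0 + 3] = np.frombuffer(genome_codon.encode(), dtype=np.uint8)


def _codon_positions(f: GeneFeature) -> int:
    return (f.end - f.start) // 3


def _gene_codon_to_genome(f: GeneFeature, codon_idx: int, offset: int) -> int:
    """Genome coordinate of base ``offset`` of codon ``codon_idx`` of gene ``f``."""
    if f.strand == "+":
        return f.start + 3 * codon_idx + offset
    return f.end - 1 - (3 * codon_idx + offset)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def simulate_genotype_pair(
    genome: GenomeRecord,
    orfs: Sequence[GeneFeature],
    n_syn: int,
    n_nonsyn: int,
    n_intergenic: int,
    seed: int = 0,
    intergenic_region: tuple[int, int] | None = None,
) -> tuple[PairwiseAlignment, TruthTable]:
    """Mutate a copy of ``genome`` with exact substitution counts by class.

    Exactly ``n_syn`` substitutions are placed at codon positions verified
    synonymous against the genetic code, ``n_nonsyn`` at verified
    nonsynonymous positions (never creating a stop codon), and
    ``n_intergenic`` outside all ORFs (optionally restricted to
    ``intergenic_region``).  At most one substitution lands in any codon, so
    every label is exact.  Returns the gap-free alignment and the truth.
    """
    rng = np.random.default_rng(seed)
    seq = list(genome.sequence)
    in_orf = np.zeros(len(seq), dtype=bool)
    for f in orfs:
        in_orf[f.start : f.end] = True

    # enumerate candidate (gene, codon) slots once, shuffle, then consume
    slots = [(f, ci) for f in orfs for ci in range(_codon_positions(f))]
    slots = [slots[i] for i in rng.permutation(len(slots))]

    subs: list[Substitution] = []
    used_codons: set[tuple[str, int]] = set()

    def codon_of(f: GeneFeature, ci: int) -> str:
        bases = [seq[_gene_codon_to_genome(f, ci, o)] for o in range(3)]
        if f.strand == "-":
            bases = [_COMP[b] for b in bases]
        return "".join(bases)

    def place(want_syn: bool, count: int, label: str) -> None:
        placed = 0
        for f, ci in slots:
            if placed == count:
                return
            if (f.id, ci) in used_codons:
                continue
            codon = codon_of(f, ci)
            if codon in _STOPS or "N" in codon:
                continue
            choices = []
            for off in range(3):
                for b in "ACGT":
                    if b == codon[off]:
                        continue
                    mut = codon[:off] + b + codon[off + 1 :]
                    if mut in _STOPS:
                        continue
                    syn = _CODON_AA[mut] == _CODON_AA[codon]
                    if syn == want_syn:
                        choices.append((off, b))
            if not choices:
                continue
            off, b = choices[int(rng.integers(len(choices)))]
            gpos = _gene_codon_to_genome(f, ci, off)
            genome_base = b if f.strand == "+" else _COMP[b]
            subs.append(
                Substitution(
                    position=gpos, ref=seq[gpos], alt=genome_base, label=label, gene_id=f.id
                )
            )
            seq[gpos] = genome_base
            used_codons.add((f.id, ci))
            placed += 1
        if placed < count:
            raise ValueError(
                f"cannot place {count} {label} substitutions; only {placed} positions available"
            )

    place(True, n_syn, "synonymous")
    place(False, n_nonsyn, "nonsynonymous")

    lo, hi = intergenic_region if intergenic_region else (0, len(seq))
    candidates = [
        i for i in range(lo, hi) if not in_orf[i] and genome.sequence[i] != "N"
    ]
    if n_intergenic > len(candidates):
        raise ValueError(
            f"cannot place {n_intergenic} intergenic substitutions; "
            f"only {len(candidates)} positions available"
        )
    for i in rng.choice(len(candidates), size=n_intergenic, replace=False):
        pos = candidates[int(i)]
        alt = BASES[int(rng.integers(4))]
        while alt == seq[pos]:
            alt = BASES[int(rng.integers(4))]
        subs.append(Substitution(position=pos, ref=seq[pos], alt=alt, label="intergenic"))
        seq[pos] = alt

    aln = PairwiseAlignment(seq1=genome.sequence, seq2="".join(seq))
    return aln, TruthTable(substitutions=subs)


def simulate_contig_set(
    k: int,
    contigs_per_group: int = 5,
    length: int = 6000,
    gc_values: Sequence[float] = (35.0, 55.0, 70.0),
    seed: int = 0,
) -> tuple[list[GenomeRecord], TruthTable]:
    """Contig sets drawn from ``k`` distinct base compositions.

    Group ``g`` contributes ``contigs_per_group`` contigs drawn i.i.d. at
    ``gc_values[g]``; truth labels record the generating group.  Degenerate
    (identical) compositions trigger a warning, not an error.
    """
    import logging

    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if length < 2000:
        raise ValueError(f"contig length must be >= 2000 bp, got {length}")
    if len(gc_values) < k:
        raise ValueError(f"need {k} composition values, got {len(gc_values)}")
    if len(set(gc_values[:k])) < k:
        logging.getLogger(__name__).warning(
            "composition specs are not all distinct; clusters will not be separable"
        )
    rng = np.random.default_rng(seed)
    records: list[GenomeRecord] = []
    truth = TruthTable()
    for g in range(k):
        for c in range(contigs_per_group):
            cid = f"group{g}_contig{c}"
            bases = _random_bases(rng, length, float(gc_values[g]))
            records.append(
                GenomeRecord(id=cid, sequence=bases.tobytes().decode("ascii"),
                             description="synthetic")
            )
            truth.contig_labels[cid] = g
    return records, truth


def verify_planted_sites(genome: GenomeRecord, truth: TruthTable) -> bool:
    """Re-find every planted site in the emitted sequence by direct comparison."""
    for site in truth.sites:
        expected = site.sequence if site.strand == "+" else revcomp(site.sequence)
        if genome.sequence[site.position : site.end] != expected:
            return False
    return True


def verify_substitutions(
    aln: PairwiseAlignment, orfs: Sequence[GeneFeature], truth: TruthTable
) -> bool:
    """Re-check every substitution's position, bases and syn/nonsyn label."""
    by_gene = {f.id: f for f in orfs}
    for sub in truth.substitutions:
        if aln.seq1[sub.position] != sub.ref or aln.seq2[sub.position] != sub.alt:
            return False
        if sub.label == "intergenic":
            if any(f.start <= sub.position < f.end for f in orfs):
                return False
            continue
        f = by_gene[sub.gene_id]
        if f.strand == "+":
            ci, off = divmod(sub.position - f.start, 3)
        else:
            ci, off = divmod(f.end - 1 - sub.position, 3)
        g0 = [_gene_codon_to_genome(f, ci, o) for o in range(3)]
        c_ref = "".join(aln.seq1[p] for p in g0)
        c_alt = "".join(aln.seq2[p] for p in g0)
        if f.strand == "-":
            c_ref = "".join(_COMP[b] for b in c_ref)
            c_alt = "".join(_COMP[b] for b in c_alt)
        syn = _CODON_AA[c_alt] == _CODON_AA[c_ref]
        if syn != (sub.label == "synonymous"):
            return False
    return True
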