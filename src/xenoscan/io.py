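"""Sequence and annotation I/O, coordinate conventions, and elementary sequence utilities.

All coordinates inside the package are 0-based half-open.  GFF3 (1-based,
inclusive) and BED (0-based, half-open) are converted only at the I/O
boundary, so no other module ever performs an off-by-one adjustment.

Ambiguous bases (``N``) are legal in genome sequences — draft contigs contain
them — but they are excluded from GC computation and are never matched by a
fixed (non-N) pattern position during motif scanning.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

__all__ = [
    "GenomeRecord",
    "GeneFeature",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "revcomp",
    "gc_percent",
]

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class GenomeRecord:
    """One named DNA sequence (contig or replicon).

    The sequence is uppercase over ``{A, C, G, T, N}``; case is normalised and
    the alphabet enforced on construction.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("GenomeRecord id must be non-empty")
        seq = self.sequence.upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid characters {sorted(bad)!r} "
                "(alphabet is A, C, G, T, N)"
            )
        if not seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class GeneFeature:
    """One annotated gene/CDS in internal 0-based half-open coordinates."""

    contig_id: str
    start: int
    end: int
    strand: str
    id: str = field(compare=False, default="")
    product: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.id!r}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.id!r}: strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def read_fasta(path: Union[str, Path]) -> list[GenomeRecord]:
    """Read a (multi-record) FASTA file into :class:`GenomeRecord` objects.

    Order is preserved, lowercase is normalised to uppercase, and ``U`` or any
    other non-DNA character is a hard error naming the offending record.
    Duplicate ids and empty files are also errors.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeRecord(id=rec.id, sequence=str(rec.seq), description=rec.description))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: Union[str, Path], width: int = 70) -> None:
    """Write records as wrapped FASTA; round-trips byte-exactly through :func:`read_fasta`."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_gff(
    path: Union[str, Path],
    feature_types: tuple[str, ...] = ("CDS", "gene"),
) -> list[GeneFeature]:
    """Read GFF3 rows of the requested feature types into internal coordinates.

    GFF3 is 1-based inclusive; the returned features are 0-based half-open
    (``start = gff_start - 1``, ``end = gff_end``) and sorted by
    ``(contig, start)``.  Malformed rows raise with the offending line number.
    """
    path = Path(path)
    features: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # malformed row
                raise ValueError(f"{path}:{lineno}: cannot parse GFF row ({exc})") from exc
            if feat.featuretype not in feature_types:
                continue
            if feat.strand not in ("+", "-"):
                raise ValueError(
                    f"{path}:{lineno}: strand must be '+' or '-', got {feat.strand!r}"
                )
            if feat.start > feat.end:
                raise ValueError(f"{path}:{lineno}: start {feat.start} > end {feat.end}")
            fid = feat.attributes.get("ID", [""])[0] or f"{feat.seqid}:{feat.start}-{feat.end}"
            product = feat.attributes.get("product", [""])[0]
            features.append(
                GeneFeature(
                    contig_id=feat.seqid,
                    start=feat.start - 1,
                    end=feat.end,
                    strand=feat.strand,
                    id=fid,
                    product=product,
                )
            )
    features.sort(key=lambda f: (f.contig_id, f.start))
    return features


def write_gff(
    features: Iterable[GeneFeature],
    path: Union[str, Path],
    source: str = "xenoscan",
    feature_type: str = "gene",
    header_lines: Iterable[str] = (),
) -> None:
    """Write features as GFF3, converting back to 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in header_lines:
            fh.write(f"#{line}\n")
        for f in features:
            attrs = f"ID={f.id}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(
                f"{f.contig_id}\t{source}\t{feature_type}\t{f.start + 1}\t{f.end}"
                f"\t.\t{f.strand}\t.\t{attrs}\n"
            )


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; ``N`` maps to ``N``."""
    bad = set(seq.upper()) - DNA_ALPHABET
    if bad:
        raise ValueError(f"invalid characters for reverse complement: {sorted(bad)!r}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    """GC content as a percentage in [0, 100].

    ``N`` bases are excluded from both numerator and denominator; a sequence
    consisting entirely of ``N`` (or empty) has undefined GC and raises.
    """
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("GC content undefined: no unambiguous bases in sequence")
    return 100.0 * gc / (gc + at)
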