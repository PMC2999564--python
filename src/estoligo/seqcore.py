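"""Sequence records, FASTA I/O, orientation handling and ORF extraction.

Everything downstream (assembly QC, probe design, simulation, selection)
works on :class:`SequenceRecord` collections read from FASTA.  ORF
extraction feeds target-annotation preparation: every maximal stop-free
codon run of at least ``min_aa`` codons in all six reading frames is
emitted as a peptide (stop-to-stop convention; no start codon required).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

SOURCES = ("sanger_ssh", "genbank_est", "contig", "singleton", "synthetic")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# IUPAC ambiguity codes other than N are collapsed to N on input.
_AMBIGUOUS = str.maketrans({c: "N" for c in "RYSWKMBDHV"})
_VALID = re.compile(r"^[ACGTN]*$")


class FastaParseError(ValueError):
    """Malformed FASTA input (empty sequence, bad residues, duplicate id)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One EST/contig/target: identifier, residues and source tag."""

    id: str
    seq: str
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaParseError("record with empty id")
        if not self.seq:
            raise FastaParseError(f"record {self.id!r} has empty sequence")
        if not _VALID.match(self.seq):
            bad = sorted(set(self.seq) - set("ACGTN"))
            raise FastaParseError(f"record {self.id!r} has invalid residues {bad}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source tag {self.source!r}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Peptide:
    """A translated stop-free codon run located on the forward strand.

    ``start_nt``/``end_nt`` are 0-based half-open forward-strand
    coordinates; for reverse frames they delimit the region whose reverse
    complement was translated.  ``frame`` is in {+1,+2,+3,-1,-2,-3}.
    """

    parent_id: str
    frame: int
    start_nt: int
    end_nt: int
    aa_seq: str

    def __post_init__(self) -> None:
        if self.end_nt - self.start_nt != 3 * len(self.aa_seq):
            raise ValueError("peptide span is not 3x its amino-acid length")


def normalize_seq(raw: str) -> str:
    """Upper-case, map U->T and collapse non-N ambiguity codes to N."""
    return raw.upper().replace("U", "T").translate(_AMBIGUOUS)


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    if not _VALID.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"cannot reverse-complement residues {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path, source: str = "synthetic") -> list[SequenceRecord]:
    """Read a multi-record FASTA file into :class:`SequenceRecord` objects.

    Residues are upper-cased, U is mapped to T and ambiguity codes to N.
    Duplicate identifiers and empty sequences are rejected with an error
    naming the offending record.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, normalize_seq(str(rec.seq)), source))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _runs(aa: str) -> Iterator[tuple[int, int]]:
    """Maximal stop-free runs as (start_codon, end_codon) half-open pairs."""
    start = 0
    for i, ch in enumerate(aa):
        if ch == "*":
            if i > start:
                yield start, i
            start = i + 1
    if len(aa) > start:
        yield start, len(aa)


def extract_orfs(record: SequenceRecord, min_aa: int = 5) -> list[Peptide]:
    """Six-frame stop-to-stop ORF extraction.

    For each frame every maximal run of non-stop codons with at least
    ``min_aa`` codons becomes a :class:`Peptide` (standard genetic code;
    codons containing N translate to X, which does not terminate a run).
    Records shorter than one codon yield an empty list.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    peptides: list[Peptide] = []
    n = record.length
    for strand, seq in ((+1, record.seq), (-1, reverse_complement(record.seq))):
        for off in range(3):
            ncod = (n - off) // 3
            if ncod < min_aa:
                continue
            sub = seq[off : off + 3 * ncod]
            aa = str(Seq(sub).translate(table=1))
            for a, b in _runs(aa):
                if b - a < min_aa:
                    continue
                s = off + 3 * a
                e = off + 3 * b
                if strand == +1:
                    start_nt, end_nt = s, e
                else:
                    start_nt, end_nt = n - e, n - s
                peptides.append(
                    Peptide(record.id, strand * (off + 1), start_nt, end_nt, aa[a:b])
                )
    return peptides


def write_peptides(peptides: Sequence[Peptide], path: str | Path) -> None:
    """Peptide FASTA with headers ``parentid|frame|start-end`` (1-based closed)."""
    with open(path, "w") as fh:
        for p in peptides:
            frame = f"+{p.frame}" if p.frame > 0 else str(p.frame)
            fh.write(f">{p.parent_id}|{frame}|{p.start_nt + 1}-{p.end_nt}\n{p.aa_seq}\n")
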