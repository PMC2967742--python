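"""Core sequence types, alphabet operations, and plain-text I/O.

Conventions used throughout the package:

* the nucleotide alphabet is ``{A, C, G, T, N}``; lowercase input is
  uppercased on read, anything else is an error (never silently N-masked);
* coordinates are 1-based inclusive internally; BED input/output converts
  at the boundary;
* FASTA is wrapped at 60 columns on write; FASTQ qualities are Sanger
  (ASCII offset 33).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AlphabetError(ValueError):
    """A sequence contains characters outside {A, C, G, T, N}."""


class ParseError(ValueError):
    """A record in an input file violates the format's invariants."""


def _normalize(seq: str, context: str = "") -> str:
    s = seq.upper()
    bad = set(s) - ALPHABET
    if bad:
        where = f" in {context}" if context else ""
        raise AlphabetError(
            f"non-nucleotide characters {sorted(bad)}{where}; "
            "allowed alphabet is A,C,G,T,N"
        )
    return s


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; N maps to N.

    >>> reverse_complement("GGGGAGG")
    'CCTCCCC'
    """
    s = _normalize(seq)
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named nucleotide sequence (a read or a reference contig).

    ``quals``, when present, are Sanger-scale integer quality scores, one
    per base.
    """

    id: str
    seq: str
    quals: Optional[list[int]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.seq = _normalize(self.seq, context=f"record {self.id!r}")
        if self.quals is not None and len(self.quals) != len(self.seq):
            raise ParseError(
                f"record {self.id!r}: {len(self.quals)} quality values "
                f"for {len(self.seq)} bases"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def mean_quality(self) -> Optional[float]:
        if not self.quals:
            return None
        return sum(self.quals) / len(self.quals)


@dataclass(frozen=True)
class GeneInterval:
    """A gene span, 1-based inclusive, with the gene's transcribed strand."""

    contig: str
    start: int
    end: int
    strand: str
    name: str
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.name}: strand must be '+' or '-', got {self.strand!r}")

    def contains(self, contig: str, position: int) -> bool:
        return contig == self.contig and self.start <= position <= self.end


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: os.PathLike | str) -> Iterator[SequenceRecord]:
    """Yield records from a (possibly multi-record) FASTA file.

    Sequences are uppercased; an empty file yields nothing; text before the
    first header is a parse error (reported with its line number).
    """
    with open(path) as handle:
        # catch leading junk ourselves so the error carries a line number
        first = handle.readline()
        while first and not first.strip():
            first = handle.readline()
        if first and not first.startswith(">"):
            raise ParseError(f"{path}: line 1: expected FASTA header starting with '>'")
        handle.seek(0)
        for title, seq in SimpleFastaParser(handle):
            rid = title.split()[0] if title.split() else title
            yield SequenceRecord(rid, seq)


def write_fasta(path: os.PathLike | str, records: Iterable[SequenceRecord], width: int = 60) -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                out.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (Sanger +33)

def read_fastq(path: os.PathLike | str) -> Iterator[SequenceRecord]:
    """Yield records from 4-line-per-record FASTQ with Sanger qualities.

    A truncated record or a sequence/quality length mismatch raises
    :class:`ParseError` naming the offending record.
    """
    with open(path) as handle:
        try:
            for rid, seq, qual in FastqGeneralIterator(handle):
                rid = rid.split()[0]
                if len(seq) != len(qual):
                    raise ParseError(
                        f"record {rid!r}: sequence length {len(seq)} != "
                        f"quality length {len(qual)}"
                    )
                yield SequenceRecord(rid, seq, quals=[ord(c) - 33 for c in qual])
        except ValueError as exc:
            if isinstance(exc, (ParseError, AlphabetError)):
                raise
            raise ParseError(f"{path}: {exc}") from exc


def write_fastq(path: os.PathLike | str, records: Iterable[SequenceRecord], default_qual: int = 30) -> None:
    with open(path, "w") as out:
        for rec in records:
            quals = rec.quals if rec.quals is not None else [default_qual] * len(rec.seq)
            qstr = "".join(chr(q + 33) for q in quals)
            out.write(f"@{rec.id}\n{rec.seq}\n+\n{qstr}\n")


def filter_by_mean_quality(records: Iterable[SequenceRecord], min_mean: float) -> Iterator[SequenceRecord]:
    """Optional read filter; records without qualities always pass.

    Off by default in the pipeline: detection never uses qualities
    quantitatively.
    """
    for rec in records:
        mq = rec.mean_quality()
        if mq is None or mq >= min_mean:
            yield rec


# ---------------------------------------------------------------------------
# BED6 gene annotation (0-based half-open on disk -> 1-based inclusive here)

def read_gene_bed(path: os.PathLike | str) -> list[GeneInterval]:
    genes: list[GeneInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}: line {lineno}: expected >=6 BED fields, got {len(fields)}")
            contig, start, end, name, _score, strand = fields[:6]
            try:
                start0, end0 = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start0 >= end0:
                raise ParseError(f"{path}: line {lineno}: start {start0} >= end {end0}")
            gene_id = fields[6] if len(fields) > 6 else None
            genes.append(GeneInterval(contig, start0 + 1, end0, strand, name, gene_id))
    return genes


def write_gene_bed(path: os.PathLike | str, genes: Iterable[GeneInterval]) -> None:
    with open(path, "w") as out:
        for g in genes:
            extra = f"\t{g.gene_id}" if g.gene_id is not None else ""
            out.write(f"{g.contig}\t{g.start - 1}\t{g.end}\t{g.name}\t0\t{g.strand}{extra}\n")
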