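"""Readers and writers: FASTA, FASTQ, GFF3 and TSV report tables.

FASTA/FASTQ parsing is delegated to Biopython's SeqIO.  GFF3 is written in
the 1-based inclusive convention with Sequence Ontology feature types; the
conversion from the package's 0-based half-open intervals happens here and
only here.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from cassfinder.seqtypes import Interval, SequenceRecord, SequenceError

GFF_VERSION_PRAGMA = "##gff-version 3"


class ParseError(ValueError):
    """Malformed input file; message names the offending record/line."""


def _check_unique(records: list[SequenceRecord], path) -> list[SequenceRecord]:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
    return records


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            records.append(
                SequenceRecord(id=rec.id, residues=str(rec.seq), source=str(path))
            )
        except SequenceError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return _check_unique(records, path)


def write_fasta(path: str | Path, records: Iterable[SequenceRecord], width: int = 70) -> None:
    bio = [
        BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTQ file; quality strings are ignored."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        try:
            records.append(
                SequenceRecord(id=rec.id, residues=str(rec.seq), source=str(path))
            )
        except SequenceError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return _check_unique(records, path)


def read_reads(path: str | Path) -> list[SequenceRecord]:
    """Read sequencing reads from FASTA or FASTQ, sniffing the format."""
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return read_fastq(path)
    return read_fasta(path)


class Gff3Feature:
    """One GFF3 feature line (internally 0-based half-open)."""

    __slots__ = ("seqid", "source", "ftype", "interval", "score", "strand", "attributes")

    def __init__(
        self,
        seqid: str,
        ftype: str,
        interval: Interval,
        attributes: Mapping[str, str] | None = None,
        source: str = "cassfinder",
        score: float | None = None,
        strand: str = "+",
    ) -> None:
        self.seqid = seqid
        self.source = source
        self.ftype = ftype
        self.interval = interval
        self.score = score
        self.strand = strand
        self.attributes = dict(attributes or {})

    def to_line(self) -> str:
        attrs = ";".join(f"{k}={v}" for k, v in self.attributes.items()) or "."
        score = "." if self.score is None else f"{self.score:.1f}"
        return "\t".join(
            [
                self.seqid,
                self.source,
                self.ftype,
                str(self.interval.start + 1),  # 1-based inclusive
                str(self.interval.end),
                score,
                self.strand,
                ".",
                attrs,
            ]
        )

    @classmethod
    def from_line(cls, line: str, lineno: int = 0) -> "Gff3Feature":
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 9:
            raise ParseError(f"GFF3 line {lineno}: expected 9 columns, got {len(parts)}")
        try:
            start1, end1 = int(parts[3]), int(parts[4])
        except ValueError as exc:
            raise ParseError(f"GFF3 line {lineno}: non-integer coordinates") from exc
        attrs: dict[str, str] = {}
        if parts[8] != ".":
            for item in parts[8].split(";"):
                if not item:
                    continue
                key, _, value = item.partition("=")
                attrs[key] = value
        score = None if parts[5] == "." else float(parts[5])
        return cls(
            seqid=parts[0],
            ftype=parts[2],
            interval=Interval(start1 - 1, end1),
            attributes=attrs,
            source=parts[1],
            score=score,
            strand=parts[6],
        )


def write_gff3(path: str | Path, features: Iterable[Gff3Feature]) -> None:
    with open(path, "w") as fh:
        fh.write(GFF_VERSION_PRAGMA + "\n")
        for feat in features:
            fh.write(feat.to_line() + "\n")


def read_gff3(path: str | Path) -> list[Gff3Feature]:
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            features.append(Gff3Feature.from_line(line, lineno))
    return features


def write_tsv(path: str | Path, rows: Sequence[Mapping[str, object]], columns: Sequence[str] | None = None) -> None:
    """Write a header + rows tab-separated table; '' for missing values."""
    if columns is None:
        if not rows:
            raise ValueError("write_tsv needs explicit columns for empty tables")
        columns = list(rows[0].keys())
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(columns), delimiter="\t", restval="")
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row.get(k, "") for k in columns})


def read_tsv(path: str | Path) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
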