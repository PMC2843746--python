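"""Chromosome sequences and CDS annotation: FASTA/GFF3/GenBank input, TSV output.

All internal coordinates are 0-based half-open; GFF3's 1-based inclusive
coordinates are converted at the boundary. Compound (join) CDS locations in
GenBank records are decomposed into their parts, each becoming an independent
interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_NUCLEOTIDES = set("ACGTUNRYSWKMBDHV")


@dataclass(frozen=True)
class CdsInterval:
    """One coding interval, 0-based half-open, on the '+' or '-' strand."""

    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid CDS interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def frame_warning(self) -> bool:
        """True when the interval length is not a codon multiple.

        Real annotations contain such exceptions (pseudogenes, frameshifts);
        they are kept but flagged.
        """
        return self.length % 3 != 0


@dataclass
class ChromosomeRecord:
    """One replicon: sequence, CDS annotation and minimal metadata."""

    id: str
    sequence: str
    cds_list: list[CdsInterval] = field(default_factory=list)
    taxon_label: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        for cds in self.cds_list:
            if cds.end > self.length:
                raise ValueError(
                    f"CDS [{cds.start}, {cds.end}) outside chromosome of "
                    f"length {self.length}"
                )


def _clean_sequence(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[ChromosomeRecord]:
    """Read a (multi-)FASTA file into chromosome records, order preserved.

    Sequences are uppercased and RNA U is mapped to T. Raises ``ValueError``
    for an empty file or for a file whose letters are mostly outside the
    IUPAC nucleotide alphabet.
    """
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = _clean_sequence(str(entry.seq))
        if seq:
            non_iupac = sum(1 for c in seq if c not in IUPAC_NUCLEOTIDES)
            if non_iupac > 0.10 * len(seq):
                raise ValueError(f"not nucleotide FASTA: {path}")
        records.append(
            ChromosomeRecord(id=entry.id, sequence=seq, taxon_label=entry.description or None)
        )
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(records: list[ChromosomeRecord], path: str | Path, width: int = 70) -> None:
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def _read_cds_gff3(path: str | Path, chromosome_id: str) -> list[CdsInterval]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8 or fields[2] != "CDS":
                continue
            if fields[0] != chromosome_id:
                continue
            start_1, end_1 = int(fields[3]), int(fields[4])
            if end_1 < start_1:
                raise ValueError(f"CDS end < start on line: {line.rstrip()}")
            strand = fields[6].replace("−", "-")
            intervals.append(CdsInterval(start_1 - 1, end_1, strand))
    return intervals


def _read_cds_genbank(path: str | Path, chromosome_id: str) -> list[CdsInterval]:
    intervals = []
    for entry in SeqIO.parse(str(path), "genbank"):
        if entry.id != chromosome_id and entry.name != chromosome_id:
            continue
        for feature in entry.features:
            if feature.type != "CDS":
                continue
            for part in feature.location.parts:
                strand = "-" if part.strand == -1 else "+"
                intervals.append(CdsInterval(int(part.start), int(part.end), strand))
    return intervals


def read_cds_annotation(path: str | Path, chromosome_id: str) -> list[CdsInterval]:
    """CDS intervals for one chromosome from a GFF3 or GenBank file.

    The format is sniffed from the first non-blank line (GenBank flat files
    begin with LOCUS). GFF3 rows are converted from 1-based inclusive to
    0-based half-open; only rows whose seqid matches ``chromosome_id`` are
    kept. Intervals whose length is not a codon multiple trigger a warning.
    """
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
    if first.startswith("LOCUS"):
        intervals = _read_cds_genbank(path, chromosome_id)
    else:
        intervals = _read_cds_gff3(path, chromosome_id)
    n_odd = sum(1 for iv in intervals if iv.frame_warning)
    if n_odd:
        warnings.warn(
            f"{n_odd} CDS interval(s) on {chromosome_id} have length not a "
            "multiple of 3",
            stacklevel=2,
        )
    return intervals


def write_gff3(record: ChromosomeRecord, path: str | Path, source: str = "oligosurvey") -> None:
    """Write the record's CDS list as a minimal GFF3 file (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {record.id} 1 {record.length}\n")
        for i, cds in enumerate(record.cds_list):
            attrs = f"ID=cds{i:05d}"
            fh.write(
                f"{record.id}\t{source}\tCDS\t{cds.start + 1}\t{cds.end}\t.\t"
                f"{cds.strand}\t0\t{attrs}\n"
            )


def merged_intervals(cds_list: list[CdsInterval]) -> list[tuple[int, int]]:
    """Union of CDS intervals as sorted disjoint (start, end) pairs."""
    if not cds_list:
        return []
    spans = sorted((c.start, c.end) for c in cds_list)
    merged = [list(spans[0])]
    for start, end in spans[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def coding_fraction(record: ChromosomeRecord) -> float:
    """Percentage of chromosome positions covered by the union of CDS."""
    if record.length == 0:
        raise ValueError("zero-length chromosome")
    covered = sum(e - s for s, e in merged_intervals(record.cds_list))
    return 100.0 * covered / record.length


def write_tsv(
    df: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None
) -> None:
    """Write a report table as TSV with optional '#'-prefixed header lines."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
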