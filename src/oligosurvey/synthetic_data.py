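"""Synthetic chromosomes with planted word enrichment and CDS annotation.

The generator emulates the statistical structure the survey assumes: an
i.i.d. background of configurable G+C content, copies of chosen oligomers
planted at a configurable rate per Mb, and non-overlapping gene-like CDS
intervals covering a configurable coding fraction of the chromosome (86% by
default, the typical prokaryotic value). Planted copies overwrite background
bases, so chromosome length — and with it every window coordinate and the
N in the null models — stays fixed.

All randomness flows from a single spec-level seed through
``numpy.random.SeedSequence`` child streams (background, annotation, then
one stream per planted word, in that order), so every fixture is
reproducible bit-exactly.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome_io import CdsInterval, ChromosomeRecord, write_fasta, write_gff3

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedWord:
    """One word to plant: rate in copies per Mb; ``frame`` restricts planting
    to positions at that reading frame (1-3) inside CDS intervals."""

    word: str
    rate_per_mb: float
    frame: int | None = None


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic chromosome."""

    length_bp: int
    gc: float = 0.5
    planted: tuple[PlantedWord, ...] = ()
    coding_fraction_target: float = 86.0
    mean_gene_bp: int = 900
    seed: int = 0
    chromosome_id: str = "synthetic"

    def __post_init__(self):
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        planted_bp = sum(
            p.rate_per_mb * self.length_bp / 1e6 * len(p.word) for p in self.planted
        )
        if any(p.rate_per_mb < 0 for p in self.planted):
            raise ValueError("planting rates must be non-negative")
        if planted_bp > 0.05 * self.length_bp:
            raise ValueError("planted material exceeds 5% of chromosome length")


def generate_random_genome(
    length_bp: int, gc: float, seed, chromosome_id: str = "synthetic"
) -> ChromosomeRecord:
    """i.i.d. chromosome with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = np.searchsorted(np.cumsum(p), rng.random(length_bp), side="right")
    sequence = _BASE_BYTES[idx].tobytes().decode("ascii")
    return ChromosomeRecord(id=chromosome_id, sequence=sequence)


def _place_non_overlapping(
    rng: np.random.Generator,
    n: int,
    length_bp: int,
    word_length: int,
    allowed: np.ndarray | None = None,
    max_attempts_per_copy: int = 200,
) -> list[int]:
    """Uniform non-overlapping start positions; bounded rejection sampling."""
    chosen: list[int] = []
    attempts = 0
    limit = max_attempts_per_copy * max(n, 1)
    while len(chosen) < n:
        if attempts >= limit:
            raise RuntimeError(
                f"could not place {n} non-overlapping copies after {limit} attempts"
            )
        attempts += 1
        if allowed is not None:
            if allowed.size == 0:
                raise RuntimeError("no allowed positions for frame-biased planting")
            cand = int(allowed[rng.integers(allowed.size)])
        else:
            cand = int(rng.integers(0, length_bp - word_length + 1))
        i = bisect_left(chosen, cand)
        if i > 0 and cand - chosen[i - 1] < word_length:
            continue
        if i < len(chosen) and chosen[i] - cand < word_length:
            continue
        insort(chosen, cand)
    return chosen


def plant_words(
    record: ChromosomeRecord, word: str, rate_per_mb: float, seed
) -> tuple[ChromosomeRecord, list[int]]:
    """Overwrite Poisson(rate x length/1e6) copies of ``word`` at uniform
    non-overlapping positions; returns the new record and the planted
    start positions (the background contributes additional chance copies)."""
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(rate_per_mb * record.length / 1e6))
    positions = _place_non_overlapping(rng, n, record.length, len(word))
    seq = bytearray(record.sequence, "ascii")
    wb = word.encode("ascii")
    for pos in positions:
        seq[pos : pos + len(word)] = wb
    planted = ChromosomeRecord(
        id=record.id,
        sequence=seq.decode("ascii"),
        cds_list=list(record.cds_list),
        taxon_label=record.taxon_label,
    )
    return planted, positions


def _frame_positions(
    cds_list: list[CdsInterval], frame: int, word_length: int
) -> np.ndarray:
    """Start positions inside CDS intervals whose reading frame is ``frame``."""
    spots: list[int] = []
    for cds in cds_list:
        last = cds.end - word_length
        if last < cds.start:
            continue
        if cds.strand == "+":
            first = cds.start + (frame - 1)
            spots.extend(range(first, last + 1, 3))
        else:
            # 5' end in coding orientation sits at offset (frame-1) from
            # cds.end, so starts share the residue of anchor mod 3
            anchor = cds.end - word_length - (frame - 1)
            if anchor < cds.start:
                continue
            first = cds.start + (anchor - cds.start) % 3
            spots.extend(range(first, last + 1, 3))
    return np.asarray(sorted(spots), dtype=np.int64)


def generate_annotation(
    record: ChromosomeRecord,
    coding_fraction_target: float = 86.0,
    mean_gene_bp: int = 900,
    seed=0,
) -> list[CdsInterval]:
    """Non-overlapping gene-like CDS intervals covering roughly the target
    percentage of the chromosome.

    Gene lengths are exponential with mean ``mean_gene_bp``, rounded to
    codon multiples; intergenic gaps are exponential with the mean that
    balances coverage at the target; strands alternate. Coverage of a 1 Mb
    chromosome lands within about +/-2% of the target.
    """
    if coding_fraction_target >= 100:
        raise ValueError("coding fraction target must be < 100%")
    if coding_fraction_target <= 0:
        return []
    rng = np.random.default_rng(seed)
    target = coding_fraction_target / 100.0
    gap_mean = mean_gene_bp * (1 - target) / target
    intervals: list[CdsInterval] = []
    pos = 0
    strand = "+"
    while True:
        gap = int(round(rng.exponential(gap_mean)))
        start = pos + gap
        if start >= record.length - 3:
            break
        gene = 3 * max(1, int(round(rng.exponential(mean_gene_bp) / 3)))
        end = min(start + gene, start + 3 * ((record.length - start) // 3))
        if end <= start:
            break
        intervals.append(CdsInterval(start, end, strand))
        strand = "-" if strand == "+" else "+"
        pos = end
    return intervals


def synthesize(spec: SyntheticSpec) -> tuple[ChromosomeRecord, dict[str, list[int]]]:
    """Generate one chromosome per the spec: background, annotation, planting.

    Returns the annotated record and a log of planted positions per word.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(2 + len(spec.planted))
    record = generate_random_genome(
        spec.length_bp, spec.gc, streams[0], chromosome_id=spec.chromosome_id
    )
    cds_list = generate_annotation(
        record, spec.coding_fraction_target, spec.mean_gene_bp, streams[1]
    )
    record.cds_list = cds_list
    planted_log: dict[str, list[int]] = {}
    for i, plant in enumerate(spec.planted):
        rng = np.random.default_rng(streams[2 + i])
        n = int(rng.poisson(plant.rate_per_mb * record.length / 1e6))
        allowed = (
            _frame_positions(cds_list, plant.frame, len(plant.word))
            if plant.frame is not None
            else None
        )
        positions = _place_non_overlapping(
            rng, n, record.length, len(plant.word), allowed=allowed
        )
        seq = bytearray(record.sequence, "ascii")
        wb = plant.word.encode("ascii")
        for pos in positions:
            seq[pos : pos + len(plant.word)] = wb
        record.sequence = seq.decode("ascii")
        planted_log.setdefault(plant.word, []).extend(positions)
    record.validate()
    return record, planted_log


def write_fixture(
    record: ChromosomeRecord,
    spec: SyntheticSpec,
    outdir: str | Path,
    planted_log: dict[str, list[int]] | None = None,
) -> dict[str, Path]:
    """Emit FASTA + GFF3 + plain-text provenance sidecar for one chromosome."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / f"{record.id}.fasta",
        "gff3": outdir / f"{record.id}.gff3",
        "provenance": outdir / f"{record.id}.provenance.txt",
    }
    write_fasta([record], paths["fasta"])
    write_gff3(record, paths["gff3"])
    with open(paths["provenance"], "w") as fh:
        fh.write(f"chromosome_id={record.id}\n")
        fh.write(f"length_bp={spec.length_bp}\n")
        fh.write(f"gc={spec.gc}\n")
        fh.write(f"coding_fraction_target={spec.coding_fraction_target}\n")
        fh.write(f"mean_gene_bp={spec.mean_gene_bp}\n")
        fh.write(f"seed={spec.seed}\n")
        for plant in spec.planted:
            fh.write(
                f"planted={plant.word}:{plant.rate_per_mb}"
                + (f":{plant.frame}" if plant.frame is not None else "")
                + "\n"
            )
        if planted_log:
            for word, positions in planted_log.items():
                fh.write(f"positions_{word}={','.join(map(str, positions))}\n")
    return paths
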