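"""Cohort-level survey of abundant oligomers across chromosomes.

The survey proceeds in stages: per-chromosome scanning for words that are
both frequent (copies/Mb above a retention threshold) and overrepresented
under the zero-order model (chi-squared level above a cut-off); intersection
of the per-genome word sets across phylogenetically distant taxa; exhaustive
enumeration of the 512 homopurine/homopyrimidine octamers as the candidate
family; and a cohort summary tallying, for every candidate, the chromosomes
where it qualifies under each null model, an overrepresentation index, ranks
and copy-number quantiles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .genome_io import ChromosomeRecord
from .kmer_counting import (
    copies_per_mb,
    decode_kmer,
    encode_sequence,
    reverse_complement_sequence,
    unique_window_counts,
)
from .markov_stats import (
    BaseComposition,
    base_composition,
    score_order0,
    score_order2,
)

DEFAULT_K_RANGE = range(8, 15)
DEFAULT_MIN_CPM = 31.0
DEFAULT_CHI2_MIN = 100.0
DEFAULT_Z_MIN = 1.96


def random_expectation_per_mb(k: int = 8) -> float:
    """Expected copies/Mb of a length-k word under equiprobable bases."""
    return 1e6 / 4**k


def retention_threshold(k: int = 8, multiplier: float = 2.0) -> int:
    """Copies/Mb retention threshold: the multiple of the random expectation,
    rounded up to a whole copy count (31/Mb for octamers at multiplier 2)."""
    return math.ceil(multiplier * random_expectation_per_mb(k))


def _strand_symmetrized(record: ChromosomeRecord) -> str:
    # N separator keeps junction windows out of the counts
    return record.sequence + "N" + reverse_complement_sequence(record.sequence)


def scan_chromosome(
    record: ChromosomeRecord,
    k_range: range = DEFAULT_K_RANGE,
    min_cpm: float = DEFAULT_MIN_CPM,
    chi2_min: float = DEFAULT_CHI2_MIN,
    both_strands: bool = False,
    comp: BaseComposition | None = None,
) -> set[str]:
    """Words of any k in ``k_range`` that are frequent and overrepresented.

    A word qualifies when copies/Mb >= ``min_cpm``, its observed count
    exceeds the zero-order expectation, and the chi-squared level reaches
    ``chi2_min``. With ``both_strands`` the observed count sums both strands,
    the expectation uses N = 2L, and copies/Mb keeps the chromosome length L
    as denominator.
    """
    ks = sorted(k_range)
    length = record.length
    if length < ks[-1]:
        raise ValueError("chromosome shorter than the largest k")
    sequence = _strand_symmetrized(record) if both_strands else record.sequence
    if comp is None:
        comp = base_composition(sequence)
    arr = encode_sequence(sequence)
    hits: set[str] = set()
    for k in ks:
        codes, counts = unique_window_counts(arr, k)
        if codes.size == 0:
            break
        keep = counts * 1e6 / length >= min_cpm
        # A k-mer occurs at most as often as its (k-1)-prefix and the
        # copies/Mb threshold does not depend on k, so once no word reaches
        # the copy threshold no longer word can: stop scanning.
        if not keep.any():
            break
        for code, obs in zip(codes[keep], counts[keep]):
            word = decode_kmer(int(code), k)
            score = score_order0(word, int(obs), comp, chi2_min=chi2_min)
            if score.call == "over":
                hits.add(word)
    return hits


def select_common_oligomers(per_genome_sets: list[set[str]]) -> set[str]:
    """Intersection of per-genome qualifying word sets.

    Words shared by phylogenetically distant taxa are candidates for
    universal enrichment.
    """
    if not per_genome_sets:
        raise ValueError("need at least one per-genome set")
    return set.intersection(*(set(s) for s in per_genome_sets))


def enumerate_homo_octamers() -> list[str]:
    """All 512 homopurine (A/G) and homopyrimidine (C/T) octamers,
    lexicographically ordered."""
    purine = ("".join(w) for w in itertools.product("AG", repeat=8))
    pyrimidine = ("".join(w) for w in itertools.product("CT", repeat=8))
    return sorted(itertools.chain(purine, pyrimidine))


def counts_for_words(sequence: str, words: list[str]) -> dict[str, int]:
    """Observed counts of an arbitrary word list, grouped internally by k."""
    arr = encode_sequence(sequence)
    by_k: dict[int, list[str]] = {}
    for w in words:
        by_k.setdefault(len(w), []).append(w)
    out: dict[str, int] = {}
    for k, group in by_k.items():
        codes, counts = unique_window_counts(arr, k)
        lookup = dict(zip(codes.tolist(), counts.tolist()))
        for w in group:
            code = 0
            for ch in w:
                code = (code << 2) | "ACGT".index(ch)
            out[w] = int(lookup.get(code, 0))
    return out


@dataclass
class OverrepresentationSummary:
    """Cohort-level tallies for one candidate oligomer."""

    oligomer: str
    n_over_0: int
    n_over_2: int
    n_under_2: int
    index: int
    rank_0: int = 0
    rank_2: int = 0
    median_cpm: float = math.nan
    q1_cpm: float = math.nan
    q3_cpm: float = math.nan


def summarise(
    cohort: list[ChromosomeRecord],
    candidates: list[str],
    min_cpm: float = DEFAULT_MIN_CPM,
    chi2_min: float = DEFAULT_CHI2_MIN,
    z_min: float = DEFAULT_Z_MIN,
    index_mode: str = "subtract",
    variance: str = "conditional",
    both_strands: bool = False,
) -> list[OverrepresentationSummary]:
    """Tally per-candidate qualification over a chromosome cohort.

    For each candidate: ``n_over_0`` counts chromosomes where the word passes
    the zero-order thresholds (copies/Mb >= min_cpm, observed above
    expectation, chi-squared >= chi2_min); ``n_over_2``/``n_under_2`` count
    order-2 Gaussian calls at |z| >= z_min. The overrepresentation index is
    n_over_2 - n_under_2 (``index_mode="subtract"``) or n_over_2 alone
    (``index_mode="exclude"``: chromosomes over and, by construction, not
    under). Ranks are 1-based, descending on n_over_0 (rank_0) and on the
    index (rank_2), ties broken lexicographically. Copy-number quantiles
    (linear interpolation) are taken over the chromosomes where the word
    qualifies under the zero-order thresholds.
    """
    if not cohort:
        raise ValueError("empty cohort")
    if index_mode not in ("subtract", "exclude"):
        raise ValueError(f"unknown index_mode {index_mode!r}")
    tallies = {
        w: {"over0": 0, "over2": 0, "under2": 0, "cpm": []} for w in candidates
    }
    for record in cohort:
        sequence = _strand_symmetrized(record) if both_strands else record.sequence
        comp = base_composition(sequence)
        observed = counts_for_words(sequence, candidates)
        for word in candidates:
            obs = observed[word]
            cpm = copies_per_mb(obs, record.length)
            s0 = score_order0(word, obs, comp, chi2_min=chi2_min)
            if s0.call == "over" and cpm >= min_cpm:
                tallies[word]["over0"] += 1
                tallies[word]["cpm"].append(cpm)
            s2 = score_order2(word, obs, comp, z_min=z_min, variance=variance)
            if s2.call == "over":
                tallies[word]["over2"] += 1
            elif s2.call == "under":
                tallies[word]["under2"] += 1

    summaries = []
    for word in candidates:
        t = tallies[word]
        index = (
            t["over2"] - t["under2"] if index_mode == "subtract" else t["over2"]
        )
        cpm_values = t["cpm"]
        if cpm_values:
            q1, med, q3 = np.percentile(cpm_values, [25, 50, 75])
        else:
            q1 = med = q3 = math.nan
        summaries.append(
            OverrepresentationSummary(
                oligomer=word,
                n_over_0=t["over0"],
                n_over_2=t["over2"],
                n_under_2=t["under2"],
                index=index,
                median_cpm=float(med),
                q1_cpm=float(q1),
                q3_cpm=float(q3),
            )
        )
    for attr, key in (("rank_0", "n_over_0"), ("rank_2", "index")):
        order = sorted(summaries, key=lambda s: (-getattr(s, key), s.oligomer))
        for rank, summary in enumerate(order, start=1):
            setattr(summary, attr, rank)
    summaries.sort(key=lambda s: s.rank_0)
    return summaries
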