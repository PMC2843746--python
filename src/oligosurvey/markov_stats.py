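"""Expected word counts and overrepresentation scores under Markov null models.

Two null models are supported:

* zero order — each base drawn independently with the chromosome's
  mononucleotide proportions; controls for genome size and base composition.
  The expected count of a word w is N * prod_b p_b^(count of b in w), with N
  the full genome size in nucleotides. Departure is scored with a one-cell
  Pearson statistic (C_obs - C_exp)^2 / C_exp, used as a level of
  overrepresentation, not a significance test, so no multiple-testing
  correction is applied.

* second order — each base conditioned on the two preceding bases;
  expectations are built from observed tri- and dinucleotide counts, which
  factors out enrichment merely inherited from embedded mono- and
  dinucleotides. The plug-in (maximal-likelihood) estimator for a word
  w_1..w_k is

      E_hat = prod_{i=1..k-2} N3(w_i w_{i+1} w_{i+2})
            / prod_{i=2..k-2} N2(w_i w_{i+1})

  which is exact for k = 3. Departure is scored with a Gaussian z using a
  clump-corrected asymptotic variance (see :func:`gaussian_z`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kmer_counting import decode_kmer, encode_sequence, unique_window_counts


@dataclass
class BaseComposition:
    """Mono-, di- and trinucleotide content of one chromosome.

    ``total_bases`` is the full genome size in nucleotides (ambiguity codes
    included); ``proportions`` are computed over unambiguous bases only, and
    the di/tri counts cover ambiguity-free windows.
    """

    total_bases: int
    proportions: dict[str, float]
    dinucleotide_counts: dict[str, int]
    trinucleotide_counts: dict[str, int]
    _tri_row_totals: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._tri_row_totals:
            rows: dict[str, int] = {}
            for tri, n in self.trinucleotide_counts.items():
                rows[tri[:2]] = rows.get(tri[:2], 0) + n
            self._tri_row_totals = rows

    def transition_prob(self, context: str, base: str) -> float:
        """P(base | two preceding bases) under the fitted order-2 chain."""
        row = self._tri_row_totals.get(context, 0)
        if row == 0:
            return 0.0
        return self.trinucleotide_counts.get(context + base, 0) / row


def base_composition(sequence: str) -> BaseComposition:
    """Mono/di/trinucleotide composition of a sequence.

    Raises ``ValueError`` when the sequence contains no unambiguous base.
    """
    arr = encode_sequence(sequence)
    valid = arr >= 0
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no unambiguous bases in sequence")
    mono = np.bincount(arr[valid], minlength=4)
    proportions = {b: float(mono[i]) / n_valid for i, b in enumerate("ACGT")}

    def _dict(k: int) -> dict[str, int]:
        codes, counts = unique_window_counts(arr, k)
        return {decode_kmer(int(c), k): int(n) for c, n in zip(codes, counts)}

    return BaseComposition(
        total_bases=len(sequence),
        proportions=proportions,
        dinucleotide_counts=_dict(2),
        trinucleotide_counts=_dict(3),
    )


def expected_count_order0(word: str, comp: BaseComposition) -> float:
    """Zero-order expected count: N * prod over bases of p_base^(multiplicity).

    Returns 0.0 (degenerate) when the word uses a base absent from the
    chromosome.
    """
    value = float(comp.total_bases)
    for base in "ACGT":
        a = word.count(base)
        if a == 0:
            continue
        p = comp.proportions.get(base, 0.0)
        if p == 0.0:
            return 0.0
        value *= p**a
    return value


def chi_squared(observed: int, expected: float) -> float:
    """One-cell Pearson statistic (C_obs - C_exp)^2 / C_exp."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    return (observed - expected) ** 2 / expected


def expected_count_order2(word: str, comp: BaseComposition) -> float:
    """Second-order plug-in expected count from tri/dinucleotide counts.

    Exact for words of length 3. Returns 0.0 (degenerate) when an internal
    dinucleotide of the word was never observed.
    """
    k = len(word)
    if k < 3:
        raise ValueError("word length must be >= 3 for the order-2 model")
    value = 1.0
    for i in range(k - 2):
        value *= comp.trinucleotide_counts.get(word[i : i + 3], 0)
        if value == 0.0:
            return 0.0
    for i in range(1, k - 2):
        n2 = comp.dinucleotide_counts.get(word[i : i + 2], 0)
        if n2 == 0:
            return 0.0
        value /= n2
    return value


def overlap_periods(word: str) -> list[int]:
    """Shifts p with word[p:] == word[:-p] (self-overlap periods)."""
    k = len(word)
    return [p for p in range(1, k) if word[p:] == word[: k - p]]


def gaussian_z(
    word: str,
    observed: int,
    comp: BaseComposition,
    variance: str = "conditional",
) -> float:
    """Gaussian overrepresentation score under the second-order model.

    z = (C_obs - E_hat) / sigma_hat. With ``variance="conditional"`` the
    variance is the clump-corrected asymptotic form

        sigma^2 = E_hat * (1 + 2 * sum_p a_p)

    where the sum runs over the word's self-overlap periods p and a_p is the
    order-2 probability of re-extending the word by its last p bases (the
    expected excess from overlapping occurrence clumps, the dominant
    non-Poisson term for the A-tract-like words surveyed here). The plug-in
    estimation covariances are O(E^2 / N3) and are neglected.
    ``variance="poisson"`` uses sigma^2 = E_hat.

    Returns NaN (degenerate, flagged by callers) when the expectation or
    variance is not positive.
    """
    e = expected_count_order2(word, comp)
    if e <= 0:
        return math.nan
    if variance == "poisson":
        var = e
    elif variance == "conditional":
        k = len(word)
        clump = 0.0
        for p in overlap_periods(word):
            ext = word + word[k - p :]
            a_p = 1.0
            for j in range(k, k + p):
                a_p *= comp.transition_prob(ext[j - 2 : j], ext[j])
            clump += a_p
        var = e * (1.0 + 2.0 * clump)
    else:
        raise ValueError(f"unknown variance mode {variance!r}")
    if var <= 0:
        return math.nan
    return (observed - e) / math.sqrt(var)


@dataclass
class WordScore:
    """Observed vs expected count of one word under one null model."""

    oligomer: str
    observed: int
    expected: float
    statistic: float
    model_order: int
    call: str = "neutral"
    degenerate: bool = False


def classify(score: WordScore, chi2_min: float = 100.0, z_min: float = 1.96) -> str:
    """Representation call for a scored word.

    Order 0: over/under when the chi-squared level reaches ``chi2_min`` and
    the observed count lies above/below expectation. Order 2: over when
    z >= z_min, under when z <= -z_min. Degenerate scores are neutral.
    """
    if score.degenerate or math.isnan(score.statistic):
        return "neutral"
    if score.model_order == 0:
        if score.statistic >= chi2_min:
            if score.observed > score.expected:
                return "over"
            if score.observed < score.expected:
                return "under"
        return "neutral"
    if score.statistic >= z_min:
        return "over"
    if score.statistic <= -z_min:
        return "under"
    return "neutral"


def score_order0(
    word: str, observed: int, comp: BaseComposition, chi2_min: float = 100.0
) -> WordScore:
    expected = expected_count_order0(word, comp)
    if expected <= 0:
        score = WordScore(word, observed, expected, math.nan, 0, degenerate=True)
    else:
        score = WordScore(word, observed, expected, chi_squared(observed, expected), 0)
    score.call = classify(score, chi2_min=chi2_min)
    return score


def score_order2(
    word: str,
    observed: int,
    comp: BaseComposition,
    z_min: float = 1.96,
    variance: str = "conditional",
) -> WordScore:
    expected = expected_count_order2(word, comp)
    z = gaussian_z(word, observed, comp, variance=variance)
    score = WordScore(
        word, observed, expected, z, 2, degenerate=not math.isfinite(z)
    )
    score.call = classify(score, z_min=z_min)
    return score
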