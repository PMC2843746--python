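import itertools
import math

import numpy as np
import pytest

from oligosurvey.kmer_counting import count_words
from oligosurvey.markov_stats import (
    WordScore,
    base_composition,
    chi_squared,
    classify,
    expected_count_order0,
    expected_count_order2,
    gaussian_z,
    overlap_periods,
    score_order0,
    score_order2,
)
from oligosurvey.synthetic_data import generate_random_genome, plant_words


class TestBaseComposition:
    def test_uniform(self):
        comp = base_composition("ACGT")
        assert comp.total_bases == 4
        assert all(p == 0.25 for p in comp.proportions.values())

    def test_homopolymer(self):
        comp = base_composition("AAAA")
        assert comp.proportions["A"] == 1.0
        assert comp.proportions["C"] == 0.0

    def test_trinucleotide_windows(self):
        comp = base_composition("AAAT")
        assert comp.trinucleotide_counts == {"AAA": 1, "AAT": 1}

    def test_proportions_sum_to_one(self, iid_1mb_comp):
        assert math.isclose(sum(iid_1mb_comp.proportions.values()), 1.0, abs_tol=1e-12)

    def test_all_ambiguous_rejected(self):
        with pytest.raises(ValueError):
            base_composition("NNNN")


class TestExpectedOrder0:
    def test_random_octamer_benchmark(self):
        comp = base_composition("ACGT" * 250_000)
        assert expected_count_order0("GAAGAAGA", comp) == pytest.approx(1e6 / 4**8)

    def test_homopolymer_genome(self):
        comp = base_composition("A" * 1000)
        assert expected_count_order0("AAAAAAAA", comp) == 1000.0

    def test_two_letter_alphabet(self):
        comp = base_composition("AT" * 128)
        assert expected_count_order0("ATATATAT", comp) == pytest.approx(1.0)

    def test_absent_base_degenerate(self):
        comp = base_composition("A" * 100)
        assert expected_count_order0("AAAAAAAC", comp) == 0.0

    def test_multinomial_completeness(self):
        """Sum of expectations over all 4^k words equals N for any composition."""
        comp = base_composition("AACGTGGTACGTTTTA")
        total = sum(
            expected_count_order0("".join(w), comp)
            for w in itertools.product("ACGT", repeat=3)
        )
        assert total == pytest.approx(comp.total_bases)


class TestChiSquared:
    @pytest.mark.parametrize(
        "obs,exp,value",
        [(15, 15.0, 0.0), (30, 15.0, 15.0), (100, 15.26, (100 - 15.26) ** 2 / 15.26)],
    )
    def test_values(self, obs, exp, value):
        assert chi_squared(obs, exp) == pytest.approx(value)

    def test_depends_only_on_obs_exp_pair(self):
        assert chi_squared(40, 20.0) == chi_squared(40, 20.0)

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError):
            chi_squared(5, 0.0)


class TestExpectedOrder2:
    def test_exact_for_trinucleotides(self, iid_1mb_comp):
        for tri, n3 in iid_1mb_comp.trinucleotide_counts.items():
            assert expected_count_order2(tri, iid_1mb_comp) == pytest.approx(n3)

    def test_hand_computed_homopolymer(self):
        comp = base_composition("A" * 10)
        # N3(AAA)=8, N2(AA)=9 -> 8*8/9
        assert expected_count_order2("AAAA", comp) == pytest.approx(8 * 8 / 9)

    def test_missing_internal_dinucleotide_degenerate(self):
        comp = base_composition("AAACCC")
        assert expected_count_order2("AATAAT", comp) == 0.0

    def test_agrees_with_order0_on_iid_megabase(self, iid_1mb_comp, rng):
        words = {
            "".join(rng.choice(list("ACGT"), 8)) for _ in range(300)
        }
        for word in sorted(words)[:200]:
            e0 = expected_count_order0(word, iid_1mb_comp)
            e2 = expected_count_order2(word, iid_1mb_comp)
            assert abs(e2 - e0) / e0 < 0.10

    def test_too_short_word_rejected(self, iid_1mb_comp):
        with pytest.raises(ValueError):
            expected_count_order2("AC", iid_1mb_comp)


class TestGaussianZ:
    def test_zero_at_expectation(self, iid_1mb_comp):
        e = expected_count_order2("GAAGAAGA", iid_1mb_comp)
        z = gaussian_z("GAAGAAGA", round(e), iid_1mb_comp)
        assert abs(z) < 0.2

    @pytest.mark.parametrize("variance", ["conditional", "poisson"])
    def test_normality_over_random_octamers(self, variance):
        """Scores of 256 random octamers on i.i.d. megabases behave like
        N(0,1): unit spread per sequence, no systematic shift. Word counts on
        one sequence are correlated, so the mean is averaged over replicate
        sequences."""
        rng = np.random.default_rng(777)
        words = set()
        while len(words) < 256:
            words.add("".join(rng.choice(list("ACGT"), 8)))
        words = sorted(words)
        replicate_means = []
        for seed in (1, 2, 3, 4):
            rec = generate_random_genome(1_000_000, 0.5, seed)
            comp = base_composition(rec.sequence)
            table = count_words(rec.sequence, 8)
            zs = np.array(
                [
                    gaussian_z(w, table.get(w, 0), comp, variance=variance)
                    for w in words
                ]
            )
            assert 0.7 < zs.std() < 1.3
            replicate_means.append(zs.mean())
        assert abs(np.mean(replicate_means)) < 0.15

    def test_planted_word_scores_high(self):
        rec = generate_random_genome(1_000_000, 0.5, seed=99)
        rec, _ = plant_words(rec, "GAAGAAGA", 60.0, seed=100)
        comp = base_composition(rec.sequence)
        obs = count_words(rec.sequence, 8).get("GAAGAAGA", 0)
        assert gaussian_z("GAAGAAGA", obs, comp) > 3

    def test_degenerate_flagged_as_nan(self):
        comp = base_composition("AAACCC")
        assert math.isnan(gaussian_z("AATAAT", 5, comp))

    def test_overlap_periods(self):
        assert overlap_periods("GAAGAAGA") == [3, 6]
        assert overlap_periods("AAAAAAAA") == list(range(1, 8))
        assert overlap_periods("ACGTACGG") == []


class TestClassify:
    def test_order0_over_at_threshold(self):
        score = WordScore("W" * 8, 60, 15.0, 135.0, 0)
        assert classify(score) == "over"

    def test_order0_under_at_threshold(self):
        score = WordScore("W" * 8, 0, 60.0, 60.0, 0)
        assert classify(score, chi2_min=60) == "under"

    def test_order0_neutral_below_threshold(self):
        score = WordScore("W" * 8, 20, 15.0, 1.7, 0)
        assert classify(score) == "neutral"

    def test_order2_calls(self):
        assert classify(WordScore("w", 10, 5.0, 2.5, 2)) == "over"
        assert classify(WordScore("w", 1, 5.0, -2.5, 2)) == "under"
        assert classify(WordScore("w", 5, 5.0, 0.0, 2)) == "neutral"

    def test_over_call_implies_excess(self, iid_1mb_comp):
        s = score_order0("GAAGAAGA", 200, iid_1mb_comp)
        assert s.call == "over" and s.observed > s.expected
        s2 = score_order2("GAAGAAGA", 200, iid_1mb_comp)
        assert s2.call == "over" and s2.observed > s2.expected
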