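import math

import numpy as np
import pytest

from _oracles import emd_grid_oracle, emd_permutation_oracle, fmax_exhaustive_oracle
from gosummary.scoring import (
    Embedder,
    FmaxInput,
    average_embedding_score,
    compute_fmax,
    confidence_from_logprobs,
    confidence_score,
    embedding_cosine,
    exact_emd,
    hash_embedder,
    mover_distance,
    mover_similarity,
    split_sentences,
    win_fraction,
)
from gosummary.summarizer import BeamResult


def beam_from_probs(probs):
    lps = sorted((math.log(p) for p in probs), reverse=True)
    return BeamResult([f"h{i}" for i in range(len(lps))], lps)


class TestConfidence:
    def test_equal_probabilities_give_one_over_n(self):
        assert confidence_score(beam_from_probs([0.1] * 4)) == pytest.approx(0.25)

    def test_normalized_inputs_pass_through(self):
        assert confidence_score(beam_from_probs([0.4, 0.3, 0.2, 0.1])) == pytest.approx(0.4)

    def test_log_space_oracle(self):
        # e^-1 / (2 e^-1 + e^-2 + e^-3) computed by hand
        beam = BeamResult(["a", "b", "c", "d"], [-1.0, -1.0, -2.0, -3.0])
        expected = math.exp(-1) / (2 * math.exp(-1) + math.exp(-2) + math.exp(-3))
        assert confidence_score(beam) == pytest.approx(expected)
        assert round(expected, 4) == 0.3995

    def test_ratios_sum_to_one_and_shift_invariant(self):
        lps = [-3.2, -4.1, -7.9, -8.4]
        ratios = confidence_from_logprobs(lps)
        assert ratios.sum() == pytest.approx(1.0)
        shifted = confidence_from_logprobs([lp - 1000.0 for lp in lps])
        assert np.allclose(ratios, shifted)

    def test_underflow_safe(self):
        beam = BeamResult(["a", "b"], [-2000.0, -2001.0])
        assert confidence_score(beam) == pytest.approx(1 / (1 + math.exp(-1)))


class TestEmbeddingScores:
    def test_identical_texts_cosine_one(self):
        e = hash_embedder(0)
        assert embedding_cosine("binds primary kinase", "binds primary kinase", e) == pytest.approx(1.0)

    def test_hand_vector_oracle(self):
        table = {"a": np.array([1.0, 0.0, 0.0]), "b": np.array([0.6, 0.8, 0.0])}
        e = Embedder("fixture", lambda t: table[t])
        assert embedding_cosine("a", "b", e) == pytest.approx(0.6)

    def test_orthogonal_vectors_cosine_zero(self):
        table = {"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0])}
        e = Embedder("fixture", lambda t: table[t])
        assert embedding_cosine("a", "b", e) == pytest.approx(0.0)

    def test_average_is_mean_of_cosines(self):
        tables = [
            {"a": np.array([1.0, 0.0, 0.0]), "b": np.array([0.6, 0.8, 0.0])},  # 0.6
            {"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0])},            # 0.0
            {"a": np.array([0.6, 0.8, 0.0]), "b": np.array([1.0, 0.0, 0.0])},  # 0.6
        ]
        embedders = [Embedder(f"e{i}", (lambda tb: lambda t: tb[t])(tb)) for i, tb in enumerate(tables)]
        assert average_embedding_score("a", "b", embedders) == pytest.approx(0.4)

    def test_empty_embedder_list_rejected(self):
        with pytest.raises(ValueError):
            average_embedding_score("a", "b", [])


class TestSentenceSplit:
    def test_splits_on_terminal_punctuation_before_uppercase(self):
        assert split_sentences("It binds kinase. It acts in the nucleus.") == [
            "It binds kinase.",
            "It acts in the nucleus.",
        ]

    def test_unsegmentable_text_is_one_sentence(self):
        assert split_sentences("no terminal punctuation here") == ["no terminal punctuation here"]


class TestMoverSimilarity:
    def test_identical_documents_similarity_one(self):
        e = hash_embedder(1)
        text = "It binds kinase. It regulates chromatin dynamics."
        for mode in ("WMS", "SMS", "S+WMS"):
            assert mover_similarity(text, text, e, mode) == pytest.approx(1.0)

    def test_single_word_documents_exp_minus_distance(self):
        e = hash_embedder(2)
        d = float(np.linalg.norm(e("kinase") - e("ribosome")))
        assert mover_similarity("kinase", "ribosome", e, "WMS") == pytest.approx(math.exp(-d))

    def test_uniform_equal_bags_match_permutation_oracle(self):
        rng = np.random.default_rng(3)
        for n in (2, 3, 4, 5):
            va, vb = rng.normal(size=(n, 4)), rng.normal(size=(n, 4))
            cost = np.linalg.norm(va[:, None] - vb[None, :], axis=2)
            w = np.full(n, 1 / n)
            assert exact_emd(cost, w, w) == pytest.approx(emd_permutation_oracle(cost), abs=1e-9)

    def test_two_word_bags_equal_better_pairing(self):
        """With 2x2 uniform bags the optimum is the cheaper of the two pairings."""
        rng = np.random.default_rng(4)
        va, vb = rng.normal(size=(2, 3)), rng.normal(size=(2, 3))
        cost = np.linalg.norm(va[:, None] - vb[None, :], axis=2)
        direct = (cost[0, 0] + cost[1, 1]) / 2
        crossed = (cost[0, 1] + cost[1, 0]) / 2
        assert exact_emd(cost, [0.5, 0.5], [0.5, 0.5]) == pytest.approx(min(direct, crossed))

    def test_unequal_bags_match_simplex_grid_oracle(self):
        rng = np.random.default_rng(5)
        cases = [
            ([0.4, 0.6], [0.25, 0.3, 0.45]),
            ([0.2, 0.35, 0.45], [0.5, 0.5]),
            ([0.15, 0.85], [1.0]),
        ]
        for a, b in cases:
            cost = np.abs(rng.normal(size=(len(a), len(b))))
            got = exact_emd(cost, np.array(a), np.array(b))
            want = emd_grid_oracle(cost, np.array(a), np.array(b), step=0.05)
            assert got == pytest.approx(want, abs=1e-9)

    def test_word_weights_proportional_to_counts(self):
        # "x x y" vs "x": all mass of the right bag sits on x, so cost = (1/3)d(y,x)
        e = hash_embedder(6)
        d = float(np.linalg.norm(e("x") - e("y")))
        assert mover_distance("x x y", "x", e, "WMS") == pytest.approx(d / 3)

    def test_metric_axioms_on_random_triples(self):
        e = hash_embedder(7)
        words = ["kinase", "ribosome", "chromatin", "membrane", "vesicle", "ligase"]
        rng = np.random.default_rng(8)
        for _ in range(100):
            texts = [" ".join(rng.choice(words, size=rng.integers(1, 5))) for _ in range(3)]
            a, b, c = texts
            dab = mover_distance(a, b, e, "WMS")
            assert dab == pytest.approx(mover_distance(b, a, e, "WMS"), abs=1e-8)
            assert dab >= -1e-12
            assert dab <= mover_distance(a, c, e, "WMS") + mover_distance(c, b, e, "WMS") + 1e-8
        # identity of indiscernibles on the bag level
        assert mover_distance("kinase ribosome", "ribosome kinase", e, "WMS") == pytest.approx(0.0, abs=1e-9)

    def test_similarity_strictly_decreasing_in_distance(self):
        assert math.exp(-0.2) > math.exp(-0.9)  # transform is monotone by construction
        e = hash_embedder(9)
        near = mover_similarity("kinase ribosome", "kinase membrane", e, "WMS")
        far = mover_similarity("kinase ribosome", "vesicle membrane", e, "WMS")
        assert near > far


class TestWinFraction:
    def test_counts_strict_wins(self):
        assert win_fraction([1, 2, 3, 4], [0, 3, 1, 2]) == 0.75

    def test_ties_are_non_wins(self):
        assert win_fraction([1.0, 1.0], [1.0, 1.0]) == 0.0

    def test_epsilon_margin_wins_everywhere(self):
        b = [0.1, 0.2, 0.3]
        a = [x + 1e-12 for x in b]
        assert win_fraction(a, b) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            win_fraction([1], [1, 2])


class TestFmax:
    def test_perfect_prediction_is_one(self):
        truth = {"P1": {"GO:0000001", "GO:0000002"}}
        preds = {"P1": {"GO:0000001": 1.0, "GO:0000002": 1.0}}
        assert compute_fmax(FmaxInput(preds, truth)) == pytest.approx(1.0)

    def test_disjoint_prediction_is_zero(self):
        truth = {"P1": {"GO:0000001"}}
        preds = {"P1": {"GO:0000009": 0.9}}
        assert compute_fmax(FmaxInput(preds, truth)) == pytest.approx(0.0)

    def test_hand_enumeration_case(self):
        # truth {a..e}; predictions a:0.9 (correct), x:0.9 (wrong)
        truth = {"P1": {f"GO:000000{i}" for i in range(1, 6)}}
        preds = {"P1": {"GO:0000001": 0.9, "GO:0000009": 0.9}}
        # at t <= 0.9: precision 1/2, recall 1/5 -> F1 = 2 * 0.5 * 0.2 / 0.7
        assert compute_fmax(FmaxInput(preds, truth)) == pytest.approx(2 * 0.5 * 0.2 / 0.7)

    def test_matches_exhaustive_oracle_on_small_instances(self):
        rng = np.random.default_rng(10)
        ids = [f"GO:{i:07d}" for i in range(1, 13)]
        for _ in range(20):
            truth = {
                f"P{p}": set(rng.choice(ids, size=rng.integers(1, 5), replace=False))
                for p in range(rng.integers(1, 6))
            }
            preds = {
                acc: {
                    str(g): float(np.round(rng.uniform(0.01, 1.0), 2))
                    for g in rng.choice(ids, size=rng.integers(0, 6), replace=False)
                }
                for acc in truth
            }
            got = compute_fmax(FmaxInput(preds, truth))
            assert got == pytest.approx(fmax_exhaustive_oracle(preds, truth), abs=1e-12)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            compute_fmax(FmaxInput({}, {"P1": set()}))
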