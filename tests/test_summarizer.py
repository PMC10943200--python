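import numpy as np
import pytest

from _oracles import beam_enumeration_oracle
from conftest import TINY_TRAIN
from gosummary.summarizer import (
    BeamResult,
    SummarizerBackend,
    TinySeq2Seq,
    TrainingConfig,
    generate,
    train,
)


class MockBackend(SummarizerBackend):
    """Fixed branching distribution over a 3-token vocabulary (token 2 = EOS)."""

    bos_id, eos_id = -1, 2

    def __init__(self, table):
        # table: prefix tuple -> probability vector over {0, 1, EOS}
        self.table = table

    def encode(self, text):
        return [0]

    def decode(self, ids):
        return " ".join(str(i) for i in ids)

    def next_logprobs(self, input_ids, prefix_ids):
        probs = np.asarray(self.table[tuple(prefix_ids)], dtype=float)
        with np.errstate(divide="ignore"):
            return np.log(probs)

    def train_batch(self, pairs, lr):  # pragma: no cover - not trainable
        raise NotImplementedError

    def loss(self, pairs):  # pragma: no cover
        raise NotImplementedError


TWO_STEP = {
    (): [0.6, 0.4, 0.0],
    (0,): [0.0, 0.0, 1.0],   # "0" then forced EOS
    (1,): [0.7, 0.0, 0.3],   # "1" -> mostly "1 0"
    (1, 0): [0.0, 0.0, 1.0],
}


class TestBeamSearch:
    def test_width_two_matches_exhaustive_products(self):
        """Beam-2 returns the two highest-probability complete paths with exact products."""
        backend = MockBackend(TWO_STEP)
        result = generate(backend, "x", beam_width=2, max_target_tokens=3)
        # complete sequences: "0" p=0.6, "1" p=0.12, "1 0" p=0.28
        assert result.hypotheses == ["0", "1 0"]
        assert np.allclose(result.probabilities, [0.6, 0.4 * 0.7 * 1.0])

    def test_wide_beam_equals_enumeration_oracle(self):
        backend = MockBackend(TWO_STEP)
        result = generate(backend, "x", beam_width=3, max_target_tokens=3)
        oracle = beam_enumeration_oracle(backend, [0], max_len=3, top_n=3)
        assert len(result.hypotheses) == 3
        for (ids, lp), hyp, got_lp in zip(oracle, result.hypotheses, result.log_probs):
            assert backend.decode([i for i in ids if i != backend.eos_id]) == hyp
            assert np.isclose(lp, got_lp)

    def test_beam_one_is_greedy(self, trained_setup):
        backend = trained_setup["backend"]
        doc = trained_setup["split"].test[0].document
        beam = generate(backend, doc, beam_width=1, max_target_tokens=20)
        # greedy reference: argmax token by token
        ids = []
        for _ in range(20):
            tok = int(np.argmax(backend.next_logprobs(backend.encode(doc.text), ids)))
            ids.append(tok)
            if tok == backend.eos_id:
                break
        assert beam.top == backend.decode([i for i in ids if i != backend.eos_id])

    def test_probabilities_non_increasing_and_length_bounded(self, trained_setup):
        backend = trained_setup["backend"]
        for record in trained_setup["split"].test[:5]:
            beam = generate(backend, record.document, beam_width=4, max_target_tokens=15)
            lps = beam.log_probs
            assert all(lps[j] >= lps[j + 1] for j in range(len(lps) - 1))
            assert all(len(h.split()) <= 15 for h in beam.hypotheses)

    def test_invalid_distribution_rejected(self):
        backend = MockBackend({(): [0.5, 0.2, 0.1]})  # sums to 0.8
        with pytest.raises(ValueError, match="distribution"):
            generate(backend, "x", beam_width=2, max_target_tokens=2)

    def test_beam_result_ordering_enforced(self):
        with pytest.raises(ValueError):
            BeamResult(["a", "b"], [-2.0, -1.0])


class TestTraining:
    def test_loss_descends_on_learnable_data(self, trained_setup):
        trace = trained_setup["trace"]
        assert trace.train_loss[-1] < trace.train_loss[0]
        assert trace.val_loss[-1] < trace.val_loss[0]

    def test_early_stopping_respects_patience(self, trained_setup):
        split = trained_setup["split"]
        corpus = [r.document.text for r in split.train[:24]] + [r.reference for r in split.train[:24]]
        backend = TinySeq2Seq(corpus, seed=1)
        # zero learning rate: validation loss can never improve after epoch 1
        cfg = TrainingConfig(epochs=50, learning_rate=1e-12, early_stopping_patience=3, seed=1)
        trace = train(backend, split.train[:24], split.validation[:8], cfg)
        assert len(trace.train_loss) <= 1 + 3

    def test_training_is_deterministic(self, trained_setup):
        split = trained_setup["split"]
        cfg = TrainingConfig(epochs=3, learning_rate=3e-3, seed=5)
        traces = []
        for _ in range(2):
            corpus = [r.document.text for r in split.train[:32]] + [r.reference for r in split.train[:32]]
            backend = TinySeq2Seq(corpus, seed=5)
            traces.append(train(backend, split.train[:32], split.validation[:8], cfg))
        assert traces[0].train_loss == traces[1].train_loss
        assert traces[0].val_loss == traces[1].val_loss

    def test_empty_dataset_rejected(self):
        backend = TinySeq2Seq(["a b c"], seed=0)
        with pytest.raises(ValueError):
            train(backend, [], [], TrainingConfig())

    def test_config_defaults_match_recipe(self):
        cfg = TrainingConfig()
        assert (cfg.epochs, cfg.learning_rate, cfg.batch_size) == (100, 1e-4, 4)
        assert (cfg.max_input_tokens, cfg.max_target_tokens) == (1024, 256)


class TestCheckpointing:
    def test_save_load_preserves_generation(self, trained_setup, tmp_path):
        backend = trained_setup["backend"]
        doc = trained_setup["split"].test[0].document
        before = generate(backend, doc, beam_width=4, max_target_tokens=20)
        backend.save(tmp_path / "ckpt")
        loaded = TinySeq2Seq.load(tmp_path / "ckpt")
        after = generate(loaded, doc, beam_width=4, max_target_tokens=20)
        assert before.hypotheses == after.hypotheses
        assert np.allclose(before.log_probs, after.log_probs)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """Backprop through attention + MLP agrees with numeric differentiation."""
        backend = TinySeq2Seq(["alpha beta gamma delta"], d=6, d_hidden=8, seed=3)
        x = backend.encode("alpha beta gamma")
        y = backend.encode("beta delta")
        _, grads = backend._loss_and_grads(x, y)
        rng = np.random.default_rng(0)
        eps = 1e-6
        for name in ("W_q", "W_h", "W_o", "E_in", "E_dec", "b_h", "b_o"):
            p = backend.params[name]
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = backend._loss_and_grads(x, y)
                p[idx] = orig - eps
                lm, _ = backend._loss_and_grads(x, y)
                p[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert np.isclose(grads[name][idx], numeric, rtol=1e-4, atol=1e-7), name
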