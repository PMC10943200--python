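"""Trainable encoder–decoder summarizer: contract, training recipe, beam search.

The summarizer maps a GO document (concatenated term definitions) to a short
functional paragraph. The training recipe is token-level cross-entropy with
Adam, batch size 4, learning rate 1e-4, up to 100 epochs with early stopping
on validation loss — the configuration used for full-scale fine-tuning of a
large pretrained encoder–decoder. Any backend satisfying
:class:`SummarizerBackend` plugs into the same ``train``/``generate`` calls;
the package ships :class:`TinySeq2Seq`, a small word-level attention
encoder–decoder written directly in numpy that trains on a CPU in minutes
and is the backend exercised by the test suite.

Beam-search hypotheses carry the raw product of their token probabilities
(accumulated in log space); those N final-beam probabilities feed the
confidence score downstream.
"""

from __future__ import annotations

import copy
import json
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .go_corpus import GODocument
from .dataset import SectionRecord


@dataclass
class TrainingConfig:
    """Training hyperparameters; defaults follow the full-scale fine-tuning recipe."""

    epochs: int = 100
    learning_rate: float = 1e-4
    batch_size: int = 4
    max_input_tokens: int = 1024
    max_target_tokens: int = 256
    early_stopping_patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.early_stopping_patience < 1:
            raise ValueError("epochs, batch_size and patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class BeamResult:
    """The N hypotheses alive at the final step of a beam search, best first.

    ``log_probs[j]`` is the sum of log next-token probabilities of hypothesis
    j, so ``exp(log_probs[j])`` is its raw (unnormalized) probability.
    """

    hypotheses: list[str]
    log_probs: list[float]

    def __post_init__(self) -> None:
        if len(self.hypotheses) != len(self.log_probs):
            raise ValueError("hypotheses and log_probs must have equal length")
        if not self.hypotheses:
            raise ValueError("empty beam result")
        if any(
            self.log_probs[j] < self.log_probs[j + 1] - 1e-12
            for j in range(len(self.log_probs) - 1)
        ):
            raise ValueError("log_probs must be non-increasing")

    @property
    def probabilities(self) -> np.ndarray:
        return np.exp(np.asarray(self.log_probs))

    @property
    def top(self) -> str:
        return self.hypotheses[0]


class SummarizerBackend(ABC):
    """Behavioral contract for a trainable conditional text generator.

    A backend owns a tokenizer (text <-> token-id sequences with BOS/EOS
    sentinels) and a conditional next-token distribution given the encoded
    input and a decoded prefix; the distribution must be a proper probability
    distribution over the vocabulary.
    """

    bos_id: int
    eos_id: int

    @abstractmethod
    def encode(self, text: str) -> list[int]: ...

    @abstractmethod
    def decode(self, ids: Sequence[int]) -> str: ...

    @abstractmethod
    def next_logprobs(self, input_ids: Sequence[int], prefix_ids: Sequence[int]) -> np.ndarray:
        """Log next-token distribution (length = vocabulary size)."""

    @abstractmethod
    def train_batch(self, pairs: list[tuple[list[int], list[int]]], lr: float) -> float:
        """One optimizer step on a batch of (input_ids, target_ids); returns mean loss."""

    @abstractmethod
    def loss(self, pairs: list[tuple[list[int], list[int]]]) -> float:
        """Mean token-level cross-entropy without updating parameters."""

    def clone(self) -> "SummarizerBackend":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# word-level tokenizer


class WordTokenizer:
    """Word-level tokenizer with UNK/BOS/EOS sentinels, vocabulary from a corpus."""

    UNK, BOS, EOS = 0, 1, 2

    def __init__(self, texts: Sequence[str]):
        words = sorted({w for t in texts for w in self.split(t)})
        self.itos = ["<unk>", "<bos>", "<eos>"] + words
        self.stoi = {w: i for i, w in enumerate(self.itos)}

    @staticmethod
    def split(text: str) -> list[str]:
        return text.split()

    def __len__(self) -> int:
        return len(self.itos)

    def encode(self, text: str) -> list[int]:
        return [self.stoi.get(w, self.UNK) for w in self.split(text)]

    def decode(self, ids: Sequence[int]) -> str:
        return " ".join(self.itos[i] for i in ids if i not in (self.BOS, self.EOS))


# ---------------------------------------------------------------------------
# tiny numpy encoder-decoder


class TinySeq2Seq(SummarizerBackend):
    """Small attention encoder–decoder over a word vocabulary, pure numpy.

    The encoder is the table of input word embeddings; the decoder predicts
    each target token from (a) single-head dot-product attention over the
    input embeddings queried by the two previous target tokens, (b) the mean
    input embedding, and (c) the previous-token embeddings, through one
    hidden ReLU layer. Gradients are computed in closed form and applied
    with Adam. Deterministic given the construction seed and input order.
    """

    def __init__(self, corpus_texts: Sequence[str], d: int = 32, d_hidden: int = 64, seed: int = 0):
        self.tokenizer = WordTokenizer(corpus_texts)
        self.bos_id = WordTokenizer.BOS
        self.eos_id = WordTokenizer.EOS
        self.d = d
        self.d_hidden = d_hidden
        self.seed = seed
        V = len(self.tokenizer)
        rng = np.random.default_rng(seed)
        s = 0.1
        self.params = {
            "E_in": rng.normal(0, s, (V, d)),
            "E_dec": rng.normal(0, s, (V, d)),
            "W_q": rng.normal(0, s, (d, 2 * d)),
            "W_h": rng.normal(0, s, (d_hidden, 4 * d)),
            "b_h": np.zeros(d_hidden),
            "W_o": rng.normal(0, s, (V, d_hidden)),
            "b_o": np.zeros(V),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- tokenizer passthrough

    def encode(self, text: str) -> list[int]:
        return self.tokenizer.encode(text)

    def decode(self, ids: Sequence[int]) -> str:
        return self.tokenizer.decode(ids)

    # -- forward

    def _forward(self, x: np.ndarray, prev1: np.ndarray, prev2: np.ndarray):
        """Logits for each decoding step given input ids x and previous-token ids."""
        p = self.params
        K = p["E_in"][x]                      # (L, d)
        cbar = K.mean(axis=0)                 # (d,)
        P1 = p["E_dec"][prev1]                # (T, d)
        P2 = p["E_dec"][prev2]
        PP = np.concatenate([P1, P2], axis=1)  # (T, 2d)
        Q = np.tanh(PP @ p["W_q"].T)          # (T, d)
        S = Q @ K.T / np.sqrt(self.d)         # (T, L)
        S = S - S.max(axis=1, keepdims=True)
        A = np.exp(S)
        A /= A.sum(axis=1, keepdims=True)
        C = A @ K                             # (T, d)
        X = np.concatenate([C, np.broadcast_to(cbar, C.shape), P1, P2], axis=1)  # (T, 4d)
        Hpre = X @ p["W_h"].T + p["b_h"]
        H = np.maximum(Hpre, 0.0)
        Z = H @ p["W_o"].T + p["b_o"]         # (T, V)
        cache = (x, prev1, prev2, K, P1, P2, PP, Q, A, C, X, H, Z)
        return Z, cache

    @staticmethod
    def _log_softmax(Z: np.ndarray) -> np.ndarray:
        Zs = Z - Z.max(axis=-1, keepdims=True)
        return Zs - np.log(np.exp(Zs).sum(axis=-1, keepdims=True))

    def next_logprobs(self, input_ids: Sequence[int], prefix_ids: Sequence[int]) -> np.ndarray:
        x = np.asarray(input_ids if len(input_ids) else [self.tokenizer.UNK])
        seq = [self.bos_id, self.bos_id, *prefix_ids]
        prev1 = np.array([seq[-1]])
        prev2 = np.array([seq[-2]])
        Z, _ = self._forward(x, prev1, prev2)
        return self._log_softmax(Z)[0]

    # -- training

    def _prep(self, input_ids: Sequence[int], target_ids: Sequence[int]):
        x = np.asarray(input_ids if len(input_ids) else [self.tokenizer.UNK])
        y = np.asarray([*target_ids, self.eos_id])
        full = np.concatenate([[self.bos_id, self.bos_id], y])
        return x, full[1:-1], full[:-2], y  # x, prev1, prev2, targets

    def _loss_and_grads(self, input_ids, target_ids):
        x, prev1, prev2, y = self._prep(input_ids, target_ids)
        Z, cache = self._forward(x, prev1, prev2)
        logp = self._log_softmax(Z)
        T = len(y)
        loss = -logp[np.arange(T), y].mean()
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss")

        p = self.params
        (x, prev1, prev2, K, P1, P2, PP, Q, A, C, X, H, Z) = cache
        dZ = np.exp(logp)
        dZ[np.arange(T), y] -= 1.0
        dZ /= T
        g = {k: np.zeros_like(v) for k, v in p.items()}
        g["W_o"] = dZ.T @ H
        g["b_o"] = dZ.sum(axis=0)
        dH = dZ @ p["W_o"]
        dH[H <= 0] = 0.0
        g["W_h"] = dH.T @ X
        g["b_h"] = dH.sum(axis=0)
        dX = dH @ p["W_h"]
        d_ = self.d
        dC, dcbar_rows, dP1, dP2 = dX[:, :d_], dX[:, d_ : 2 * d_], dX[:, 2 * d_ : 3 * d_], dX[:, 3 * d_ :]
        dK = A.T @ dC
        dA = dC @ K.T
        dS = A * (dA - (dA * A).sum(axis=1, keepdims=True))
        dQ = dS @ K / np.sqrt(d_)
        dK += dS.T @ Q / np.sqrt(d_)
        dQpre = dQ * (1.0 - Q**2)
        g["W_q"] = dQpre.T @ PP
        dPP = dQpre @ p["W_q"]
        dP1 = dP1 + dPP[:, :d_]
        dP2 = dP2 + dPP[:, d_:]
        # mean-pooled context: distribute to every input embedding row
        dK += dcbar_rows.sum(axis=0) / len(x)
        np.add.at(g["E_in"], x, dK)
        np.add.at(g["E_dec"], prev1, dP1)
        np.add.at(g["E_dec"], prev2, dP2)
        return loss, g

    def train_batch(self, pairs, lr):
        total = {k: np.zeros_like(v) for k, v in self.params.items()}
        losses = []
        for input_ids, target_ids in pairs:
            loss, g = self._loss_and_grads(input_ids, target_ids)
            losses.append(loss)
            for k in total:
                total[k] += g[k]
        n = len(pairs)
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, param in self.params.items():
            grad = total[k] / n
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * grad
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * grad**2
            mhat = self._adam_m[k] / (1 - b1**self._adam_t)
            vhat = self._adam_v[k] / (1 - b2**self._adam_t)
            param -= lr * mhat / (np.sqrt(vhat) + eps)
        return float(np.mean(losses))

    def loss(self, pairs):
        losses = []
        for input_ids, target_ids in pairs:
            x, prev1, prev2, y = self._prep(input_ids, target_ids)
            Z, _ = self._forward(x, prev1, prev2)
            logp = self._log_softmax(Z)
            losses.append(-logp[np.arange(len(y)), y].mean())
        return float(np.mean(losses))

    # -- persistence

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.params)
        manifest = {
            "backend": "TinySeq2Seq",
            "d": self.d,
            "d_hidden": self.d_hidden,
            "seed": self.seed,
            "vocab": self.tokenizer.itos,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest))

    @classmethod
    def load(cls, directory: str | Path) -> "TinySeq2Seq":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        model = cls.__new__(cls)
        model.tokenizer = WordTokenizer.__new__(WordTokenizer)
        model.tokenizer.itos = manifest["vocab"]
        model.tokenizer.stoi = {w: i for i, w in enumerate(manifest["vocab"])}
        model.bos_id, model.eos_id = WordTokenizer.BOS, WordTokenizer.EOS
        model.d, model.d_hidden, model.seed = manifest["d"], manifest["d_hidden"], manifest["seed"]
        with np.load(directory / "weights.npz") as npz:
            model.params = {k: npz[k] for k in npz.files}
        model._adam_m = {k: np.zeros_like(v) for k, v in model.params.items()}
        model._adam_v = {k: np.zeros_like(v) for k, v in model.params.items()}
        model._adam_t = 0
        return model


# ---------------------------------------------------------------------------
# training loop


@dataclass
class LossTrace:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def write_csv(self, stream) -> None:
        stream.write("epoch,train_loss,val_loss\n")
        for i, (tr, vl) in enumerate(zip(self.train_loss, self.val_loss), start=1):
            stream.write(f"{i},{tr:.6f},{vl:.6f}\n")


def _to_pairs(records: Sequence[SectionRecord], backend: SummarizerBackend, cfg: TrainingConfig):
    pairs = []
    for r in records:
        x = backend.encode(r.document.text)[: cfg.max_input_tokens]
        y = backend.encode(r.reference)[: cfg.max_target_tokens]
        pairs.append((x, y))
    return pairs


def train(
    backend: SummarizerBackend,
    train_set: Sequence[SectionRecord],
    val_set: Sequence[SectionRecord],
    config: TrainingConfig | None = None,
) -> LossTrace:
    """Fit the backend by teacher-forced cross-entropy with early stopping.

    Each epoch shuffles the training pairs with a seeded generator, steps
    Adam per mini-batch, then evaluates validation loss; training halts at
    ``config.epochs`` or once validation loss has not improved for
    ``config.early_stopping_patience`` consecutive epochs.
    """
    cfg = config or TrainingConfig()
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    train_pairs = _to_pairs(train_set, backend, cfg)
    val_pairs = _to_pairs(val_set, backend, cfg)
    rng = np.random.default_rng(cfg.seed)
    trace = LossTrace()
    best_val = np.inf
    stale = 0
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(train_pairs))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_pairs[i] for i in order[start : start + cfg.batch_size]]
            epoch_losses.append(backend.train_batch(batch, cfg.learning_rate))
        vl = backend.loss(val_pairs)
        trace.train_loss.append(float(np.mean(epoch_losses)))
        trace.val_loss.append(vl)
        if vl < best_val - 1e-9:
            best_val = vl
            stale = 0
        else:
            stale += 1
            if stale >= cfg.early_stopping_patience:
                break
    return trace


# ---------------------------------------------------------------------------
# beam search


def generate(
    backend: SummarizerBackend,
    document: GODocument | str,
    beam_width: int = 4,
    max_target_tokens: int = 256,
    length_normalize: bool = False,
) -> BeamResult:
    """Length-bounded beam search returning the final N ranked hypotheses.

    Keeps the ``beam_width`` highest-scoring partial sequences at each step;
    a beam that emits EOS is frozen but keeps competing for its slot. The
    score of a hypothesis is the sum of its token log-probabilities (raw
    product of probabilities — no length penalty — unless
    ``length_normalize`` is set, which ranks by mean token log-probability).
    """
    text = document.text if isinstance(document, GODocument) else document
    if not text.strip():
        raise ValueError("cannot generate from an empty document")
    if beam_width < 1:
        raise ValueError("beam_width must be >= 1")
    input_ids = backend.encode(text)
    # beams: (prefix token ids, cumulative logprob, finished)
    beams: list[tuple[list[int], float, bool]] = [([], 0.0, False)]
    for _step in range(max_target_tokens):
        if all(b[2] for b in beams):
            break
        candidates: list[tuple[list[int], float, bool]] = []
        for prefix, lp, finished in beams:
            if finished:
                candidates.append((prefix, lp, True))
                continue
            logprobs = np.asarray(backend.next_logprobs(input_ids, prefix), dtype=float)
            total = np.logaddexp.reduce(logprobs)  # tolerates -inf (zero-probability tokens)
            if logprobs.ndim != 1 or np.isnan(total) or abs(total) > 1e-6:
                raise ValueError(f"backend emitted an invalid next-token distribution (log-sum {total:.3g})")
            for tok in np.argsort(logprobs)[::-1][: beam_width + 1]:
                tok = int(tok)
                candidates.append((prefix + [tok], lp + float(logprobs[tok]), tok == backend.eos_id))
        candidates.sort(key=lambda c: (_rank_score(c, length_normalize), -len(c[0])), reverse=True)
        beams = candidates[:beam_width]
    # sequences still unfinished at the length bound are returned as-is;
    # the result is always ordered by raw hypothesis probability
    beams.sort(key=lambda c: c[1], reverse=True)
    hyps, lps = [], []
    for prefix, lp, finished in beams:
        ids = prefix[:-1] if finished else prefix
        hyps.append(backend.decode(ids))
        lps.append(lp)
    return BeamResult(hyps, lps)


def _rank_score(candidate, length_normalize: bool) -> float:
    prefix, lp, _ = candidate
    if length_normalize and prefix:
        return lp / len(prefix)
    return lp
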