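"""Evaluation of generated paragraphs and predicted GO terms.

Four families of scores:

* **Confidence** — for a beam search returning N final hypotheses with raw
  probabilities Prob(j), the confidence of the top hypothesis i is
  ``Prob(i) / sum_j Prob(j)``: how dominant the chosen paragraph is among
  the alternatives the decoder explored (N = 4 by default).
* **Embedding cosine** — cosine similarity in [-1, 1] between fixed-dimension
  embeddings of candidate and reference, averaged over a panel of embedders
  (the panel holds three slots by default, mirroring the common practice of
  averaging a general-domain, a distilled, and a biomedical sentence
  embedder).
* **Mover similarities** — WMS / SMS / S+WMS: exact optimal-transport
  (earth-mover) distances between weighted bags of word embeddings, sentence
  embeddings, or both, mapped to a similarity in (0, 1] by exp(-distance).
* **Fmax** — the protein-centric maximum-F1 of predicted GO terms over a
  score-threshold grid (CAFA convention), for the predicted-GO input path.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import IO, Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog
from scipy.special import logsumexp

from .summarizer import BeamResult

SCORE_CLASSES = {"high": (0.8, 1.0), "moderate": (0.5, 0.8), "low": (0.0, 0.5)}


# ---------------------------------------------------------------------------
# confidence


def confidence_score(beam: BeamResult) -> float:
    """Dominance of the top hypothesis: Prob(top) / sum of all N beam probabilities.

    Computed from log-probabilities with a max shift, so it is invariant to
    adding any constant to all log-probabilities and immune to underflow.
    """
    lp = np.asarray(beam.log_probs, dtype=float)
    if lp.size == 0:
        raise ValueError("empty beam")
    if np.any(~np.isfinite(lp)):
        raise ValueError("non-positive hypothesis probability")
    return float(np.exp(lp[0] - logsumexp(lp)))


def confidence_from_logprobs(log_probs: Sequence[float]) -> np.ndarray:
    """Eq.-style ratio for every hypothesis; the entries sum to 1."""
    lp = np.asarray(log_probs, dtype=float)
    return np.exp(lp - logsumexp(lp))


# ---------------------------------------------------------------------------
# embedders


class Embedder:
    """Deterministic map from text to a fixed-dimension vector.

    Wraps a name and a callable; same text must always yield the same vector.
    Pretrained sentence embedders plug in through this same interface.
    """

    def __init__(self, name: str, fn: Callable[[str], np.ndarray]):
        self.name = name
        self._fn = fn

    def __call__(self, text: str) -> np.ndarray:
        if not text.strip():
            raise ValueError(f"{self.name}: cannot embed empty text")
        return np.asarray(self._fn(text), dtype=float)


def hash_embedder(seed: int = 0, dim: int = 256, name: str | None = None) -> Embedder:
    """Vocabulary-free deterministic test embedder.

    Each word is hashed (with the seed) to seed a generator that draws a unit
    Gaussian direction in ``dim`` dimensions; a text embeds as the mean of
    its word vectors. Distinct words give near-orthogonal directions at high
    dimension, so shared-word content dominates the cosine.
    """
    cache: dict[str, np.ndarray] = {}

    def word_vec(word: str) -> np.ndarray:
        v = cache.get(word)
        if v is None:
            digest = hashlib.blake2b(f"{seed}:{word}".encode(), digest_size=8).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "little"))
            v = rng.standard_normal(dim)
            v /= np.linalg.norm(v)
            cache[word] = v
        return v

    def embed(text: str) -> np.ndarray:
        words = text.split()
        return np.mean([word_vec(w) for w in words], axis=0)

    return Embedder(name or f"hash-{dim}d-seed{seed}", embed)


def embedding_cosine(candidate: str, reference: str, e: Embedder) -> float:
    """Cosine similarity of the two embeddings, in [-1, 1]."""
    u, v = e(candidate), e(reference)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0:
        raise ValueError(f"zero-norm embedding for candidate text: {candidate[:40]!r}")
    if nv == 0:
        raise ValueError(f"zero-norm embedding for reference text: {reference[:40]!r}")
    return float(np.dot(u, v) / (nu * nv))


def average_embedding_score(candidate: str, reference: str, embedders: Sequence[Embedder]) -> float:
    """Arithmetic mean of per-embedder cosines over the configured panel."""
    if not embedders:
        raise ValueError("empty embedder list")
    return float(np.mean([embedding_cosine(candidate, reference, e) for e in embedders]))


def default_embedder_panel(seed: int = 0, dim: int = 256) -> list[Embedder]:
    """Three deterministic hash embedders filling the three panel slots."""
    return [hash_embedder(seed + k, dim) for k in range(3)]


# ---------------------------------------------------------------------------
# mover similarities (exact optimal transport)

_SENT_SPLIT = re.compile(r"(?<=[.!?])\s+(?=[A-Z])")


def split_sentences(text: str) -> list[str]:
    """Deterministic segmentation: sentence-final punctuation + whitespace + uppercase."""
    parts = [s.strip() for s in _SENT_SPLIT.split(text.strip()) if s.strip()]
    return parts or [text.strip()]


def exact_emd(
    cost: np.ndarray, a: np.ndarray, b: np.ndarray
) -> float:
    """Optimal value of the exact transportation problem (linear program).

    Minimizes <cost, P> over plans P >= 0 with row sums ``a`` and column sums
    ``b`` (both normalized to total mass 1).
    """
    cost = np.asarray(cost, dtype=float)
    a = np.asarray(a, dtype=float) / np.sum(a)
    b = np.asarray(b, dtype=float) / np.sum(b)
    m, n = cost.shape
    A_eq = np.zeros((m + n - 1, m * n))
    for i in range(m):
        A_eq[i, i * n : (i + 1) * n] = 1.0
    for j in range(n - 1):  # last column constraint is redundant
        A_eq[m + j, j::n] = 1.0
    b_eq = np.concatenate([a, b[:-1]])
    res = linprog(cost.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def _word_bag(text: str, e: Embedder, stop_words: frozenset[str] = frozenset()) -> tuple[np.ndarray, np.ndarray]:
    words = [w for w in text.split() if w not in stop_words]
    if not words:
        words = text.split()  # never let stop-word removal empty a bag
    uniq: dict[str, int] = {}
    for w in words:
        uniq[w] = uniq.get(w, 0) + 1
    vecs = np.array([e(w) for w in uniq])
    weights = np.array(list(uniq.values()), dtype=float)
    return vecs, weights / weights.sum()


def _sentence_bag(text: str, e: Embedder) -> tuple[np.ndarray, np.ndarray]:
    sents = split_sentences(text)
    vecs = np.array([e(s) for s in sents])
    weights = np.array([len(s.split()) for s in sents], dtype=float)
    return vecs, weights / weights.sum()


def _combined_bag(text: str, e: Embedder) -> tuple[np.ndarray, np.ndarray]:
    wv, ww = _word_bag(text, e)
    sv, sw = _sentence_bag(text, e)
    vecs = np.vstack([wv, sv])
    weights = np.concatenate([ww, sw])
    return vecs, weights / weights.sum()


_BAGS = {"WMS": _word_bag, "SMS": _sentence_bag, "S+WMS": _combined_bag}


def mover_distance(
    candidate: str,
    reference: str,
    e: Embedder,
    mode: str = "WMS",
    stop_words: frozenset[str] = frozenset(),
) -> float:
    """Exact earth-mover distance between the two documents' weighted bags.

    WMS uses bags of word embeddings weighted by counts; SMS bags of sentence
    embeddings (mean of word vectors) weighted by sentence length; S+WMS the
    renormalized union of both. Ground cost is Euclidean distance. Stop-word
    removal (word bags only) is off unless a word set is supplied.
    """
    if mode not in _BAGS:
        raise ValueError(f"unknown mode: {mode!r} (use WMS, SMS or S+WMS)")
    if not candidate.strip() or not reference.strip():
        raise ValueError("mover distance requires non-empty texts")
    if mode == "WMS" and stop_words:
        va, wa = _word_bag(candidate, e, stop_words)
        vb, wb = _word_bag(reference, e, stop_words)
    else:
        va, wa = _BAGS[mode](candidate, e)
        vb, wb = _BAGS[mode](reference, e)
    cost = np.linalg.norm(va[:, None, :] - vb[None, :, :], axis=2)
    return exact_emd(cost, wa, wb)


def mover_similarity(
    candidate: str,
    reference: str,
    e: Embedder,
    mode: str = "WMS",
    stop_words: frozenset[str] = frozenset(),
) -> float:
    """Similarity in (0, 1]: exp(-distance). 1.0 iff the bags coincide."""
    return float(np.exp(-mover_distance(candidate, reference, e, mode, stop_words)))


# ---------------------------------------------------------------------------
# win rate


def win_fraction(scores_a: Sequence[float], scores_b: Sequence[float]) -> float:
    """Fraction of paired entries where a strictly beats b (ties are non-wins)."""
    if len(scores_a) != len(scores_b):
        raise ValueError(f"length mismatch: {len(scores_a)} vs {len(scores_b)}")
    if not scores_a:
        raise ValueError("empty score lists")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    return float(np.mean(a > b))


# ---------------------------------------------------------------------------
# Fmax


@dataclass
class FmaxInput:
    """Per-protein predicted GO terms with scores, plus ground-truth term sets."""

    predictions: Mapping[str, Mapping[str, float]]
    truth: Mapping[str, frozenset[str] | set[str]]

    def __post_init__(self) -> None:
        for acc, scored in self.predictions.items():
            for gid, s in scored.items():
                if not 0 <= s <= 1:
                    raise ValueError(f"{acc}/{gid}: score {s} outside [0, 1]")


def compute_fmax(inp: FmaxInput, thresholds: Sequence[float] | None = None) -> float:
    """Protein-centric Fmax over a threshold grid (default 0.01 steps on (0, 1]).

    At each threshold t, precision averages |pred_t ∩ truth| / |pred_t| over
    proteins with at least one prediction scoring >= t, and recall averages
    |pred_t ∩ truth| / |truth| over every protein with non-empty truth; Fmax
    is the maximum harmonic mean across thresholds (0 where undefined).
    """
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0 + 1e-9, 0.01)
    truth = {acc: frozenset(t) for acc, t in inp.truth.items() if t}
    if not truth:
        raise ValueError("no protein has non-empty ground truth")
    fmax = 0.0
    for t in thresholds:
        precisions, recalls = [], []
        for acc, true_set in truth.items():
            pred_t = {g for g, s in inp.predictions.get(acc, {}).items() if s >= t}
            if pred_t:
                precisions.append(len(pred_t & true_set) / len(pred_t))
            recalls.append(len(pred_t & true_set) / len(true_set))
        if not precisions:
            continue
        p = float(np.mean(precisions))
        r = float(np.mean(recalls))
        if p + r > 0:
            fmax = max(fmax, 2 * p * r / (p + r))
    return fmax


def read_predictions_tsv(stream: IO[str]) -> dict[str, dict[str, float]]:
    """Predictions TSV: accession<TAB>GO id<TAB>score."""
    preds: dict[str, dict[str, float]] = {}
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("!"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise ValueError(f"line {lineno}: expected accession<TAB>GO id<TAB>score")
        acc, gid, score = parts
        preds.setdefault(acc, {})[gid] = float(score)
    return preds


# ---------------------------------------------------------------------------
# per-dataset report


@dataclass
class ScoreRow:
    accession: str
    cosines: dict[str, float]
    average_embedding: float
    wms: float
    sms: float
    s_wms: float
    confidence: float


@dataclass
class ScoreReport:
    """Per-entry scores plus the confidence-by-accuracy-class aggregation."""

    rows: list[ScoreRow] = field(default_factory=list)

    def class_of(self, score: float) -> str:
        if score >= 0.8:
            return "high"
        if score >= 0.5:
            return "moderate"
        return "low"

    def class_counts(self) -> dict[str, int]:
        counts = {"high": 0, "moderate": 0, "low": 0}
        for r in self.rows:
            counts[self.class_of(r.average_embedding)] += 1
        return counts

    def confidence_by_class(self) -> dict[str, list[float]]:
        out: dict[str, list[float]] = {"high": [], "moderate": [], "low": []}
        for r in self.rows:
            out[self.class_of(r.average_embedding)].append(r.confidence)
        return out

    def write_tsv(self, stream: IO[str]) -> None:
        names = sorted(self.rows[0].cosines) if self.rows else []
        header = ["accession", *[f"cosine_{n}" for n in names], "avg_embedding", "wms", "sms", "s_wms", "confidence"]
        stream.write("\t".join(header) + "\n")
        for r in self.rows:
            vals = [r.accession]
            vals += [f"{r.cosines[n]:.4f}" for n in names]
            vals += [f"{v:.4f}" for v in (r.average_embedding, r.wms, r.sms, r.s_wms, r.confidence)]
            stream.write("\t".join(vals) + "\n")


def score_report(
    entries: Sequence[tuple[str, str, str]],
    beams: Mapping[str, BeamResult],
    embedders: Sequence[Embedder],
    mover_embedder: Embedder | None = None,
) -> ScoreReport:
    """Score (accession, candidate, reference) entries with the full panel.

    ``beams`` supplies the beam result per accession for the confidence
    column; the first embedder doubles as the mover-metric embedder unless
    one is given explicitly.
    """
    me = mover_embedder or embedders[0]
    report = ScoreReport()
    for acc, candidate, reference in entries:
        cosines = {e.name: embedding_cosine(candidate, reference, e) for e in embedders}
        report.rows.append(
            ScoreRow(
                accession=acc,
                cosines=cosines,
                average_embedding=float(np.mean(list(cosines.values()))),
                wms=mover_similarity(candidate, reference, me, "WMS"),
                sms=mover_similarity(candidate, reference, me, "SMS"),
                s_wms=mover_similarity(candidate, reference, me, "S+WMS"),
                confidence=confidence_score(beams[acc]),
            )
        )
    return report
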