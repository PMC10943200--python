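# Methods

## Problem and pipeline

A protein's function is commonly recorded as a set of Gene Ontology (GO)
terms drawn from three namespaces — biological process (BP), cellular
component (CC), molecular function (MF) — each term carrying a short
free-text definition. The package treats "describe this protein in prose"
as abstractive summarization: concatenate the definitions of all annotated
terms into a *GO document* and condense it into a section paragraph of the
kind curated databases maintain (Function, Subunit structure, Pathway).
Stages: corpus construction → annotation-overlap redundancy reduction →
per-section dataset assembly and splitting → encoder–decoder training →
beam-search generation with a confidence score → evaluation.

## Corpus construction

Definitions are joined with single spaces in ascending GO-id order
(namespace-grouped BP→CC→MF order is available); the order is a free choice
— nothing in the task fixes one — and ascending id was picked for
determinism. Definitions lacking terminal punctuation get a "." appended so
sentence boundaries survive for the sentence-mover metrics. Documents are
truncated to the first `max_tokens` whitespace words (default 1024, the
input budget of the full-scale summarizer); subword re-tokenization and its
own cap are the backend's business, keeping this layer model-agnostic.
Multi-line OBO definitions are collapsed to single-spaced text. Only
id/name/namespace/def/is_obsolete are read from OBO: the pipeline uses no
DAG structure, so `is_a` edges are deliberately ignored.

## Redundancy reduction

Overlap of two annotation sets is |A∩B| / min(|A|,|B|) — equivalently the
larger of the two fractions using either set as denominator. It is 1 exactly
when the smaller set is contained in the larger; a containment coefficient
rather than Jaccard, so a sparsely annotated protein nested inside a richly
annotated one still counts as redundant. Clustering at threshold 0.90 uses
single-linkage connected components: the unique parameter-free rule that
guarantees every between-cluster pair falls below threshold (a greedy
leader variant is available for comparison but has no such guarantee). One
representative per cluster is drawn uniformly with a recorded seed.
All-pairs computation uses an inverted GO-id index so only pairs sharing at
least one term are compared; cost is O(n²) in the worst case, which is the
documented scaling boundary of this implementation.

## Datasets and splits

Each section gets its own dataset because entries rarely carry all three
paragraphs; a protein with several paragraphs appears in several datasets,
and the three sections are split independently. The split is a seeded
uniform shuffle partitioned as ⌊0.8 n⌋ / ⌊0.1 n⌋ / remainder — no
stratification — which reproduces e.g. 97,600 → 78,080/9,760/9,760 exactly.
Records are keyed by accession, so within a section a protein never
straddles train and test.

## Summarizer

`TrainingConfig` defaults (100 epochs, Adam at 1e-4, batch 4, input cap
1024, target cap 256, early stopping on validation cross-entropy with
patience 5) are the recipe for fine-tuning a large pretrained
encoder–decoder (12-block, 12-head, 768-dim transformer class). That
full-scale training is out of scope here; the contract `SummarizerBackend`
(tokenizer + proper conditional next-token distribution + batched
cross-entropy step) is what the rest of the package depends on.

The bundled backend, `TinySeq2Seq`, is a from-scratch numpy model sized for
CPU: word-level tokenizer over the training corpus, 32-dim embeddings, one
attention head over the input embeddings queried by the two previous target
tokens, mean-pooled input context, one 64-unit ReLU layer, softmax output.
Gradients are closed-form (verified against finite differences in the test
suite) and applied with Adam. Trained from random initialization it needs a
larger step than a fine-tuned pretrained model, so its training profile is
epochs 40, learning rate 3e-3, batch 4, patience 8; one integer seed drives
initialization and shuffling, and single-threaded runs are bit-reproducible.

Beam search keeps the `beam_width` highest-scoring partial sequences;
a sequence emitting EOS is frozen but keeps competing for its slot, and
search stops when all beams are finished or the target-length bound is hit.
A hypothesis scores the sum of its token log-probabilities — the raw
product of probabilities, no length penalty — because the confidence ratio
consumes plain probabilities; whether length normalization is appropriate
is genuinely open, so it exists behind a flag (ranking only; reported
probabilities stay raw). Probabilities live in log space end to end.

## Confidence score

For the N final hypotheses (N = 4 by default), confidence of the top
hypothesis i is Prob(i) / Σⱼ Prob(j), computed from log-probabilities via a
max shift. It sums to 1 over the beam, equals 1/N under indifference, and
is invariant to uniform log-probability shifts. The top-1 hypothesis is
always the one scored.

## Evaluation metrics

*Embedding cosine.* Candidate and reference embed to fixed-dimension
vectors; score is the cosine in [-1, 1], averaged over a three-slot embedder
panel. Pretrained sentence embedders plug into the `Embedder` contract; the
package ships a deterministic hash embedder (each word hashes to a seeded
unit Gaussian direction, text = mean of word vectors, 256-dim) used by the
whole test suite: shared words dominate the cosine and distinct words are
near-orthogonal, so it orders candidate quality sensibly without any
download.

*Mover similarities.* WMS treats documents as count-weighted bags of word
embeddings; SMS as length-weighted bags of sentence embeddings (sentence =
mean of word vectors; segmentation splits on terminal punctuation followed
by whitespace and an uppercase letter, falling back to one sentence); S+WMS
is the renormalized union of both bags. Bags normalize to mass 1, ground
cost is Euclidean, the transport problem is solved exactly as a linear
program (HiGHS), and similarity = exp(−distance) ∈ (0, 1] — distances are
also exposed raw, since a "similarity in (0,1] that is a minimum transport
cost" admits both readings and the exponential map is the convention of the
metrics' source formulation. No stop-word removal by default (a flagless
hand-rolled list would be arbitrary); the word bags use whitespace tokens.

*Win rate* counts strictly greater paired scores; ties are non-wins.

*Fmax.* Protein-centric CAFA convention: at each threshold t on a 0.01
grid, precision averages over proteins with ≥1 prediction scoring ≥ t,
recall over all truth-bearing proteins; Fmax is the best harmonic mean.
Tested against exhaustive enumeration of all distinct scores.

## Perturbation protocols

Deletion: targets have exactly 8 terms of the probed category, ≥1 term of
each other category, 10–24 terms total; k = 1..7 category terms are removed
uniformly (other categories untouched), three seeded trials per (target, k),
scores averaged over trials then targets, curve keyed by terms *remaining*.
Addition: exactly 5 category terms, 7–15 total, original document ≤ 512
tokens (headroom under the 1024 input cap); k = 1..10 "irrelevant" terms —
defined as vocabulary terms not annotated to the protein, with an optional
exclusion hook — are added; curve keyed by terms added. Trial seeds derive
from a seed sequence spawned per (target, k, trial), so trials are
independent across cells but fully reproducible.

## Synthetic world

The fixture generator is a pure function of (spec, seed). Vocabulary:
templated one-to-three-sentence definitions per namespace over a bundled
word bank, pairwise distinct. Proteins: annotation sets of 4–10 terms with
≥1 term per namespace; engineered redundancy groups share a core of
⌈overlap·m⌉ terms (disjoint pools across groups) so within-group overlap
meets the configured fraction by construction. References derive from the
annotation by a fixed compositional rule — one clause per term, ascending
id, Function ≤ 4 clauses, Subunit from CC terms, Pathway one short sentence
from the first BP term — so identical annotations give identical paragraphs
and the document→paragraph mapping is learnable by a small model; lengths
order Pathway < Subunit < Function as in real section paragraphs.
Per-section availability is a seeded Bernoulli draw (defaults 1.0 / 0.64 /
0.15, mirroring the relative sizes of real Function / Subunit / Pathway
datasets). Synthetic GO-prediction scores (for the Fmax path) recover each
true term with probability 1 − corruption at a high score and inject a
matching number of false terms lower.

What passing tests do **not** show: the templated world has a closed
vocabulary, deterministic reference rules and no paraphrase, so success
here demonstrates the pipeline's correctness and the learnability machinery
— not that a small model (or any model) reaches useful quality on curated
database prose, which requires full-scale data and a pretrained backend.

## Study scales

The end-to-end properties run on a 400-protein world (320/40/40 Function
split, ~85-word vocabulary model) where training takes seconds; the
deletion curve uses 10 engineered targets × 3 trials × 7 levels. The
trained-vs-untrained comparison asks the fitted backend to beat its
randomly initialized clone on the average embedding score for ≥ 90 % of
held-out records — the desk-scale analogue of fine-tuned-vs-vanilla win
rates — and the observed win rate is 100 % across seeds; the deletion curve
declines monotonically from full annotation to one remaining term.

## Known limitations

* O(n²) worst-case clustering; fine at desk scale, not at database scale.
* The exact-transport LP is dense; bags beyond a few hundred atoms (very
  long paragraphs under S+WMS) get slow. Entropic approximations are out of
  scope because the oracle tests require exactness.
* Whitespace word tokenization ties WMS bags and token caps to surface
  forms; no lemmatization or casefolding.
* The hash embedder measures lexical overlap in disguise; it cannot reward
  true paraphrase the way pretrained embedders do.
* `TinySeq2Seq`'s two-token decoder context limits long-range coherence;
  it is a reference implementation of the contract, not a quality target.
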