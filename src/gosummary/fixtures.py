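"""Self-contained synthetic GO world for tests and desk-scale experiments.

Everything downstream — parsing, clustering, dataset assembly, training,
scoring, perturbation — runs against data generated here, so no external
GO release, annotation file or reference corpus is ever needed. The world is
deliberately templated rather than linguistically realistic: every GO term
gets a unique definition composed from namespace-specific templates over a
bundled word bank, and every protein's reference paragraphs are derived from
its annotation set by a fixed compositional rule (one clause per term). That
rule-based mapping is what makes the document -> paragraph task learnable by
a small CPU-trained model; it is a fidelity trade-off, not an attempt to
mimic UniProt prose.

Generation is a pure function of (spec, seed): the same spec reproduces a
byte-identical world, and writers emit minimal valid OBO 1.2 / GAF 2.2 /
TSV dialects so the on-disk readers are exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Mapping, Sequence

import numpy as np

from .go_corpus import AnnotationSet, GOTerm, build_document
from .perturbation import PerturbationConfig
from .scoring import Embedder, hash_embedder

# bundled word bank: enough combinations for a few hundred distinct terms
NOUNS = [
    "kinase", "ribosome", "chromatin", "membrane", "vesicle", "microtubule",
    "proteasome", "nucleosome", "polymerase", "ligase", "receptor", "channel",
    "transporter", "filament", "organelle", "centromere", "telomere", "spindle",
    "lysosome", "peroxisome", "mitochondrion", "flagellum", "ribonuclease",
    "helicase", "phosphatase", "protease", "chaperone", "cofactor", "substrate",
    "histone",
]
QUALIFIERS = [
    "primary", "secondary", "catalytic", "regulatory", "structural",
    "transient", "stable", "inner", "outer", "terminal",
]

_NS_LONG = {"BP": "biological_process", "CC": "cellular_component", "MF": "molecular_function"}

_DEF_TEMPLATES = {
    "MF": "Binding to a {qual} {noun}.",
    "BP": "A process that regulates {qual} {noun} dynamics.",
    "CC": "A cellular component found in the {qual} {noun} region.",
}
_EXTRA_SENTENCE = " It also contributes to {noun2} turnover."

_CLAUSE_TEMPLATES = {
    "MF": "It binds {qual} {noun}.",
    "BP": "It regulates {qual} {noun} dynamics.",
    "CC": "It is found in the {qual} {noun} region.",
}


@dataclass
class FixtureSpec:
    """Parameters of the synthetic world.

    Section availability defaults mirror the relative sizes of real per-section
    datasets (Function available for every entry, Subunit for ~64%, Pathway
    for ~15%).
    """

    n_terms: dict[str, int] = field(default_factory=lambda: {"BP": 40, "CC": 30, "MF": 30})
    n_proteins: int = 100
    terms_per_protein: tuple[int, int] = (4, 10)
    redundancy_groups: list[tuple[int, float]] = field(default_factory=list)
    section_availability: dict[str, float] = field(
        default_factory=lambda: {"Function": 1.0, "Subunit": 0.64, "Pathway": 0.15}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_terms.values()) or self.n_proteins <= 0:
            raise ValueError("term and protein counts must be positive")
        if not all(0 <= f <= 1 for f in self.section_availability.values()):
            raise ValueError("availability fractions must lie in [0, 1]")


def make_vocabulary(spec: FixtureSpec) -> dict[str, GOTerm]:
    """Deterministic templated vocabulary; distinct terms get distinct definitions."""
    vocab: dict[str, GOTerm] = {}
    serial = 1
    for ns in ("BP", "CC", "MF"):
        n = spec.n_terms.get(ns, 0)
        if n > len(NOUNS) * len(QUALIFIERS):
            raise ValueError(f"{ns}: at most {len(NOUNS) * len(QUALIFIERS)} distinct terms supported")
        for i in range(n):
            noun = NOUNS[i % len(NOUNS)]
            qual = QUALIFIERS[(i // len(NOUNS)) % len(QUALIFIERS)]
            definition = _DEF_TEMPLATES[ns].format(qual=qual, noun=noun)
            if i % 3 == 0:  # vary definition length: some terms get a second sentence
                definition += _EXTRA_SENTENCE.format(noun2=NOUNS[(i + 7) % len(NOUNS)])
            gid = f"GO:{serial:07d}"
            serial += 1
            vocab[gid] = GOTerm(gid, ns, f"{qual} {noun} {ns.lower()}", definition)
    return vocab


def _term_meta(term: GOTerm) -> tuple[str, str]:
    """Recover (qualifier, noun) from a synthetic term's name."""
    qual, noun, _ = term.name.split(" ")
    return qual, noun


def reference_paragraphs(ann: AnnotationSet, vocab: Mapping[str, GOTerm]) -> dict[str, str]:
    """Rule-derived reference paragraphs: identical annotations give identical text.

    Function: one clause per term for up to the first four terms (ascending
    GO id) — 2-4 sentences. Subunit: clauses from the first two CC terms (or
    a fixed monomer sentence) — 1-2 sentences. Pathway: one short sentence
    from the first BP term. Lengths therefore order Pathway < Subunit <
    Function, matching real section-length ordering.
    """
    ids = sorted(ann.go_ids)
    clauses = []
    for g in ids[:4]:
        term = vocab[g]
        qual, noun = _term_meta(term)
        clauses.append(_CLAUSE_TEMPLATES[term.namespace].format(qual=qual, noun=noun))
    function = " ".join(clauses)

    cc_ids = [g for g in ids if vocab[g].namespace == "CC"][:2]
    if cc_ids:
        parts = []
        for g in cc_ids:
            qual, noun = _term_meta(vocab[g])
            parts.append(f"Forms a complex in the {qual} {noun} region.")
        subunit = " ".join(parts)
    else:
        subunit = "Monomer in solution."

    bp_ids = [g for g in ids if vocab[g].namespace == "BP"]
    if bp_ids:
        qual, noun = _term_meta(vocab[bp_ids[0]])
        pathway = f"Acts in the {qual} {noun} pathway."
    else:
        pathway = "No defined pathway."

    return {"Function": function, "Subunit": subunit, "Pathway": pathway}


def make_proteins(
    spec: FixtureSpec, vocab: Mapping[str, GOTerm]
) -> tuple[list[AnnotationSet], dict[str, dict[str, str]]]:
    """Draw annotation sets (with designated redundancy groups) and references.

    Group members share a core of terms large enough that every within-group
    pairwise overlap meets the configured fraction; different groups draw
    from disjoint term pools so between-group overlap stays low. Reference
    paragraphs come from :func:`reference_paragraphs`; per-section presence
    is a seeded Bernoulli draw at the configured availability.
    """
    rng = np.random.default_rng(spec.seed)
    all_ids = sorted(vocab)
    by_ns = {ns: sorted(g for g in vocab if vocab[g].namespace == ns) for ns in ("BP", "CC", "MF")}
    lo, hi = spec.terms_per_protein

    anns: list[AnnotationSet] = []
    serial = 1
    used_by_groups: set[str] = set()

    for size, overlap in spec.redundancy_groups:
        if not 0 < overlap <= 1:
            raise ValueError(f"group overlap {overlap} outside (0, 1]")
        m = hi  # largest allowed size keeps the shared core from being the whole set
        core_n = math.ceil(overlap * m)
        extras_n = m - core_n
        need = core_n + extras_n * size
        available = [g for g in all_ids if g not in used_by_groups]
        if need > len(available):
            raise ValueError(
                f"infeasible overlap constraints: group needs {need} fresh terms, {len(available)} left"
            )
        drawn = list(rng.choice(available, size=need, replace=False))
        core = set(drawn[:core_n])
        used_by_groups.update(drawn)
        for member in range(size):
            extras = set(drawn[core_n + member * extras_n : core_n + (member + 1) * extras_n])
            anns.append(AnnotationSet(f"P{serial:06d}", frozenset(core | extras)))
            serial += 1

    while len(anns) < spec.n_proteins:
        size = int(rng.integers(lo, hi + 1))
        # one term from each namespace first, then the rest from anywhere
        chosen = {str(rng.choice(by_ns[ns])) for ns in ("BP", "CC", "MF") if by_ns[ns]}
        remaining = [g for g in all_ids if g not in chosen]
        extra = max(0, size - len(chosen))
        chosen.update(rng.choice(remaining, size=min(extra, len(remaining)), replace=False).tolist())
        anns.append(AnnotationSet(f"P{serial:06d}", frozenset(chosen)))
        serial += 1

    references: dict[str, dict[str, str]] = {}
    for ann in anns:
        paragraphs = reference_paragraphs(ann, vocab)
        kept = {
            section: text
            for section, text in paragraphs.items()
            if rng.random() < spec.section_availability.get(section, 0.0)
        }
        references[ann.accession] = kept
    return anns, references


def make_perturbation_pool(
    vocab: Mapping[str, GOTerm],
    cfg: PerturbationConfig,
    n_matching: int,
    n_nonmatching: int,
    seed: int = 0,
) -> list[AnnotationSet]:
    """Engineer a protein pool where exactly ``n_matching`` satisfy the target filter.

    Matching proteins carry exactly ``cfg.exact_category_count`` terms of the
    target category, at least one term of each other category, and a total
    inside ``cfg.total_range``; non-matching proteins violate the
    category-count requirement by one.
    """
    rng = np.random.default_rng(seed)
    by_ns = {ns: sorted(g for g in vocab if vocab[g].namespace == ns) for ns in ("BP", "CC", "MF")}
    others = [ns for ns in ("BP", "CC", "MF") if ns != cfg.category]
    lo, hi = cfg.total_range
    out: list[AnnotationSet] = []
    for i in range(n_matching + n_nonmatching):
        matching = i < n_matching
        cat_n = cfg.exact_category_count if matching else cfg.exact_category_count + 1
        total = int(rng.integers(max(lo, cat_n + 2), hi + 1))
        chosen = set(rng.choice(by_ns[cfg.category], size=cat_n, replace=False).tolist())
        rest = total - cat_n  # >= 2, split across the two other categories
        for ns, n_take in zip(others, (rest // 2, rest - rest // 2)):
            chosen.update(rng.choice(by_ns[ns], size=min(n_take, len(by_ns[ns])), replace=False).tolist())
        out.append(AnnotationSet(f"T{i:06d}", frozenset(chosen)))
    return out


def make_predictions(
    anns: Sequence[AnnotationSet],
    vocab: Mapping[str, GOTerm],
    corruption_rate: float = 0.3,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Synthetic GO-prediction scores standing in for an upstream predictor's output.

    Each true term is recovered with probability ``1 - corruption_rate`` at a
    high score; a matching number of false terms is injected at lower
    scores. Output matches the predictions-TSV schema consumed by Fmax.
    """
    if not 0 <= corruption_rate <= 1:
        raise ValueError("corruption_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    all_ids = sorted(vocab)
    preds: dict[str, dict[str, float]] = {}
    for ann in anns:
        scored: dict[str, float] = {}
        for g in sorted(ann.go_ids):
            if rng.random() >= corruption_rate:
                scored[g] = float(np.round(rng.uniform(0.6, 1.0), 4))
        n_false = rng.binomial(len(ann.go_ids), corruption_rate)
        candidates = [g for g in all_ids if g not in ann.go_ids]
        for g in rng.choice(candidates, size=min(n_false, len(candidates)), replace=False):
            scored[str(g)] = float(np.round(rng.uniform(0.1, 0.7), 4))
        preds[ann.accession] = scored
    return preds


def make_test_embedder(seed: int = 0, dim: int = 256) -> Embedder:
    """The deterministic hash embedder used throughout the test suite."""
    return hash_embedder(seed=seed, dim=dim)


# ---------------------------------------------------------------------------
# on-disk writers (minimal valid dialects)


def write_obo(vocab: Mapping[str, GOTerm], stream: IO[str]) -> None:
    """Minimal OBO 1.2 flat file with one [Term] stanza per term."""
    stream.write("format-version: 1.2\nontology: synthetic-go\n")
    for gid in sorted(vocab):
        t = vocab[gid]
        stream.write(
            f"\n[Term]\nid: {t.id}\nname: {t.name}\nnamespace: {_NS_LONG[t.namespace]}\n"
            f'def: "{t.definition}" [SYN:fixture]\n'
        )


def write_gaf(anns: Sequence[AnnotationSet], stream: IO[str]) -> None:
    """Minimal GAF 2.2: accession in column 2, GO id in column 5."""
    stream.write("!gaf-version: 2.2\n")
    for ann in anns:
        for g in sorted(ann.go_ids):
            cols = [
                "SYN", ann.accession, ann.accession, "enables", g, "SYN:0000001",
                "IEA", "", "F", "", "", "protein", "taxon:0000", "20240101", "SYN", "", "",
            ]
            stream.write("\t".join(cols) + "\n")


def write_predictions_tsv(preds: Mapping[str, Mapping[str, float]], stream: IO[str]) -> None:
    for acc in sorted(preds):
        for g in sorted(preds[acc]):
            stream.write(f"{acc}\t{g}\t{preds[acc][g]:.4f}\n")
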