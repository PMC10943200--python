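"""GO deletion / addition robustness protocols.

How much does summary quality depend on the completeness of a protein's GO
annotation? The deletion protocol picks proteins carrying exactly eight
terms of one target category (with at least one term in each other category
and 10-24 terms in total), removes 1-7 of the category terms at random, and
tracks the mean embedding score against the number of terms *remaining*. The
addition protocol picks proteins with exactly five category terms (7-15
total, original document <= 512 tokens so grown documents still fit the
input cap) and injects 1-10 random irrelevant terms. Each (target, k) cell
is averaged over three seeded trials, then over targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Callable, Mapping, Sequence

import numpy as np

from .go_corpus import AnnotationSet, GOTerm, build_document


@dataclass
class PerturbationConfig:
    mode: str = "deletion"  # deletion | addition
    category: str = "BP"
    exact_category_count: int | None = None  # default 8 (deletion) / 5 (addition)
    total_range: tuple[int, int] | None = None  # default (10, 24) / (7, 15)
    max_doc_tokens_for_addition: int = 512
    k_range: tuple[int, int] | None = None  # default (1, 7) / (1, 10)
    trials: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("deletion", "addition"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        if self.category not in ("BP", "CC", "MF"):
            raise ValueError(f"unknown category: {self.category!r}")
        if self.exact_category_count is None:
            self.exact_category_count = 8 if self.mode == "deletion" else 5
        if self.total_range is None:
            self.total_range = (10, 24) if self.mode == "deletion" else (7, 15)
        if self.k_range is None:
            self.k_range = (1, 7) if self.mode == "deletion" else (1, 10)
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if self.mode == "deletion" and self.k_range[1] >= self.exact_category_count:
            raise ValueError("deletion k_range must leave at least one category term")


@dataclass
class PerturbationCurve:
    """Mean score per k (terms remaining for deletion, terms added for addition)."""

    mode: str
    category: str
    points: dict[int, float]
    n_targets: int
    trials: int
    seed: int

    def write_tsv(self, stream: IO[str]) -> None:
        stream.write("mode\tcategory\tk\tmean_score\tn_targets\ttrials\tseed\n")
        for k in sorted(self.points):
            stream.write(
                f"{self.mode}\t{self.category}\t{k}\t{self.points[k]:.4f}"
                f"\t{self.n_targets}\t{self.trials}\t{self.seed}\n"
            )


def _category_counts(ann: AnnotationSet, vocab: Mapping[str, GOTerm]) -> dict[str, int]:
    counts = {"BP": 0, "CC": 0, "MF": 0}
    for g in ann.go_ids:
        counts[vocab[g].namespace] += 1
    return counts


def select_targets(
    anns: Sequence[AnnotationSet],
    vocab: Mapping[str, GOTerm],
    cfg: PerturbationConfig,
) -> list[AnnotationSet]:
    """Apply the target-selection filter for the configured protocol."""
    lo, hi = cfg.total_range
    out = []
    for ann in anns:
        counts = _category_counts(ann, vocab)
        if counts[cfg.category] != cfg.exact_category_count:
            continue
        if any(counts[c] < 1 for c in counts if c != cfg.category):
            continue
        if not lo <= len(ann.go_ids) <= hi:
            continue
        if cfg.mode == "addition":
            doc = build_document(ann, vocab)
            if doc.token_count > cfg.max_doc_tokens_for_addition:
                continue
        out.append(ann)
    return out


def perturb(
    ann: AnnotationSet,
    vocab: Mapping[str, GOTerm],
    cfg: PerturbationConfig,
    k: int,
    trial_seed: int,
    pool: Sequence[str] | None = None,
) -> AnnotationSet:
    """Remove k category terms, or add k pool terms, with a seeded uniform draw."""
    rng = np.random.default_rng(trial_seed)
    if cfg.mode == "deletion":
        category_terms = sorted(g for g in ann.go_ids if vocab[g].namespace == cfg.category)
        if k < 0 or k >= len(category_terms):
            raise ValueError(f"cannot remove {k} of {len(category_terms)} {cfg.category} terms")
        if k == 0:
            return ann
        removed = set(rng.choice(category_terms, size=k, replace=False))
        return AnnotationSet(ann.accession, ann.go_ids - removed)
    else:
        if pool is None:
            raise ValueError("addition mode requires a pool of candidate terms")
        pool = sorted(set(pool) - ann.go_ids)
        if k < 0:
            raise ValueError("k must be >= 0")
        if k == 0:
            return ann
        if len(pool) < k:
            raise ValueError(f"addition pool has {len(pool)} terms, need {k}")
        added = set(rng.choice(pool, size=k, replace=False))
        return AnnotationSet(ann.accession, ann.go_ids | added)


def run_curve(
    targets: Sequence[AnnotationSet],
    vocab: Mapping[str, GOTerm],
    cfg: PerturbationConfig,
    score_fn: Callable[[AnnotationSet], float],
    pool: Sequence[str] | None = None,
) -> PerturbationCurve:
    """Score each target under every perturbation level, averaging over trials.

    ``score_fn`` maps a (perturbed) annotation set to a score — typically:
    build the document, generate a summary with the trained backend, and
    return its average embedding score against the target's reference
    paragraph. Deletion curves are keyed by the number of category terms
    remaining; addition curves by the number of terms added.
    """
    if not targets:
        raise ValueError("no targets to perturb")
    ss = np.random.SeedSequence(cfg.seed)
    points: dict[int, float] = {}
    ks = range(cfg.k_range[0], cfg.k_range[1] + 1)
    for k in ks:
        per_target = []
        for t_idx, ann in enumerate(targets):
            trial_scores = []
            for trial in range(cfg.trials):
                child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(t_idx, k, trial))
                trial_seed = int(child.generate_state(1)[0] % (2**31))
                perturbed = perturb(ann, vocab, cfg, k, trial_seed, pool=pool)
                trial_scores.append(score_fn(perturbed))
            per_target.append(float(np.mean(trial_scores)))
        key = cfg.exact_category_count - k if cfg.mode == "deletion" else k
        points[key] = float(np.mean(per_target))
    return PerturbationCurve(cfg.mode, cfg.category, points, len(targets), cfg.trials, cfg.seed)
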