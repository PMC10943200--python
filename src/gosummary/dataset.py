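"""Per-section paired datasets and the 80/10/10 split.

Each UniProt-style section (Function, Subunit structure, Pathway) gets its
own dataset because an entry rarely carries all three paragraphs. A record
pairs a protein's GO document with its reference paragraph for one section.
Splitting is a seeded uniform shuffle partitioned by floor arithmetic:
|train| = floor(0.8 n), |val| = floor(0.1 n), test takes the remainder —
which reproduces printed counts like 97,600 -> 78,080/9,760/9,760 exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

from .go_corpus import AnnotationSet, GODocument, GOTerm, build_document

SECTIONS = ("Function", "Subunit", "Pathway")


@dataclass(frozen=True)
class SectionRecord:
    """One (GO document, reference paragraph) pair for one section."""

    accession: str
    section: str
    document: GODocument
    reference: str

    def __post_init__(self) -> None:
        if self.section not in SECTIONS:
            raise ValueError(f"unknown section: {self.section!r}")
        if not self.reference.strip():
            raise ValueError(f"{self.accession}: empty reference paragraph")


@dataclass
class DatasetSplit:
    train: list[SectionRecord]
    validation: list[SectionRecord]
    test: list[SectionRecord]
    seed: int
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def __iter__(self):
        return iter((self.train, self.validation, self.test))


def split_sizes(n: int, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)) -> tuple[int, int, int]:
    """Floor-rule sizes: (floor(f_train n), floor(f_val n), remainder)."""
    n_train = int(np.floor(fractions[0] * n))
    n_val = int(np.floor(fractions[1] * n))
    return n_train, n_val, n - n_train - n_val


def assemble_section(
    representatives: Sequence[AnnotationSet],
    vocab: Mapping[str, GOTerm],
    references: Mapping[str, Mapping[str, str]],
    section: str,
    max_tokens: int = 1024,
) -> list[SectionRecord]:
    """Build one section's dataset from the redundancy-reduced protein list.

    Proteins lacking a (non-empty) paragraph for ``section`` are simply
    excluded; a protein with all three paragraphs appears in all three
    section datasets.
    """
    if section not in SECTIONS:
        raise ValueError(f"unknown section: {section!r}")
    records = []
    for ann in representatives:
        paragraph = references.get(ann.accession, {}).get(section, "")
        if not paragraph.strip():
            continue
        doc = build_document(ann, vocab, max_tokens=max_tokens)
        records.append(SectionRecord(ann.accession, section, doc, paragraph))
    return records


def split_dataset(records: Sequence[SectionRecord], seed: int) -> DatasetSplit:
    """Shuffle with a seeded generator and partition 80/10/10 by the floor rule."""
    n = len(records)
    if n < 3:
        raise ValueError(f"need at least 3 records to populate all parts, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    shuffled = [records[i] for i in perm]
    n_train, n_val, _ = split_sizes(n)
    return DatasetSplit(
        train=shuffled[:n_train],
        validation=shuffled[n_train : n_train + n_val],
        test=shuffled[n_train + n_val :],
        seed=seed,
    )


def write_records_jsonl(records: Iterable[SectionRecord], stream: IO[str]) -> None:
    """Serialize records as JSONL {accession, section, input_text, target_text}."""
    for r in records:
        stream.write(
            json.dumps(
                {
                    "accession": r.accession,
                    "section": r.section,
                    "input_text": r.document.text,
                    "target_text": r.reference,
                }
            )
            + "\n"
        )


def read_records_jsonl(stream: IO[str]) -> list[SectionRecord]:
    out = []
    for line in stream:
        if not line.strip():
            continue
        row = json.loads(line)
        text = row["input_text"]
        doc = GODocument(row["accession"], text, len(text.split()), False)
        out.append(SectionRecord(row["accession"], row["section"], doc, row["target_text"]))
    return out


def read_references(stream: IO[str], fmt: str = "tsv") -> dict[str, dict[str, str]]:
    """Read reference paragraphs: TSV accession<TAB>section<TAB>paragraph, or JSONL."""
    refs: dict[str, dict[str, str]] = {}
    for lineno, line in enumerate(stream, start=1):
        if not line.strip():
            continue
        if fmt == "tsv":
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"line {lineno}: expected accession<TAB>section<TAB>paragraph")
            acc, section, paragraph = parts
        elif fmt == "jsonl":
            row = json.loads(line)
            acc, section, paragraph = row["accession"], row["section"], row["paragraph"]
        else:
            raise ValueError(f"unknown format: {fmt!r}")
        if section not in SECTIONS:
            raise ValueError(f"line {lineno}: unknown section {section!r}")
        refs.setdefault(acc, {})[section] = paragraph
    return refs


def write_references_tsv(refs: Mapping[str, Mapping[str, str]], stream: IO[str]) -> None:
    for acc in sorted(refs):
        for section in SECTIONS:
            if section in refs[acc] and refs[acc][section].strip():
                stream.write(f"{acc}\t{section}\t{refs[acc][section]}\n")
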