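"""GO vocabularies, protein annotations, and concatenated description documents.

A protein's *GO document* is the concatenation of the free-text definitions of
every GO term annotated to it (e.g. GO:0000049 carries the definition "Binding
to a transfer RNA."). That document is the input the summarizer condenses into
a UniProt-style paragraph. This module reads the two standard upstream formats
(OBO 1.2 term vocabularies, GAF 2.x annotation files, plus a simple TSV
dialect) and builds token-capped documents from them.
"""

from __future__ import annotations

import io
import json
import logging
import re
from dataclasses import dataclass
from typing import IO, Iterable, Literal, Mapping

import obonet

logger = logging.getLogger(__name__)

GO_ID_PATTERN = re.compile(r"^GO:\d{7}$")

#: OBO namespace name -> short category code
NAMESPACE_CODES = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
}

Namespace = Literal["BP", "CC", "MF"]


class ParseError(ValueError):
    """Raised when an input stream violates its format contract."""


@dataclass(frozen=True)
class GOTerm:
    """A Gene Ontology term: accession, category, label and free-text definition."""

    id: str
    namespace: Namespace
    name: str
    definition: str

    def __post_init__(self) -> None:
        if not GO_ID_PATTERN.match(self.id):
            raise ValueError(f"not a GO accession: {self.id!r}")
        if self.namespace not in ("BP", "CC", "MF"):
            raise ValueError(f"unknown namespace: {self.namespace!r}")
        if not self.definition.strip():
            raise ValueError(f"empty definition for {self.id}")


@dataclass(frozen=True)
class AnnotationSet:
    """A protein accession together with its (deduplicated) set of GO term ids."""

    accession: str
    go_ids: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "go_ids", frozenset(self.go_ids))
        for g in self.go_ids:
            if not GO_ID_PATTERN.match(g):
                raise ValueError(f"{self.accession}: not a GO accession: {g!r}")

    def __len__(self) -> int:
        return len(self.go_ids)


@dataclass(frozen=True)
class GODocument:
    """Concatenated GO-definition text for one protein, capped at ``max_tokens``."""

    accession: str
    text: str
    token_count: int
    truncated: bool


def _clean_definition(raw: str) -> str:
    """Strip OBO def decoration: surrounding quotes, trailing dbxref brackets, escapes."""
    s = raw.strip()
    # obonet keeps the raw `def` value: "<quoted text>" [dbxref, ...]
    m = re.match(r'^"(?P<text>(?:[^"\\]|\\.)*)"\s*(?:\[.*\])?\s*$', s, re.DOTALL)
    if m:
        s = m.group("text")
    s = s.replace('\\"', '"').replace("\\n", " ").replace("\\\\", "\\")
    # collapse internal whitespace; multi-paragraph definitions become one line
    return re.sub(r"\s+", " ", s).strip()


def parse_obo(stream: IO[str] | str) -> dict[str, GOTerm]:
    """Parse an OBO 1.2 flat file into a map from GO id to :class:`GOTerm`.

    Obsolete terms are skipped (with a logged count). A ``[Term]`` stanza
    missing its id, namespace or definition raises :class:`ParseError` naming
    the stanza.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    graph = obonet.read_obo(stream, ignore_obsolete=False)
    vocab: dict[str, GOTerm] = {}
    n_obsolete = 0
    for node, data in graph.nodes(data=True):
        if data.get("is_obsolete") == "true":
            n_obsolete += 1
            continue
        if not GO_ID_PATTERN.match(node):
            raise ParseError(f"stanza {node!r}: id is not a GO accession")
        ns = data.get("namespace")
        if ns not in NAMESPACE_CODES:
            raise ParseError(f"stanza {node}: missing or unknown namespace {ns!r}")
        raw_def = data.get("def")
        if raw_def is None:
            raise ParseError(f"stanza {node}: missing def line")
        definition = _clean_definition(raw_def)
        if not definition:
            raise ParseError(f"stanza {node}: empty definition")
        vocab[node] = GOTerm(
            id=node,
            namespace=NAMESPACE_CODES[ns],
            name=data.get("name", ""),
            definition=definition,
        )
    if n_obsolete:
        logger.info("parse_obo: skipped %d obsolete term(s)", n_obsolete)
    return vocab


def parse_annotations(
    stream: IO[str] | str, dialect: Literal["gaf", "tsv"] = "gaf"
) -> list[AnnotationSet]:
    """Read protein GO annotations from a GAF 2.x file or a simple TSV dialect.

    GAF: tab-separated with the accession in column 2 and the GO id in column
    5; comment lines start with ``!``. Simple TSV: ``accession<TAB>GO:...,GO:...``.
    Rows sharing an accession merge into one :class:`AnnotationSet`; an
    invalid GO id raises :class:`ParseError` with its line number; accessions
    left with zero ids are dropped with a warning.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    by_acc: dict[str, set[str]] = {}
    order: list[str] = []

    def add(acc: str, gid: str, lineno: int) -> None:
        if not GO_ID_PATTERN.match(gid):
            raise ParseError(f"line {lineno}: invalid GO id {gid!r}")
        if acc not in by_acc:
            by_acc[acc] = set()
            order.append(acc)
        by_acc[acc].add(gid)

    if dialect == "gaf":
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise ParseError(f"line {lineno}: GAF row has {len(cols)} columns, need >= 5")
            add(cols[1].strip(), cols[4].strip(), lineno)
    elif dialect == "tsv":
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("!"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"line {lineno}: expected accession<TAB>id,id,...")
            acc, ids = parts
            for gid in ids.split(","):
                gid = gid.strip()
                if gid:
                    add(acc.strip(), gid, lineno)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    out: list[AnnotationSet] = []
    for acc in order:
        if not by_acc[acc]:
            logger.warning("parse_annotations: %s has no valid GO ids; dropped", acc)
            continue
        out.append(AnnotationSet(acc, frozenset(by_acc[acc])))
    return out


class MissingTermError(KeyError):
    """Raised in strict mode when annotated GO ids are absent from the vocabulary."""

    def __init__(self, accession: str, missing: Iterable[str]):
        self.accession = accession
        self.missing = sorted(missing)
        super().__init__(f"{accession}: GO ids missing from vocabulary: {', '.join(self.missing)}")


def _ensure_sentence(text: str) -> str:
    return text if text.endswith((".", "!", "?")) else text + "."


def build_document(
    ann: AnnotationSet,
    vocab: Mapping[str, GOTerm],
    max_tokens: int = 1024,
    order: Literal["go_id", "namespace"] = "go_id",
    strict: bool = True,
) -> GODocument:
    """Concatenate the definitions of ``ann``'s GO terms into a capped document.

    Definitions are joined with single spaces in a deterministic order
    (ascending GO id by default, or grouped BP -> CC -> MF) and truncated to
    the first ``max_tokens`` whitespace tokens. In lenient mode ids absent
    from ``vocab`` are skipped with a warning; strict mode raises
    :class:`MissingTermError` listing them.
    """
    if max_tokens < 1:
        raise ValueError("max_tokens must be >= 1")
    if not ann.go_ids:
        raise ValueError(f"{ann.accession}: empty annotation set")
    missing = [g for g in ann.go_ids if g not in vocab]
    if missing:
        if strict:
            raise MissingTermError(ann.accession, missing)
        logger.warning(
            "build_document: %s: skipping %d id(s) missing from vocabulary", ann.accession, len(missing)
        )
    ids = [g for g in ann.go_ids if g in vocab]
    if not ids:
        raise ValueError(f"{ann.accession}: no annotated id present in vocabulary")
    if order == "go_id":
        ids.sort()
    elif order == "namespace":
        ns_rank = {"BP": 0, "CC": 1, "MF": 2}
        ids.sort(key=lambda g: (ns_rank[vocab[g].namespace], g))
    else:
        raise ValueError(f"unknown order rule: {order!r}")
    text = " ".join(_ensure_sentence(vocab[g].definition) for g in ids)
    tokens = text.split()
    truncated = len(tokens) > max_tokens
    if truncated:
        tokens = tokens[:max_tokens]
        text = " ".join(tokens)
    return GODocument(ann.accession, text, len(tokens), truncated)


def write_documents_jsonl(docs: Iterable[GODocument], stream: IO[str]) -> None:
    """Export documents as JSONL rows {accession, text, token_count, truncated}."""
    for d in docs:
        stream.write(
            json.dumps(
                {
                    "accession": d.accession,
                    "text": d.text,
                    "token_count": d.token_count,
                    "truncated": d.truncated,
                }
            )
            + "\n"
        )


def read_documents_jsonl(stream: IO[str]) -> list[GODocument]:
    docs = []
    for line in stream:
        if line.strip():
            r = json.loads(line)
            docs.append(GODocument(r["accession"], r["text"], r["token_count"], r["truncated"]))
    return docs


def write_annotations_tsv(anns: Iterable[AnnotationSet], stream: IO[str]) -> None:
    """Write the simple TSV annotation dialect (sorted ids, comma-joined)."""
    for a in anns:
        stream.write(f"{a.accession}\t{','.join(sorted(a.go_ids))}\n")
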