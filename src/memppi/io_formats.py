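"""Readers and writers for the pipeline's on-disk formats.

All formats are plain text, UTF-8:

* PubTator-style annotated abstracts: ``id|t|title`` and ``id|a|abstract``
  lines followed by tab-separated annotation lines
  ``id<TAB>start<TAB>end<TAB>surface<TAB>type<TAB>gene_id``; documents are
  separated by blank lines.  Character offsets are 0-based, half-open, over
  the string ``title + " " + abstract`` (the BioCreative interchange norm).
* Gold / predicted interacting pairs: TSV keyed by document id and an
  unordered Entrez Gene ID pair.
* Knowledge-base triples: 3-column TSV ``head<TAB>relation<TAB>tail``.
* Word vectors: word2vec text format (optional count/dim header line).
* Attention dumps: TSV of per-token attention weights.

Pairs are canonicalized by sorting the two gene ids lexicographically;
relations are undirected at evaluation time.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("memppi")

__all__ = [
    "Document",
    "Mention",
    "GoldPair",
    "TripleRecord",
    "PredictionRecord",
    "FormatError",
    "ParseError",
    "ValidationError",
    "canonical_pair",
    "read_pubtator",
    "write_pubtator",
    "read_pairs_tsv",
    "write_pairs_tsv",
    "read_triples_tsv",
    "write_triples_tsv",
    "read_word_vectors",
    "write_word_vectors",
    "read_predictions_tsv",
    "write_predictions_tsv",
    "write_attention_tsv",
]


class FormatError(ValueError):
    """A file does not conform to its documented format."""


class ParseError(FormatError):
    """A malformed line; the message names the offending line number."""


class ValidationError(FormatError):
    """Structurally parseable input violating a semantic invariant."""


def canonical_pair(gene_a: str, gene_b: str) -> tuple[str, str]:
    """Order an unordered gene-id pair lexicographically."""
    return (gene_a, gene_b) if gene_a <= gene_b else (gene_b, gene_a)


@dataclass(frozen=True)
class Document:
    """One abstract: id, title and abstract body.

    Offsets of mentions refer to ``text``, i.e. ``title + " " + abstract``.
    """

    doc_id: str
    title: str = ""
    abstract: str = ""

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValidationError("Document requires a non-empty doc_id")
        if not self.title and not self.abstract:
            raise ValidationError(
                f"Document {self.doc_id!r}: title and abstract both empty"
            )

    @property
    def text(self) -> str:
        return f"{self.title} {self.abstract}"


@dataclass(frozen=True)
class Mention:
    """A protein mention: character span plus normalized Entrez Gene ID."""

    doc_id: str
    start: int
    length: int
    surface: str
    gene_id: str
    type: str = "Gene"

    @property
    def end(self) -> int:
        return self.start + self.length

    def validate_against(self, doc: Document) -> None:
        sliced = doc.text[self.start : self.end]
        if sliced != self.surface:
            raise ValidationError(
                f"doc {doc.doc_id}: mention offset {self.start}+{self.length} "
                f"yields {sliced!r}, annotation says {self.surface!r}"
            )


@dataclass(frozen=True)
class GoldPair:
    """Document-level interacting pair of distinct gene ids (unordered)."""

    doc_id: str
    pair: tuple[str, str]

    def __post_init__(self) -> None:
        a, b = self.pair
        if a == b:
            raise ValidationError(
                f"doc {self.doc_id}: pair has identical gene ids {a!r}"
            )
        object.__setattr__(self, "pair", canonical_pair(a, b))


@dataclass(frozen=True)
class TripleRecord:
    """A knowledge-base triple (head entity, relation label, tail entity)."""

    head_id: str
    relation_label: str
    tail_id: str

    def __post_init__(self) -> None:
        if not (self.head_id and self.relation_label and self.tail_id):
            raise ValidationError(f"triple with empty field: {self}")


@dataclass(frozen=True)
class PredictionRecord:
    """A predicted interacting pair with provenance and score."""

    doc_id: str
    pair: tuple[str, str]
    score: float = 1.0
    source: str = "model"  # model | rule | both

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair", canonical_pair(*self.pair))


# ---------------------------------------------------------------------------
# PubTator-style documents
# ---------------------------------------------------------------------------

def read_pubtator(path: str | Path) -> tuple[list[Document], list[Mention]]:
    """Parse a PubTator-style file into documents and validated mentions."""
    docs: list[Document] = []
    mentions: list[Mention] = []
    seen_ids: set[str] = set()
    cur: dict[str, str] | None = None
    cur_anns: list[tuple[int, Mention]] = []

    def flush() -> None:
        nonlocal cur, cur_anns
        if cur is None:
            return
        doc = Document(cur["id"], cur.get("t", ""), cur.get("a", ""))
        if doc.doc_id in seen_ids:
            raise ValidationError(f"duplicate doc_id {doc.doc_id!r}")
        seen_ids.add(doc.doc_id)
        docs.append(doc)
        for lineno, m in cur_anns:
            if m.doc_id != doc.doc_id:
                raise ParseError(
                    f"line {lineno}: annotation doc id {m.doc_id!r} does not "
                    f"match current document {doc.doc_id!r}"
                )
            m.validate_against(doc)
            mentions.append(m)
        cur, cur_anns = None, []

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if "|" in line and "\t" not in line:
                parts = line.split("|", 2)
                if len(parts) != 3 or parts[1] not in ("t", "a"):
                    raise ParseError(f"line {lineno}: malformed title/abstract line")
                doc_id, kind, text = parts
                if cur is not None and cur["id"] != doc_id:
                    flush()
                if cur is None:
                    cur = {"id": doc_id}
                if kind in cur:
                    raise ParseError(f"line {lineno}: duplicate |{kind}| line")
                cur[kind] = text
            elif "\t" in line:
                cols = line.split("\t")
                if len(cols) != 6:
                    raise ParseError(
                        f"line {lineno}: annotation needs 6 tab-separated "
                        f"columns, got {len(cols)}"
                    )
                doc_id, s, e, surface, mtype, gene_id = cols
                try:
                    start, end = int(s), int(e)
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: non-integer offset") from exc
                if end <= start:
                    raise ParseError(f"line {lineno}: end {end} <= start {start}")
                cur_anns.append(
                    (
                        lineno,
                        Mention(doc_id, start, end - start, surface, gene_id, mtype),
                    )
                )
                if cur is None:
                    raise ParseError(
                        f"line {lineno}: annotation precedes its document"
                    )
            else:
                raise ParseError(f"line {lineno}: unrecognized line {line!r}")
    flush()
    return docs, mentions


def write_pubtator(
    path: str | Path, docs: Sequence[Document], mentions: Sequence[Mention]
) -> None:
    by_doc: dict[str, list[Mention]] = {}
    for m in mentions:
        by_doc.setdefault(m.doc_id, []).append(m)
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(f"{doc.doc_id}|t|{doc.title}\n")
            fh.write(f"{doc.doc_id}|a|{doc.abstract}\n")
            for m in by_doc.get(doc.doc_id, []):
                fh.write(
                    f"{m.doc_id}\t{m.start}\t{m.end}\t{m.surface}"
                    f"\t{m.type}\t{m.gene_id}\n"
                )
            fh.write("\n")


# ---------------------------------------------------------------------------
# Pair / triple TSV
# ---------------------------------------------------------------------------

def read_pairs_tsv(path: str | Path) -> list[GoldPair]:
    """Read (doc_id, gene_a, gene_b) rows; unordered, duplicates collapsed."""
    pairs: list[GoldPair] = []
    seen: set[tuple[str, tuple[str, str]]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"line {lineno}: expected 3 columns, got {len(cols)}")
            gp = GoldPair(cols[0], (cols[1], cols[2]))
            key = (gp.doc_id, gp.pair)
            if key not in seen:
                seen.add(key)
                pairs.append(gp)
    return pairs


def write_pairs_tsv(path: str | Path, pairs: Iterable[GoldPair]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gp in pairs:
            fh.write(f"{gp.doc_id}\t{gp.pair[0]}\t{gp.pair[1]}\n")


def read_triples_tsv(path: str | Path) -> list[TripleRecord]:
    """Read head/relation/tail rows; exact duplicates removed, order kept."""
    triples: list[TripleRecord] = []
    seen: set[TripleRecord] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise ParseError(f"line {lineno}: expected 3 columns, got {len(cols)}")
            tr = TripleRecord(*cols)
            if tr not in seen:
                seen.add(tr)
                triples.append(tr)
    return triples


def write_triples_tsv(path: str | Path, triples: Iterable[TripleRecord]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tr in triples:
            fh.write(f"{tr.head_id}\t{tr.relation_label}\t{tr.tail_id}\n")


# ---------------------------------------------------------------------------
# word2vec text vectors
# ---------------------------------------------------------------------------

def read_word_vectors(path: str | Path, dim: int) -> dict[str, np.ndarray]:
    """Read word2vec text-format vectors, all of dimension ``dim``.

    A leading ``<count> <dim>`` header line is tolerated and skipped.
    """
    vecs: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        lines = []
        if first:
            parts = first.split()
            if len(parts) == 2 and all(p.isdigit() for p in parts):
                pass  # header line, skip
            else:
                lines.append((1, first))
        lines.extend((i, ln) for i, ln in enumerate(fh, start=2))
        for lineno, raw in lines:
            parts = raw.split()
            if not parts:
                continue
            if len(parts) != dim + 1:
                raise FormatError(
                    f"line {lineno}: expected word + {dim} floats, "
                    f"got {len(parts) - 1} values"
                )
            try:
                vec = np.array([float(x) for x in parts[1:]], dtype=np.float64)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-numeric vector entry") from exc
            vecs[parts[0]] = vec
    return vecs


def write_word_vectors(
    path: str | Path, vecs: Mapping[str, np.ndarray], header: bool = True
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        items = list(vecs.items())
        if header and items:
            dim = len(items[0][1])
            fh.write(f"{len(items)} {dim}\n")
        for word, vec in items:
            fh.write(word + " " + " ".join(f"{x:.6f}" for x in vec) + "\n")


# ---------------------------------------------------------------------------
# predictions and attention dumps
# ---------------------------------------------------------------------------

def read_predictions_tsv(path: str | Path) -> list[PredictionRecord]:
    recs: list[PredictionRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise ParseError(f"line {lineno}: expected 5 columns, got {len(cols)}")
            doc_id, a, b, score, source = cols
            if source not in ("model", "rule", "both"):
                raise ParseError(f"line {lineno}: unknown source {source!r}")
            recs.append(PredictionRecord(doc_id, (a, b), float(score), source))
    return recs


def write_predictions_tsv(
    path: str | Path, records: Iterable[PredictionRecord]
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(
                f"{r.doc_id}\t{r.pair[0]}\t{r.pair[1]}\t{r.score:.6f}\t{r.source}\n"
            )


def write_attention_tsv(
    path: str | Path,
    rows: Iterable[tuple[str, int, int, int, str, float]],
) -> None:
    """Write (doc_id, instance index, layer, network, token, weight) rows."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_id\tinstance\tlayer\tnetwork\ttoken\tweight\n")
        for doc_id, inst, layer, network, token, weight in rows:
            fh.write(f"{doc_id}\t{inst}\t{layer}\t{network}\t{token}\t{weight:.6f}\n")
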