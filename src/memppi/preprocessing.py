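"""Candidate-instance generation from annotated abstracts.

Document-level interacting-pair annotations are projected down to every
co-occurring mention pair of the two interactors (distant labeling).  A
mention pair survives as a candidate instance only if

* the sentence distance between the two mentions is < 3, and
* the token distance is more than 3 and < 50 (both bounds strict).

The instance context is the token span between the pair plus three expansion
tokens on each side, with the two pair mentions removed, every other protein
mention replaced by ``gene0``, numeric tokens replaced by ``NUMBER``, special
characters (e.g. ``*``) dropped, and everything lowercased.  Each context
token carries its token-count distance to either mention slot (minimum 1),
which the classifier's position-impact weighting consumes.

Sentence segmentation and tokenization are deterministic and rule-based: a
sentence break is ``[.?!]`` + whitespace + an uppercase letter or digit;
tokens are whitespace-delimited chunks with leading/trailing punctuation
split off.  Multi-token mention surfaces are collapsed to a single token.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .io_formats import Document, GoldPair, Mention, canonical_pair

logger = logging.getLogger("memppi")

__all__ = [
    "Token",
    "Sentence",
    "TokenizedDocument",
    "CandidateInstance",
    "segment_and_tokenize",
    "enumerate_mention_pairs",
    "apply_distance_rules",
    "build_context",
    "generate_instances",
    "write_instances",
    "read_instances",
    "MAX_SENTENCE_DISTANCE",
    "MIN_TOKEN_DISTANCE",
    "MAX_TOKEN_DISTANCE",
    "FLANK",
]

MAX_SENTENCE_DISTANCE = 3   # keep iff |sent_i - sent_j| < 3
MIN_TOKEN_DISTANCE = 3      # keep iff token distance > 3 ...
MAX_TOKEN_DISTANCE = 50     # ... and < 50
FLANK = 3                   # expansion words on both sides of the pair

NUMBER_RE = re.compile(r"^[0-9][0-9.,%]*$")
SPECIAL_CHARS = set("*•†‡§")
_WORDISH_RE = re.compile(
    r"[A-Za-z0-9][A-Za-z0-9.,%\-_/'+]*[A-Za-z0-9]|[A-Za-z0-9]|[^\sA-Za-z0-9]"
)
_BOUNDARY_RE = re.compile(r"[.?!]+(\s+)")


@dataclass(frozen=True)
class Token:
    text: str
    start: int            # character offset into Document.text
    sent: int             # 0-based sentence index
    mention_idx: Optional[int] = None   # index into the document's mentions


@dataclass(frozen=True)
class Sentence:
    index: int
    tokens: tuple[Token, ...]


@dataclass
class TokenizedDocument:
    doc_id: str
    sentences: list[Sentence]
    tokens: list[Token]                  # flat stream, document order
    mentions: list[Mention]
    mention_positions: list[int]         # flat token index per mention

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class CandidateInstance:
    """One mention-pair occurrence with its masked context window."""

    doc_id: str
    gene1: str                   # gene id of the earlier mention (at p1)
    gene2: str                   # gene id of the later mention (at p2)
    surface1: str
    surface2: str
    p1: int                      # flat token index, p1 < p2
    p2: int
    context: tuple[str, ...]
    dist1: tuple[int, ...]       # token distance of each context token to p1
    dist2: tuple[int, ...]
    label: Optional[int] = None

    @property
    def pair(self) -> tuple[str, str]:
        return canonical_pair(self.gene1, self.gene2)


def _sentence_spans(text: str, protected: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Split ``text`` into sentence (start, end) spans.

    A break sits after [.?!]+ followed by whitespace when the next character
    is an uppercase letter or a digit; breaks inside protected (mention)
    spans are suppressed.
    """
    breaks = []
    for m in _BOUNDARY_RE.finditer(text):
        nxt = m.end()
        if nxt >= len(text):
            continue
        if not (text[nxt].isupper() or text[nxt].isdigit()):
            continue
        if any(s <= m.start() < e for s, e in protected):
            continue
        breaks.append(nxt)
    spans = []
    prev = 0
    for b in breaks:
        spans.append((prev, b))
        prev = b
    spans.append((prev, len(text)))
    return [(s, e) for s, e in spans if text[s:e].strip()]


def segment_and_tokenize(
    doc: Document, mentions: Sequence[Mention] = ()
) -> TokenizedDocument:
    """Segment a document into sentences and tokens.

    Mention character spans are kept atomic: each mention becomes exactly one
    token regardless of its surface.  Overlapping mentions are resolved by
    keeping the earlier-starting (then longer) one; a mention straddling a
    sentence boundary is assigned the sentence containing its start offset.
    """
    text = doc.text
    ments = [m for m in mentions if m.doc_id == doc.doc_id]
    for m in ments:
        m.validate_against(doc)
    # resolve overlaps deterministically
    kept: list[tuple[Mention, int]] = []
    last_end = -1
    order = sorted(range(len(ments)), key=lambda i: (ments[i].start, -ments[i].length))
    for i in order:
        m = ments[i]
        if m.start < last_end:
            logger.warning(
                "doc %s: dropping mention %r at %d overlapping a previous one",
                doc.doc_id, m.surface, m.start,
            )
            continue
        kept.append((m, i))
        last_end = m.end
    protected = [(m.start, m.end) for m, _ in kept]
    spans = _sentence_spans(text, protected)

    sent_of_char = [len(spans) - 1] * (len(text) + 1)
    for si, (s, e) in enumerate(spans):
        for c in range(s, e):
            sent_of_char[c] = si

    tokens: list[Token] = []
    mention_pos: dict[int, int] = {}
    cursor = 0
    prot_iter = list(kept) + [(None, None)]
    for m, orig_idx in prot_iter:
        gap_end = m.start if m is not None else len(text)
        gap = text[cursor:gap_end]
        for tm in _WORDISH_RE.finditer(gap):
            start = cursor + tm.start()
            tokens.append(Token(tm.group(), start, sent_of_char[start]))
        if m is not None:
            si = sent_of_char[m.start]
            if sent_of_char[max(m.end - 1, m.start)] != si:
                logger.warning(
                    "doc %s: mention %r straddles a sentence boundary; "
                    "assigned to sentence %d", doc.doc_id, m.surface, si,
                )
            mention_pos[orig_idx] = len(tokens)
            tokens.append(Token(m.surface, m.start, si, mention_idx=orig_idx))
            cursor = m.end
    sentences = []
    for si in range(len(spans)):
        stoks = tuple(t for t in tokens if t.sent == si)
        sentences.append(Sentence(si, stoks))
    positions = [mention_pos[i] for i in range(len(ments)) if i in mention_pos]
    kept_mentions = [ments[i] for i in range(len(ments)) if i in mention_pos]
    return TokenizedDocument(doc.doc_id, sentences, tokens, kept_mentions, positions)


def enumerate_mention_pairs(
    tdoc: TokenizedDocument,
    gold: Optional[Iterable[GoldPair]] = None,
    labeled: bool = True,
) -> list[tuple[int, int, Optional[int]]]:
    """All unordered mention pairs with distinct gene ids.

    Returns (mention index i, mention index j, label) with the earlier token
    position first.  In labeled mode the label is 1 iff the gene-id pair is
    in this document's gold set (distant labeling), else 0; in prediction
    mode labels are None.
    """
    gold_pairs: set[tuple[str, str]] = set()
    if gold is not None:
        gold_pairs = {g.pair for g in gold if g.doc_id == tdoc.doc_id}
    out: list[tuple[int, int, Optional[int]]] = []
    n = len(tdoc.mentions)
    idx = sorted(range(n), key=lambda i: tdoc.mention_positions[i])
    for a in range(n):
        for b in range(a + 1, n):
            i, j = idx[a], idx[b]
            mi, mj = tdoc.mentions[i], tdoc.mentions[j]
            if mi.gene_id == mj.gene_id:
                continue
            label: Optional[int] = None
            if labeled:
                label = int(canonical_pair(mi.gene_id, mj.gene_id) in gold_pairs)
            out.append((i, j, label))
    return out


def apply_distance_rules(
    sent_i: int, sent_j: int, p1: int, p2: int
) -> bool:
    """Keep a mention pair iff |Δsentence| < 3 and 3 < Δtoken < 50."""
    if abs(sent_i - sent_j) >= MAX_SENTENCE_DISTANCE:
        return False
    dist = p2 - p1
    return MIN_TOKEN_DISTANCE < dist < MAX_TOKEN_DISTANCE


def _mask_token(tok: Token) -> Optional[str]:
    if tok.mention_idx is not None:
        return "gene0"
    text = tok.text
    if NUMBER_RE.match(text):
        return "NUMBER"
    text = "".join(ch for ch in text if ch not in SPECIAL_CHARS)
    if not text:
        return None
    return text.lower()


def build_context(
    tdoc: TokenizedDocument,
    mention_i: int,
    mention_j: int,
    label: Optional[int] = None,
) -> Optional[CandidateInstance]:
    """Masked context window for one mention pair.

    Window = up to three tokens left of the first mention, everything
    between the pair, up to three tokens right of the second mention; the
    two pair mentions themselves are removed.  Distances are token counts
    to the removed mention slots, measured before removal, with minimum 1.
    Returns None when masking leaves an empty context (never happens for
    rule-passing pairs unless every window token is a removed special
    character).
    """
    pi = tdoc.mention_positions[mention_i]
    pj = tdoc.mention_positions[mention_j]
    if pi > pj:
        pi, pj = pj, pi
        mention_i, mention_j = mention_j, mention_i
    mi, mj = tdoc.mentions[mention_i], tdoc.mentions[mention_j]
    toks = tdoc.tokens
    window = (
        list(range(max(0, pi - FLANK), pi))
        + list(range(pi + 1, pj))
        + list(range(pj + 1, min(len(toks), pj + 1 + FLANK)))
    )
    context: list[str] = []
    dist1: list[int] = []
    dist2: list[int] = []
    for t in window:
        masked = _mask_token(toks[t])
        if masked is None:
            continue
        context.append(masked)
        dist1.append(max(1, abs(t - pi)))
        dist2.append(max(1, abs(t - pj)))
    if not context:
        logger.warning(
            "doc %s: empty context for pair (%s, %s); instance skipped",
            tdoc.doc_id, mi.gene_id, mj.gene_id,
        )
        return None
    return CandidateInstance(
        doc_id=tdoc.doc_id,
        gene1=mi.gene_id,
        gene2=mj.gene_id,
        surface1=mi.surface,
        surface2=mj.surface,
        p1=pi,
        p2=pj,
        context=tuple(context),
        dist1=tuple(dist1),
        dist2=tuple(dist2),
        label=label,
    )


def generate_instances(
    docs: Sequence[Document],
    mentions: Sequence[Mention],
    gold: Optional[Sequence[GoldPair]] = None,
    labeled: bool = True,
) -> list[CandidateInstance]:
    """Full candidate-generation pipeline over a corpus.

    Deterministic: document order, then (p1, p2) order within a document.
    """
    by_doc: dict[str, list[Mention]] = {}
    for m in mentions:
        by_doc.setdefault(m.doc_id, []).append(m)
    instances: list[CandidateInstance] = []
    for doc in docs:
        tdoc = segment_and_tokenize(doc, by_doc.get(doc.doc_id, []))
        for i, j, label in enumerate_mention_pairs(tdoc, gold, labeled=labeled):
            pi, pj = tdoc.mention_positions[i], tdoc.mention_positions[j]
            si = tdoc.tokens[pi].sent
            sj = tdoc.tokens[pj].sent
            if not apply_distance_rules(si, sj, min(pi, pj), max(pi, pj)):
                continue
            inst = build_context(tdoc, i, j, label)
            if inst is not None:
                instances.append(inst)
    return instances


# ---------------------------------------------------------------------------
# instance serialization (JSON lines)
# ---------------------------------------------------------------------------

def write_instances(path: str | Path, instances: Iterable[CandidateInstance]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for inst in instances:
            rec = {
                "doc_id": inst.doc_id,
                "gene1": inst.gene1,
                "gene2": inst.gene2,
                "surface1": inst.surface1,
                "surface2": inst.surface2,
                "p1": inst.p1,
                "p2": inst.p2,
                "context": list(inst.context),
                "dist1": list(inst.dist1),
                "dist2": list(inst.dist2),
                "label": inst.label,
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_instances(path: str | Path) -> list[CandidateInstance]:
    out: list[CandidateInstance] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            out.append(
                CandidateInstance(
                    doc_id=rec["doc_id"],
                    gene1=rec["gene1"],
                    gene2=rec["gene2"],
                    surface1=rec["surface1"],
                    surface2=rec["surface2"],
                    p1=rec["p1"],
                    p2=rec["p2"],
                    context=tuple(rec["context"]),
                    dist1=tuple(rec["dist1"]),
                    dist2=tuple(rec["dist2"]),
                    label=rec["label"],
                )
            )
    return out
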