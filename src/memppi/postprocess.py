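"""Sentence-support rule, merging, and micro-averaged evaluation.

The sentence-support rule declares a gene pair interacting when more than N
sentences of a document mention both genes (N defaults to 2, i.e. at least
three supporting sentences — the inequality is strict).  Rule hits are
merged with the classifier's document-level positives by set union on
(doc, unordered pair), keeping provenance.

Evaluation is micro-averaged Exact Match on Entrez Gene ID pairs:
TP/FP/FN are pooled over all documents, weighting every pair equally, then
P = TP/(TP+FP), R = TP/(TP+FN), F = 2PR/(P+R), each 0 when its
denominator is 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .io_formats import Document, GoldPair, Mention, PredictionRecord, canonical_pair
from .preprocessing import segment_and_tokenize

logger = logging.getLogger("memppi")

__all__ = [
    "PostprocessConfig",
    "EvalResult",
    "sentence_support_pairs",
    "merge",
    "evaluate_micro",
]


@dataclass
class PostprocessConfig:
    support_threshold: int = 2   # emit iff co-mention sentence count > N

    def __post_init__(self) -> None:
        if self.support_threshold < 0:
            raise ValueError("support threshold must be >= 0")


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


def sentence_support_pairs(
    doc: Document,
    mentions: Sequence[Mention],
    cfg: PostprocessConfig = PostprocessConfig(),
) -> list[PredictionRecord]:
    """Pairs co-mentioned in more than N sentences of one document.

    A sentence supports a pair when it contains at least one mention of
    both genes.
    """
    tdoc = segment_and_tokenize(doc, mentions)
    genes_by_sentence: dict[int, set[str]] = {}
    for m, pos in zip(tdoc.mentions, tdoc.mention_positions):
        genes_by_sentence.setdefault(tdoc.tokens[pos].sent, set()).add(m.gene_id)
    support: dict[tuple[str, str], int] = {}
    for genes in genes_by_sentence.values():
        for a, b in combinations(sorted(genes), 2):
            support[(a, b)] = support.get((a, b), 0) + 1
    return [
        PredictionRecord(doc_id=doc.doc_id, pair=pair, score=1.0, source="rule")
        for pair, count in sorted(support.items())
        if count > cfg.support_threshold
    ]


def merge(
    model_set: Iterable[PredictionRecord], rule_set: Iterable[PredictionRecord]
) -> list[PredictionRecord]:
    """Set union on (doc, pair); provenance kept as model/rule/both."""
    out: dict[tuple[str, tuple[str, str]], PredictionRecord] = {}
    for rec in model_set:
        out[(rec.doc_id, rec.pair)] = PredictionRecord(
            rec.doc_id, rec.pair, rec.score, "model"
        )
    for rec in rule_set:
        key = (rec.doc_id, rec.pair)
        if key in out:
            prev = out[key]
            out[key] = PredictionRecord(
                prev.doc_id, prev.pair, max(prev.score, rec.score), "both"
            )
        else:
            out[key] = PredictionRecord(rec.doc_id, rec.pair, rec.score, "rule")
    return list(out.values())


def evaluate_micro(
    predictions: Iterable[PredictionRecord], gold: Iterable[GoldPair]
) -> EvalResult:
    """Micro-averaged P/R/F over pooled per-document pair decisions."""
    pred_keys: set[tuple[str, tuple[str, str]]] = set()
    n_dupes = 0
    for rec in predictions:
        key = (rec.doc_id, canonical_pair(*rec.pair))
        if key in pred_keys:
            n_dupes += 1
        pred_keys.add(key)
    if n_dupes:
        logger.warning("deduplicated %d duplicate predicted pairs", n_dupes)
    gold_keys = {(g.doc_id, g.pair) for g in gold}
    tp = len(pred_keys & gold_keys)
    fp = len(pred_keys - gold_keys)
    fn = len(gold_keys - pred_keys)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvalResult(tp, fp, fn, precision, recall, f1)
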