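"""TransE knowledge-representation learning over PPI triples.

TransE embeds a triple (h, r, t) so that h + r ≈ t, trained with the margin
ranking loss

    L = Σ max(0, γ + ||h + r − t|| − ||h' + r − t'||)

over corrupted triples (h', r, t') obtained by replacing the head or tail
with a uniformly drawn entity (filtered so the corruption is not itself a
known triple).  Entity vectors are initialized as the average of the word
vectors of the entity's mention words and re-normalized to unit L2 after
every update; relation vectors are drawn from a normal distribution and
left unconstrained.

The trained store also indexes relations by unordered entity pair: the
relation embedding of a protein pair is the mean of the vectors of all
relations linking the pair in the KB, or the zero vector for pairs absent
from the KB.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .io_formats import (
    TripleRecord,
    canonical_pair,
    read_word_vectors,
    write_word_vectors,
)

logger = logging.getLogger("memppi")

__all__ = [
    "TransEConfig",
    "KnowledgeStore",
    "WordVectorLookup",
    "init_entity_vector",
    "corrupt",
    "margin_loss",
    "batch_margin_loss_grads",
    "train_transe",
    "pair_relation_vector",
    "mean_rank_tails",
]


@dataclass
class TransEConfig:
    dim: int = 100
    margin: float = 1.0
    learning_rate: float = 0.01
    epochs: int = 500
    batch_size: int = 512
    seed: int = 0
    norm: str = "L2"            # L1 | L2

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        if self.norm not in ("L1", "L2"):
            raise ValueError(f"unknown norm {self.norm!r}")


class WordVectorLookup:
    """Word→vector lookup with a cached random draw for unseen words.

    A word absent from the underlying table is assigned a N(0, 0.01) draw
    seeded by (lookup seed, crc32 of the word), cached on first use.  The
    draw is therefore a pure function of the word and the seed, independent
    of query order, so training- and prediction-time lookups agree.
    """

    def __init__(self, vectors: Mapping[str, np.ndarray], dim: int, seed: int = 0):
        self.vectors = dict(vectors)
        self.dim = dim
        self.seed = seed
        self._cache: dict[str, np.ndarray] = {}
        for v in self.vectors.values():
            if len(v) != dim:
                raise ValueError("word vector dimension mismatch")

    def __call__(self, word: str) -> np.ndarray:
        if word in self.vectors:
            return np.asarray(self.vectors[word], dtype=np.float64)
        if word not in self._cache:
            rng = np.random.default_rng(
                [self.seed & 0x7FFFFFFF, zlib.crc32(word.encode("utf-8"))]
            )
            self._cache[word] = rng.normal(0.0, 0.01, self.dim)
        return self._cache[word]


def init_entity_vector(
    entity_id: str,
    mention_words: Sequence[str],
    word_vecs: WordVectorLookup,
) -> np.ndarray:
    """Averaged word embeddings of an entity's mention words.

    An entity with no usable words falls back to a cached random draw keyed
    by the entity id itself.
    """
    words = [w for w in mention_words if w]
    if not words:
        return word_vecs(f"<entity:{entity_id}>")
    return np.mean([word_vecs(w) for w in words], axis=0)


def corrupt(
    triple: TripleRecord,
    entity_ids: Sequence[str],
    triple_set: frozenset | set,
    rng: np.random.Generator,
    max_tries: int = 100,
) -> TripleRecord:
    """Corrupt head or tail (probability 0.5 each) with a uniform entity.

    Resamples while the corruption is itself a known triple (filtered
    sampling), giving up after ``max_tries`` draws and accepting the last.
    """
    if len(entity_ids) < 2:
        raise ValueError("need at least 2 entities to corrupt")
    cand = triple
    for _ in range(max_tries):
        replace_head = rng.random() < 0.5
        e = entity_ids[int(rng.integers(len(entity_ids)))]
        if replace_head:
            cand = TripleRecord(e, triple.relation_label, triple.tail_id)
        else:
            cand = TripleRecord(triple.head_id, triple.relation_label, e)
        if cand != triple and cand not in triple_set:
            return cand
    return cand


def _distances(
    heads: np.ndarray, rels: np.ndarray, tails: np.ndarray, norm: str
) -> np.ndarray:
    diff = heads + rels - tails
    if norm == "L1":
        return np.abs(diff).sum(axis=-1)
    return np.linalg.norm(diff, axis=-1)


def margin_loss(
    pos_batch: Sequence[TripleRecord],
    neg_batch: Sequence[TripleRecord],
    store: "KnowledgeStore",
    margin: float,
    norm: str = "L2",
) -> float:
    """Σ max(0, γ + d(h+r, t) − d(h'+r, t')) over an aligned batch."""
    if len(pos_batch) != len(neg_batch):
        raise ValueError("pos/neg batches must be aligned")
    total = 0.0
    for pos, neg in zip(pos_batch, neg_batch):
        h = store.entity_vec[pos.head_id]
        r = store.relation_vec[pos.relation_label]
        t = store.entity_vec[pos.tail_id]
        hn = store.entity_vec[neg.head_id]
        tn = store.entity_vec[neg.tail_id]
        d_pos = _distances(h, r, t, norm)
        d_neg = _distances(hn, r, tn, norm)
        total += max(0.0, margin + float(d_pos) - float(d_neg))
    return total


def batch_margin_loss_grads(
    E: np.ndarray,
    R: np.ndarray,
    h: np.ndarray,
    r: np.ndarray,
    t: np.ndarray,
    hc: np.ndarray,
    tc: np.ndarray,
    margin: float,
    norm: str = "L2",
) -> tuple[float, np.ndarray, np.ndarray]:
    """Margin ranking loss and its analytic gradients for one batch.

    ``E``/``R`` are the entity/relation embedding matrices; the remaining
    arguments are aligned index arrays of positive triples (h, r, t) and
    their corruptions (hc, r, tc).  Returns (loss, dL/dE, dL/dR).
    """
    diff_pos = E[h] + R[r] - E[t]
    diff_neg = E[hc] + R[r] - E[tc]
    if norm == "L1":
        d_pos = np.abs(diff_pos).sum(axis=1)
        d_neg = np.abs(diff_neg).sum(axis=1)
        g_pos = np.sign(diff_pos)
        g_neg = np.sign(diff_neg)
    else:
        d_pos = np.linalg.norm(diff_pos, axis=1)
        d_neg = np.linalg.norm(diff_neg, axis=1)
        g_pos = diff_pos / np.maximum(d_pos, 1e-12)[:, None]
        g_neg = diff_neg / np.maximum(d_neg, 1e-12)[:, None]
    terms = margin + d_pos - d_neg
    loss = float(np.maximum(terms, 0.0).sum())
    w = (terms > 0).astype(np.float64)[:, None]
    gp = g_pos * w
    gn = g_neg * w
    dE = np.zeros_like(E)
    dR = np.zeros_like(R)
    np.add.at(dE, h, gp)
    np.add.at(dE, t, -gp)
    np.add.at(dE, hc, -gn)
    np.add.at(dE, tc, gn)
    np.add.at(dR, r, gp - gn)
    return loss, dE, dR


@dataclass
class KnowledgeStore:
    """Entity and relation vectors plus an unordered pair → relations index."""

    dim: int
    entity_vec: dict[str, np.ndarray] = field(default_factory=dict)
    relation_vec: dict[str, np.ndarray] = field(default_factory=dict)
    pair_index: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    loss_trace: list[float] = field(default_factory=list)

    @classmethod
    def from_triples(
        cls,
        triples: Sequence[TripleRecord],
        dim: int,
        entity_vec: Mapping[str, np.ndarray],
        relation_vec: Mapping[str, np.ndarray],
    ) -> "KnowledgeStore":
        store = cls(dim, dict(entity_vec), dict(relation_vec))
        for tr in triples:
            key = canonical_pair(tr.head_id, tr.tail_id)
            rels = store.pair_index.setdefault(key, [])
            if tr.relation_label not in rels:
                rels.append(tr.relation_label)
        return store

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_word_vectors(outdir / "entities.tsv", self.entity_vec, header=False)
        write_word_vectors(outdir / "relations.tsv", self.relation_vec, header=False)
        with open(outdir / "pair_index.tsv", "w", encoding="utf-8") as fh:
            for (a, b), rels in sorted(self.pair_index.items()):
                fh.write(f"{a}\t{b}\t" + ",".join(rels) + "\n")
        with open(outdir / "dim.txt", "w", encoding="utf-8") as fh:
            fh.write(f"{self.dim}\n")

    @classmethod
    def load(cls, indir: str | Path) -> "KnowledgeStore":
        indir = Path(indir)
        with open(indir / "dim.txt", encoding="utf-8") as fh:
            dim = int(fh.read().strip())
        store = cls(dim)
        store.entity_vec = read_word_vectors(indir / "entities.tsv", dim)
        store.relation_vec = read_word_vectors(indir / "relations.tsv", dim)
        with open(indir / "pair_index.tsv", encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                a, b, rels = line.rstrip("\n").split("\t")
                store.pair_index[(a, b)] = rels.split(",")
        return store


def pair_relation_vector(
    store: KnowledgeStore, gene_a: str, gene_b: str
) -> np.ndarray:
    """Mean relation vector of an unordered pair; zeros for absent pairs."""
    rels = store.pair_index.get(canonical_pair(gene_a, gene_b))
    if not rels:
        return np.zeros(store.dim)
    return np.mean([store.relation_vec[r] for r in rels], axis=0)


def train_transe(
    triples: Sequence[TripleRecord],
    cfg: TransEConfig,
    word_vecs: Optional[Mapping[str, np.ndarray]] = None,
    entity_words: Optional[Mapping[str, Sequence[str]]] = None,
) -> KnowledgeStore:
    """Minibatch SGD on the TransE margin ranking loss.

    ``entity_words`` maps an entity id to its mention words for averaged-word
    initialization (default: the lowercased entity id as a single word).
    Entity vectors are renormalized to unit L2 after every minibatch update;
    deterministic given ``cfg.seed``.  The per-epoch loss trace is stored on
    the returned KnowledgeStore.
    """
    if not triples:
        raise ValueError("empty triple set")
    rng = np.random.default_rng(cfg.seed)
    lookup = WordVectorLookup(word_vecs or {}, cfg.dim, seed=cfg.seed + 1)

    entities = sorted({t.head_id for t in triples} | {t.tail_id for t in triples})
    relations = sorted({t.relation_label for t in triples})
    e_index = {e: i for i, e in enumerate(entities)}
    r_index = {r: i for i, r in enumerate(relations)}

    E = np.empty((len(entities), cfg.dim))
    for e, i in e_index.items():
        words = (entity_words or {}).get(e, [e.lower()])
        E[i] = init_entity_vector(e, words, lookup)
    norms = np.linalg.norm(E, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    E /= norms
    R = rng.normal(0.0, 0.1, (len(relations), cfg.dim))

    triple_set = set(triples)
    tri_idx = np.array(
        [(e_index[t.head_id], r_index[t.relation_label], e_index[t.tail_id])
         for t in triples],
        dtype=np.int64,
    )
    lr = cfg.learning_rate
    trace: list[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(triples))
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            h, r, t = tri_idx[batch, 0], tri_idx[batch, 1], tri_idx[batch, 2]
            hc = h.copy()
            tc = t.copy()
            for bi, oi in enumerate(batch):
                neg = corrupt(triples[oi], entities, triple_set, rng)
                hc[bi] = e_index[neg.head_id]
                tc[bi] = e_index[neg.tail_id]
            loss, dE, dR = batch_margin_loss_grads(
                E, R, h, r, t, hc, tc, cfg.margin, cfg.norm
            )
            epoch_loss += loss
            if loss > 0:
                E -= lr * dE
                R -= lr * dR
                norms = np.linalg.norm(E, axis=1, keepdims=True)
                norms[norms == 0] = 1.0
                E /= norms
        trace.append(epoch_loss)

    store = KnowledgeStore.from_triples(
        triples,
        cfg.dim,
        {e: E[i].copy() for e, i in e_index.items()},
        {r: R[i].copy() for r, i in r_index.items()},
    )
    store.loss_trace = trace
    return store


def mean_rank_tails(
    store: KnowledgeStore,
    triples: Sequence[TripleRecord],
    filtered: bool = True,
) -> float:
    """Mean rank of the true tail among all stored entities.

    For each triple, entities are scored by ||h + r − e|| (L2) and ranked;
    with ``filtered`` the other known true tails for (h, r) are removed
    from the candidate list before ranking (the true tail keeps competing).
    """
    entities = sorted(store.entity_vec)
    E = np.stack([store.entity_vec[e] for e in entities])
    e_index = {e: i for i, e in enumerate(entities)}
    known: dict[tuple[str, str], set[str]] = {}
    for t in triples:
        known.setdefault((t.head_id, t.relation_label), set()).add(t.tail_id)
    ranks = []
    for t in triples:
        h = store.entity_vec[t.head_id]
        r = store.relation_vec[t.relation_label]
        d = np.linalg.norm(h + r - E, axis=1)
        if filtered:
            for other in known[(t.head_id, t.relation_label)]:
                if other != t.tail_id:
                    d[e_index[other]] = np.inf
        ti = e_index[t.tail_id]
        rank = 1 + int(np.sum(d < d[ti]))
        ranks.append(rank)
    return float(np.mean(ranks))
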