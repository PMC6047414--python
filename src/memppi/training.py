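"""Training loop, instance-level prediction, and document aggregation.

Training minimizes the mean cross-entropy −(1/N) Σ log p(y_l | T_l) with
Adam (learning rate 0.001, batch size 100 by default) over shuffled
minibatches of candidate instances.  Word embeddings are trainable
(initialized from a word2vec-format table when given); entity and relation
embeddings from the knowledge store are frozen inputs unless
``finetune_kb_vectors`` is set on the model configuration.

At prediction time each instance gets p(PPIm | T) and an argmax label; a
document-level (doc, gene-id pair) is positive iff at least one of its
instances is positive, carrying the maximum instance probability as score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .io_formats import PredictionRecord, canonical_pair
from .knowledge import KnowledgeStore, WordVectorLookup, init_entity_vector, pair_relation_vector
from .model import (
    UNK,
    BatchTensors,
    InstanceTensors,
    ModelConfig,
    ModelParams,
    forward_batch,
    forward_instance,
    init_params,
    loss_and_grads,
    predict_label,
)
from .preprocessing import CandidateInstance

logger = logging.getLogger("memppi")

__all__ = [
    "TrainConfig",
    "tune_weight_decay",
    "InstancePrediction",
    "cross_entropy",
    "build_vocab",
    "train",
    "predict_instances",
    "aggregate_document",
    "collect_attention_rows",
    "crossval_folds",
]


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 100
    epochs: int = 60
    weight_decay: float = 0.01   # L2 penalty on weight matrices (not biases)
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid training configuration")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")


@dataclass(frozen=True)
class InstancePrediction:
    doc_id: str
    pair: tuple[str, str]
    probability: float          # p(PPIm)
    label: int


def cross_entropy(probabilities, labels) -> float:
    """Mean negative log-likelihood of the true labels.

    ``probabilities`` holds per-instance class distributions (rows of
    length 2); probabilities are clamped at 1e-12 before the log.
    """
    probs = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if len(probs) != len(y):
        raise ValueError("probabilities and labels differ in length")
    picked = np.clip(probs[np.arange(len(y)), y], 1e-12, None)
    return float(-np.mean(np.log(picked)))


def build_vocab(instances: Sequence[CandidateInstance], min_count: int = 1) -> dict[str, int]:
    counts: dict[str, int] = {}
    for inst in instances:
        for w in inst.context:
            counts[w] = counts.get(w, 0) + 1
    vocab = {UNK: 0}
    for w in sorted(counts):
        if counts[w] >= min_count:
            vocab[w] = len(vocab)
    return vocab


def _surface_words(surface: str) -> list[str]:
    return [w for w in surface.lower().split() if w]


def _resolve_entity(
    gene_id: str,
    surface: str,
    kstore: KnowledgeStore,
    lookup: WordVectorLookup,
    cfg: ModelConfig,
) -> np.ndarray:
    if cfg.entity_source == "transe" and gene_id in kstore.entity_vec:
        return np.asarray(kstore.entity_vec[gene_id], dtype=np.float64)
    # entities absent from the KB (or the averaged-words ablations) fall
    # back to the mean of the mention's word vectors
    return init_entity_vector(gene_id, _surface_words(surface), lookup)


@dataclass
class _Encoded:
    tok: list[np.ndarray]
    dist1: list[np.ndarray]
    dist2: list[np.ndarray]
    e1: np.ndarray
    e2: np.ndarray
    rel: np.ndarray
    y: Optional[np.ndarray]
    ent_table: np.ndarray
    rel_table: np.ndarray
    ent_index: dict[str, int]
    rel_index: dict[str, int]


def _encode(
    instances: Sequence[CandidateInstance],
    vocab: Mapping[str, int],
    kstore: KnowledgeStore,
    lookup: WordVectorLookup,
    cfg: ModelConfig,
    trained: Optional[ModelParams] = None,
    labeled: bool = True,
) -> _Encoded:
    """Token ids, distances, and resolved entity/relation tables.

    When ``trained`` carries fine-tuned KB rows, entities/pairs seen in
    training reuse the trained vectors; anything unseen is resolved from
    the knowledge store (with averaged-word fallback).
    """
    ent_index: dict[str, int] = {}
    rel_index: dict[str, int] = {}
    ent_rows: list[np.ndarray] = []
    rel_rows: list[np.ndarray] = []

    def ent_row(gene_id: str, surface: str) -> int:
        if gene_id not in ent_index:
            if (
                trained is not None
                and cfg.finetune_kb_vectors
                and gene_id in trained.ent_index
            ):
                vec = trained.params["ent"][trained.ent_index[gene_id]]
            else:
                vec = _resolve_entity(gene_id, surface, kstore, lookup, cfg)
            ent_index[gene_id] = len(ent_rows)
            ent_rows.append(np.asarray(vec, dtype=np.float64))
        return ent_index[gene_id]

    def rel_row(gene_a: str, gene_b: str) -> int:
        key = "|".join(canonical_pair(gene_a, gene_b))
        if key not in rel_index:
            if (
                trained is not None
                and cfg.finetune_kb_vectors
                and key in trained.rel_index
            ):
                vec = trained.params["rel"][trained.rel_index[key]]
            elif cfg.use_relation_embedding:
                vec = pair_relation_vector(kstore, gene_a, gene_b)
            else:
                vec = np.zeros(cfg.dim)
            rel_index[key] = len(rel_rows)
            rel_rows.append(np.asarray(vec, dtype=np.float64))
        return rel_index[key]

    tok, d1, d2, e1, e2, rel, ys = [], [], [], [], [], [], []
    for inst in instances:
        tok.append(np.array([vocab.get(w, 0) for w in inst.context], dtype=np.int64))
        d1.append(np.asarray(inst.dist1, dtype=np.float64))
        d2.append(np.asarray(inst.dist2, dtype=np.float64))
        e1.append(ent_row(inst.gene1, inst.surface1))
        e2.append(ent_row(inst.gene2, inst.surface2))
        rel.append(rel_row(inst.gene1, inst.gene2))
        if labeled:
            if inst.label is None:
                raise ValueError("labeled encoding requires instance labels")
            ys.append(inst.label)
    return _Encoded(
        tok=tok,
        dist1=d1,
        dist2=d2,
        e1=np.array(e1, dtype=np.int64),
        e2=np.array(e2, dtype=np.int64),
        rel=np.array(rel, dtype=np.int64),
        y=np.array(ys, dtype=np.int64) if labeled else None,
        ent_table=np.stack(ent_rows) if ent_rows else np.zeros((0, cfg.dim)),
        rel_table=np.stack(rel_rows) if rel_rows else np.zeros((0, cfg.dim)),
        ent_index=ent_index,
        rel_index=rel_index,
    )


def _make_batch(enc: _Encoded, idx: np.ndarray) -> BatchTensors:
    lens = np.array([len(enc.tok[i]) for i in idx], dtype=np.int64)
    N = int(lens.max())
    B = len(idx)
    tok = np.zeros((B, N), dtype=np.int64)
    mask = np.zeros((B, N))
    dist1 = np.ones((B, N))
    dist2 = np.ones((B, N))
    for bi, i in enumerate(idx):
        L = lens[bi]
        tok[bi, :L] = enc.tok[i]
        mask[bi, :L] = 1.0
        dist1[bi, :L] = enc.dist1[i]
        dist2[bi, :L] = enc.dist2[i]
    return BatchTensors(
        tok=tok,
        mask=mask,
        nlen=lens,
        dist1=dist1,
        dist2=dist2,
        e1=enc.e1[idx],
        e2=enc.e2[idx],
        rel=enc.rel[idx],
        y=enc.y[idx] if enc.y is not None else None,
    )


class _Adam:
    def __init__(self, keys: Iterable[str], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.keys = list(keys)

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k in self.keys:
            g = grads[k]
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    instances: Sequence[CandidateInstance],
    kstore: KnowledgeStore,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    word_vecs: Optional[Mapping[str, np.ndarray]] = None,
) -> ModelParams:
    """Fit the classifier on labeled candidate instances.

    Deterministic given the two seeds; the per-epoch mean-loss trace is
    stored on the returned ModelParams.
    """
    if not instances:
        raise ValueError("no training instances")
    labels = {inst.label for inst in instances}
    if None in labels:
        raise ValueError("training requires labeled instances")
    if len(labels) < 2:
        logger.warning("training set contains a single class %s", labels)

    vocab = build_vocab(instances)
    lookup = WordVectorLookup(word_vecs or {}, model_cfg.dim, seed=model_cfg.seed)
    enc = _encode(instances, vocab, kstore, lookup, model_cfg, labeled=True)

    rng = np.random.default_rng(model_cfg.seed)
    word_init = np.vstack(
        [np.zeros((1, model_cfg.dim))]
        + [lookup(w)[None, :] for w in sorted(vocab, key=vocab.get) if w != UNK]
    ) if len(vocab) > 1 else np.zeros((1, model_cfg.dim))
    mp = init_params(
        model_cfg,
        vocab,
        word_init=word_init,
        n_entities=len(enc.ent_index),
        n_relations=len(enc.rel_index),
        rng=rng,
    )
    mp.params["ent"] = enc.ent_table
    mp.params["rel"] = enc.rel_table
    mp.ent_index = enc.ent_index
    mp.rel_index = enc.rel_index

    opt = _Adam(mp.trainable_keys(), train_cfg.learning_rate)
    shuffle_rng = np.random.default_rng(train_cfg.seed)
    n = len(instances)
    for _epoch in range(train_cfg.epochs):
        order = shuffle_rng.permutation(n) if train_cfg.shuffle else np.arange(n)
        total, seen = 0.0, 0
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            batch = _make_batch(enc, idx)
            loss, grads, _ = loss_and_grads(mp, batch)
            if train_cfg.weight_decay:
                # decay the large memorization-prone tensors (embeddings,
                # transforms, classifier); the low-dimensional attention
                # scorer and the biases stay free so attention can sharpen
                for key in opt.keys:
                    if not key.startswith(("ba", "bs", "wa")):
                        grads[key] = grads[key] + train_cfg.weight_decay * mp.params[key]
            opt.step(mp.params, grads)
            total += loss * len(idx)
            seen += len(idx)
        mp.loss_trace.append(total / seen)
    return mp


def predict_instances(
    instances: Sequence[CandidateInstance],
    mp: ModelParams,
    kstore: KnowledgeStore,
    word_vecs: Optional[Mapping[str, np.ndarray]] = None,
    batch_size: int = 100,
) -> list[InstancePrediction]:
    """Per-instance probabilities and argmax labels, input order preserved."""
    if not instances:
        return []
    lookup = WordVectorLookup(word_vecs or {}, mp.cfg.dim, seed=mp.cfg.seed)
    enc = _encode(instances, mp.vocab, kstore, lookup, mp.cfg, trained=mp, labeled=False)
    # swap in the prediction-time entity/relation tables
    pred_mp = ModelParams(
        mp.cfg,
        mp.vocab,
        {**mp.params, "ent": enc.ent_table, "rel": enc.rel_table},
        ent_index=enc.ent_index,
        rel_index=enc.rel_index,
    )
    out: list[InstancePrediction] = []
    for start in range(0, len(instances), batch_size):
        idx = np.arange(start, min(start + batch_size, len(instances)))
        batch = _make_batch(enc, idx)
        probs, _ = forward_batch(pred_mp, batch)
        for bi, i in enumerate(idx):
            inst = instances[i]
            p1 = float(probs[bi, 1])
            out.append(
                InstancePrediction(
                    doc_id=inst.doc_id,
                    pair=inst.pair,
                    probability=p1,
                    label=predict_label(probs[bi]),
                )
            )
    return out


def aggregate_document(preds: Iterable[InstancePrediction]) -> list[PredictionRecord]:
    """Document-level any-positive aggregation over (doc, pair) groups.

    A pair is positive iff at least one of its instances is predicted
    positive; the score is the maximum instance probability.
    """
    groups: dict[tuple[str, tuple[str, str]], list[InstancePrediction]] = {}
    order: list[tuple[str, tuple[str, str]]] = []
    for p in preds:
        key = (p.doc_id, p.pair)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(p)
    records = []
    for key in order:
        members = groups[key]
        if any(m.label == 1 for m in members):
            records.append(
                PredictionRecord(
                    doc_id=key[0],
                    pair=key[1],
                    score=max(m.probability for m in members),
                    source="model",
                )
            )
    return records


def collect_attention_rows(
    instances: Sequence[CandidateInstance],
    mp: ModelParams,
    kstore: KnowledgeStore,
    word_vecs: Optional[Mapping[str, np.ndarray]] = None,
) -> list[tuple[str, int, int, int, str, float]]:
    """Per-token attention weights for every layer and network.

    Rows are (doc_id, instance index, layer, network, token, weight),
    ready for the attention-dump TSV.
    """
    lookup = WordVectorLookup(word_vecs or {}, mp.cfg.dim, seed=mp.cfg.seed)
    enc = _encode(instances, mp.vocab, kstore, lookup, mp.cfg, trained=mp, labeled=False)
    rows: list[tuple[str, int, int, int, str, float]] = []
    emb = mp.params["emb"]
    for i, inst in enumerate(instances):
        tens = InstanceTensors(
            m=emb[enc.tok[i]].T,
            dist1=enc.dist1[i],
            dist2=enc.dist2[i],
            e1=enc.ent_table[enc.e1[i]],
            e2=enc.ent_table[enc.e2[i]],
            rel=enc.rel_table[enc.rel[i]],
        )
        _, att = forward_instance(tens, mp, collect_attention=True)
        for layer, network, alpha in att:
            for t_idx, w in enumerate(inst.context):
                rows.append((inst.doc_id, i, layer, network, w, float(alpha[t_idx])))
    return rows


def tune_weight_decay(
    instances: Sequence[CandidateInstance],
    kstore: KnowledgeStore,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    candidates: Sequence[float] = (0.003, 0.01, 0.03),
    word_vecs: Optional[Mapping[str, np.ndarray]] = None,
    n_folds: int = 5,
    max_folds: int = 1,
) -> float:
    """Select the L2 penalty by cross-validation on the training set.

    Folds are grouped by document; validation scores pair-level micro-F1
    against the distant labels.  ``max_folds`` caps how many of the
    ``n_folds`` splits are evaluated (1 = a single held-out fold), which
    keeps tuning cheap at small corpus sizes.
    """
    from .postprocess import evaluate_micro   # local import, avoids a cycle
    from .io_formats import GoldPair

    folds = crossval_folds(instances, n_folds=n_folds, seed=train_cfg.seed)[:max_folds]
    best_wd, best_f = candidates[0], -1.0
    for wd in candidates:
        scores = []
        for fit_insts, dev_insts in folds:
            cfg_wd = replace(train_cfg, weight_decay=wd)
            mp = train(fit_insts, kstore, model_cfg, cfg_wd, word_vecs=word_vecs)
            preds = predict_instances(dev_insts, mp, kstore, word_vecs=word_vecs)
            recs = aggregate_document(preds)
            gold = [
                GoldPair(doc_id, pair)
                for doc_id, pair in sorted(
                    {(i.doc_id, i.pair) for i in dev_insts if i.label == 1}
                )
            ]
            scores.append(evaluate_micro(recs, gold).f1)
        mean_f = float(np.mean(scores))
        logger.info("weight_decay %.4g: dev F1 %.4f", wd, mean_f)
        if mean_f > best_f:
            best_wd, best_f = wd, mean_f
    return best_wd


def crossval_folds(
    instances: Sequence[CandidateInstance], n_folds: int = 5, seed: int = 0
) -> list[tuple[list[CandidateInstance], list[CandidateInstance]]]:
    """Document-grouped K-fold splits for hyperparameter tuning."""
    docs = sorted({inst.doc_id for inst in instances})
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(docs))
    folds: list[set[str]] = [set() for _ in range(n_folds)]
    for i, di in enumerate(order):
        folds[i % n_folds].add(docs[di])
    out = []
    for f in folds:
        train_insts = [x for x in instances if x.doc_id not in f]
        test_insts = [x for x in instances if x.doc_id in f]
        out.append((train_insts, test_insts))
    return out
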