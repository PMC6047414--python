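"""Synthetic corpora, gold pairs, KB triples and word vectors.

The generator emulates the statistical structure the pipeline exploits,
at desk scale:

* documents whose gene-pair placements satisfy the candidate rules
  (same-sentence mentions, token distance inside (3, 50));
* interacting (gold) pairs carry a planted trigger word — drawn from an
  interaction/mutation lexicon — between the two mentions with a
  configurable probability, non-interacting placements at a lower
  background rate;
* a KB whose triples cover gold pairs at a configurable consistency rate
  ρ plus decoy triples over non-gold pairs, with a small PPI relation
  vocabulary;
* seeded random unit-norm word vectors over the full generator vocabulary.

Placements within a document are spaced at least three sentences apart, so
every candidate instance maps to exactly one placement and the distant
document-level labels are exact instance labels.  Filler tokens follow a
Zipf-like frequency profile.  Gene surfaces are ``GENE<k>`` with gene id
``<k>``, which keeps offset re-slicing and normalization trivial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_formats import (
    Document,
    GoldPair,
    Mention,
    TripleRecord,
    canonical_pair,
    write_pairs_tsv,
    write_pubtator,
    write_triples_tsv,
    write_word_vectors,
)

logger = logging.getLogger("memppi")

__all__ = ["SimConfig", "SimData", "generate_corpus", "generate_kb",
           "generate_word_vectors", "generate_dataset", "simulate_to_dir"]

DEFAULT_TRIGGERS = (
    "phosphorylation", "mutant", "binds", "kinase", "interact", "complex",
)
DEFAULT_RELATIONS = (
    "physical_association", "direct_interaction", "phosphorylation_reaction",
    "ubiquitination_reaction", "association",
)
_PLACEMENT_GAP = 3   # min sentence distance between placements in a doc


@dataclass
class SimConfig:
    n_docs: int = 200
    n_genes: int = 240
    vocab_size: int = 120
    dim: int = 100
    sentences_per_doc: tuple[int, int] = (10, 13)
    tokens_per_sentence: tuple[int, int] = (8, 14)
    pairs_per_doc: tuple[int, int] = (2, 3)
    token_distance_range: tuple[int, int] = (5, 12)
    positive_pair_rate: float = 0.5
    triggers: tuple[str, ...] = DEFAULT_TRIGGERS
    trigger_prob: float = 0.9
    background_trigger_prob: float = 0.05
    kb_consistency: float = 0.9     # ρ: P(gold pair gets a KB triple)
    decoy_rate: float = 0.1         # decoy triples per gold pair
    n_relations: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.positive_pair_rate, self.trigger_prob,
                     self.background_trigger_prob, self.kb_consistency):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for lo, hi in (self.sentences_per_doc, self.tokens_per_sentence,
                       self.pairs_per_doc, self.token_distance_range):
            if lo > hi or lo < 1:
                raise ValueError("ranges must be non-empty and positive")
        lo, hi = self.token_distance_range
        if lo <= 3 or hi >= 50:
            raise ValueError(
                "token_distance_range must sit strictly inside (3, 50) so "
                "placements satisfy the candidate rules"
            )
        # placements sit at sentences s0 + i*(gap+1) with s0 <= 1
        needed = 2 + (_PLACEMENT_GAP + 1) * (self.pairs_per_doc[1] - 1)
        if self.pairs_per_doc[1] > 1 and self.sentences_per_doc[0] < needed:
            raise ValueError(
                f"sentences_per_doc must start at >= {needed} to space "
                f"{self.pairs_per_doc[1]} placements {_PLACEMENT_GAP} "
                "sentences apart"
            )
        if self.n_genes < 2 * self.pairs_per_doc[1]:
            raise ValueError("n_genes too small for the requested placements")

    @property
    def filler_words(self) -> list[str]:
        return [f"w{i:03d}" for i in range(self.vocab_size)]

    @property
    def relation_labels(self) -> list[str]:
        base = list(DEFAULT_RELATIONS)
        while len(base) < self.n_relations:
            base.append(f"relation_{len(base)}")
        return base[: self.n_relations]

    @property
    def gene_ids(self) -> list[str]:
        return [str(k + 1) for k in range(self.n_genes)]

    def gene_surface(self, gene_id: str) -> str:
        return f"GENE{gene_id}"


@dataclass
class SimData:
    """One generated study: corpus, annotations, gold pairs, KB, vectors."""

    cfg: SimConfig
    docs: list[Document]
    mentions: list[Mention]
    gold: list[GoldPair]
    triples: list[TripleRecord]
    word_vecs: dict[str, np.ndarray]

    @property
    def entity_words(self) -> dict[str, list[str]]:
        return {g: [self.cfg.gene_surface(g).lower()] for g in self.cfg.gene_ids}

    def subset(self, doc_ids: Sequence[str]) -> "SimData":
        wanted = set(doc_ids)
        return SimData(
            cfg=self.cfg,
            docs=[d for d in self.docs if d.doc_id in wanted],
            mentions=[m for m in self.mentions if m.doc_id in wanted],
            gold=[g for g in self.gold if g.doc_id in wanted],
            triples=self.triples,
            word_vecs=self.word_vecs,
        )

    def split(self, n_train: int) -> tuple["SimData", "SimData"]:
        ids = [d.doc_id for d in self.docs]
        return self.subset(ids[:n_train]), self.subset(ids[n_train:])


def _zipf_probs(k: int) -> np.ndarray:
    w = 1.0 / np.arange(1, k + 1) ** 1.1
    return w / w.sum()


def generate_corpus(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[Document], list[Mention], list[GoldPair]]:
    """Documents with planted mention-pair placements and gold labels."""
    rng = rng or np.random.default_rng([cfg.seed & 0x7FFFFFFF, 1])
    fillers = cfg.filler_words
    probs = _zipf_probs(len(fillers))
    docs: list[Document] = []
    mentions: list[Mention] = []
    gold: list[GoldPair] = []

    for di in range(cfg.n_docs):
        doc_id = f"d{di:04d}"
        ns = int(rng.integers(cfg.sentences_per_doc[0], cfg.sentences_per_doc[1] + 1))
        n_place = int(rng.integers(cfg.pairs_per_doc[0], cfg.pairs_per_doc[1] + 1))
        slots = []
        s = int(rng.integers(0, 2)) if n_place > 1 else int(rng.integers(0, ns))
        for _ in range(n_place):
            slots.append(s)
            s += _PLACEMENT_GAP + 1
        genes = [str(g) for g in
                 rng.choice(cfg.n_genes, size=2 * n_place, replace=False) + 1]

        # sentence token lists
        sents: list[list[str]] = []
        doc_mentions: list[tuple[int, int, str]] = []   # (sent, tok idx, gene)
        for si in range(ns):
            if si in slots:
                pi = slots.index(si)
                ga, gb = genes[2 * pi], genes[2 * pi + 1]
                delta = int(rng.integers(cfg.token_distance_range[0],
                                         cfg.token_distance_range[1] + 1))
                between = [fillers[j] for j in
                           rng.choice(len(fillers), size=delta - 1, p=probs)]
                positive = rng.random() < cfg.positive_pair_rate
                plant = cfg.trigger_prob if positive else cfg.background_trigger_prob
                if between and rng.random() < plant:
                    pos = int(rng.integers(len(between)))
                    between[pos] = cfg.triggers[int(rng.integers(len(cfg.triggers)))]
                if positive:
                    gold.append(GoldPair(doc_id, (ga, gb)))
                pre = [fillers[j] for j in rng.choice(len(fillers), size=3, p=probs)]
                post = [fillers[j] for j in rng.choice(len(fillers), size=3, p=probs)]
                toks = pre + [cfg.gene_surface(ga)] + between + [cfg.gene_surface(gb)] + post
                doc_mentions.append((si, 3, ga))
                doc_mentions.append((si, 3 + delta, gb))
            else:
                nt = int(rng.integers(cfg.tokens_per_sentence[0],
                                      cfg.tokens_per_sentence[1] + 1))
                toks = [fillers[j] for j in rng.choice(len(fillers), size=nt, p=probs)]
            toks[0] = toks[0].capitalize()
            sents.append(toks)

        title_words = [fillers[j] for j in rng.choice(len(fillers), size=4, p=probs)]
        title = " ".join(title_words).capitalize() + "."
        # assemble abstract, tracking character offsets of every token
        abstract_parts: list[str] = []
        offset = 0   # within the abstract
        token_starts: dict[tuple[int, int], int] = {}
        for si, toks in enumerate(sents):
            for ti, tok in enumerate(toks):
                token_starts[(si, ti)] = offset
                abstract_parts.append(tok)
                offset += len(tok)
                if ti < len(toks) - 1:
                    abstract_parts.append(" ")
                    offset += 1
            abstract_parts.append(".")
            offset += 1
            if si < len(sents) - 1:
                abstract_parts.append(" ")
                offset += 1
        abstract = "".join(abstract_parts)
        doc = Document(doc_id, title, abstract)
        base = len(title) + 1
        for si, ti, gid in doc_mentions:
            surface = cfg.gene_surface(gid)
            m = Mention(doc_id, base + token_starts[(si, ti)], len(surface),
                        surface, gid)
            m.validate_against(doc)
            mentions.append(m)
        docs.append(doc)

    # collapse duplicate gold rows (same pair planted in two docs is distinct)
    seen = set()
    uniq_gold = []
    for g in gold:
        key = (g.doc_id, g.pair)
        if key not in seen:
            seen.add(key)
            uniq_gold.append(g)
    return docs, mentions, uniq_gold


def generate_kb(
    cfg: SimConfig,
    gold: Sequence[GoldPair],
    rng: Optional[np.random.Generator] = None,
) -> list[TripleRecord]:
    """Triples covering gold pairs at rate ρ plus decoys over non-gold pairs."""
    rng = rng or np.random.default_rng([cfg.seed & 0x7FFFFFFF, 2])
    relations = cfg.relation_labels
    gold_pairs = sorted({g.pair for g in gold})
    triples: list[TripleRecord] = []
    seen: set[TripleRecord] = set()

    def add(a: str, b: str) -> None:
        rel = relations[int(rng.integers(len(relations)))]
        if rng.random() < 0.5:
            a, b = b, a
        tr = TripleRecord(a, rel, b)
        if tr not in seen:
            seen.add(tr)
            triples.append(tr)

    for a, b in gold_pairs:
        if rng.random() < cfg.kb_consistency:
            add(a, b)
    n_decoys = round(cfg.decoy_rate * len(gold_pairs))
    gold_set = set(gold_pairs)
    made, attempts = 0, 0
    while made < n_decoys and attempts < 100 * (n_decoys + 1):
        attempts += 1
        g = rng.choice(cfg.n_genes, size=2, replace=False) + 1
        pair = canonical_pair(str(g[0]), str(g[1]))
        if pair in gold_set:
            continue
        add(*pair)
        made += 1
    return triples


def generate_word_vectors(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> dict[str, np.ndarray]:
    """Unit-norm random vectors for every word the generator can emit."""
    rng = rng or np.random.default_rng([cfg.seed & 0x7FFFFFFF, 3])
    vocab = (
        cfg.filler_words
        + list(cfg.triggers)
        + [cfg.gene_surface(g).lower() for g in cfg.gene_ids]
        + ["gene0", "NUMBER", ".", ","]
    )
    out: dict[str, np.ndarray] = {}
    for w in vocab:
        v = rng.normal(0.0, 1.0, cfg.dim)
        out[w] = v / np.linalg.norm(v)
    return out


def generate_dataset(cfg: SimConfig) -> SimData:
    """Corpus + KB + word vectors under one seed."""
    docs, mentions, gold = generate_corpus(cfg)
    triples = generate_kb(cfg, gold)
    vecs = generate_word_vectors(cfg)
    return SimData(cfg, docs, mentions, gold, triples, vecs)


def simulate_to_dir(cfg: SimConfig, outdir: str | Path) -> SimData:
    """Generate a dataset and write the four pipeline input files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = generate_dataset(cfg)
    write_pubtator(outdir / "docs.pubtator", data.docs, data.mentions)
    write_pairs_tsv(outdir / "pairs.tsv", data.gold)
    write_triples_tsv(outdir / "triples.tsv", data.triples)
    write_word_vectors(outdir / "vectors.txt", data.word_vecs)
    return data
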