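"""Dual memory-network classifier with multi-hop attention.

The classifier decides whether a candidate mention pair expresses a
mutation-affected protein-protein interaction.  The masked context-word
embeddings form an external memory m ∈ R^{d×n}.  Two memory networks — one
per entity — each run K computational layers; at layer k a network

1. re-weights every memory column by a position-impact factor
   per_ik = (1 − p_i/n) − (k/d)(1 − 2 p_i/n), where p_i is the token
   distance of context word i to that network's entity mention,
2. scores each weighted column against its query entity,
   g_i = tanh(Wa [m_i; e] + ba), and normalizes with a softmax to
   attention weights α,
3. pools v_att = Σ_i α_i m_i and updates its query
   e' = Wt e ⊕ v_att (dimension-wise sum; the Max variant takes the
   dimension-wise maximum instead).

The two networks share Wa, ba, Wt by default so the same attention
operation serves both entities; the "different attention" variant unties
Wa/ba.  The single-network variant keeps one memory and concatenates both
entity embeddings to every memory column (Wa ∈ R^{1×3d}); its shared
v_att updates both queries.  The final queries, concatenated with the
pair's KB relation embedding when enabled, feed a 2-way softmax.

Named variant configurations: ``mnm`` (TransE entities + relation, dual,
shared attention, sum pooling), ``ae``/``te``/``ae_tr`` prior-knowledge
ablations, ``mnm_da``/``mnm_max``/``mnm_single`` architecture ablations.

Everything is NumPy; :func:`loss_and_grads` returns analytic gradients for
every trainable tensor (verified against central finite differences in the
test suite).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger("memppi")

__all__ = [
    "ModelConfig",
    "LayerParams",
    "InstanceTensors",
    "ModelParams",
    "BatchTensors",
    "position_percentage",
    "weight_memory",
    "attention",
    "attention_weights",
    "hop_update",
    "forward_instance",
    "predict_label",
    "forward_batch",
    "loss_and_grads",
    "init_params",
    "UNK",
]

UNK = "<unk>"

VARIANTS = {
    "mnm": {},
    "ae": {"entity_source": "averaged_words", "use_relation_embedding": False},
    "te": {"entity_source": "transe", "use_relation_embedding": False},
    "ae_tr": {"entity_source": "averaged_words", "use_relation_embedding": True},
    "mnm_da": {"attention_sharing": "separate"},
    "mnm_max": {"pooling": "max"},
    "mnm_single": {"architecture": "single"},
}


@dataclass
class ModelConfig:
    layers: int = 4                      # K computational layers
    dim: int = 100                       # word/entity/relation dimension d
    entity_source: str = "transe"        # transe | averaged_words
    use_relation_embedding: bool = True
    architecture: str = "dual"           # dual | single
    attention_sharing: str = "shared"    # shared | separate
    pooling: str = "sum"                 # sum | max
    finetune_kb_vectors: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layers < 1:
            raise ValueError("need at least one computational layer")
        if self.entity_source not in ("transe", "averaged_words"):
            raise ValueError(f"unknown entity_source {self.entity_source!r}")
        if self.architecture not in ("dual", "single"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.attention_sharing not in ("shared", "separate"):
            raise ValueError(f"unknown attention_sharing {self.attention_sharing!r}")
        if self.pooling not in ("sum", "max"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if self.architecture == "single" and self.attention_sharing == "separate":
            raise ValueError("the single-network variant has one attention")

    @classmethod
    def variant(cls, name: str, **overrides) -> "ModelConfig":
        """Named system configuration (mnm, ae, te, ae_tr, mnm_da, ...)."""
        key = name.lower().replace("-", "_")
        if key not in VARIANTS:
            raise ValueError(f"unknown variant {name!r}; options: {sorted(VARIANTS)}")
        kwargs = dict(VARIANTS[key])
        kwargs.update(overrides)
        return cls(**kwargs)

    @property
    def classifier_dim(self) -> int:
        base = 2 * self.dim
        return base + self.dim if self.use_relation_embedding else base


@dataclass
class LayerParams:
    """Attention and transform parameters of one computational layer."""

    wa: np.ndarray        # (2d,) — or (3d,) in the single-network variant
    ba: float
    wt: np.ndarray        # (d, d)


@dataclass
class InstanceTensors:
    """One candidate instance in tensor form (memory is d×n, column-major)."""

    m: np.ndarray          # (d, n) raw context-word embeddings
    dist1: np.ndarray      # (n,) token distances to mention 1
    dist2: np.ndarray      # (n,)
    e1: np.ndarray         # (d,)
    e2: np.ndarray         # (d,)
    rel: np.ndarray        # (d,)
    label: Optional[int] = None


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def position_percentage(p, n, k: int, d: int):
    """Position-impact factor (1 − p/n) − (k/d)(1 − 2 p/n).

    ``p`` is the relative token distance (1-based), ``n`` the context
    length, ``k`` the 1-based layer number, ``d`` the embedding dimension.
    Accepts scalars or arrays in ``p``.
    """
    n = np.asarray(n, dtype=np.float64)
    if np.any(n <= 0):
        raise ValueError("context length n must be positive")
    p = np.asarray(p, dtype=np.float64)
    frac = p / n
    return (1.0 - frac) - (k / d) * (1.0 - 2.0 * frac)


def weight_memory(m: np.ndarray, dists: np.ndarray, k: int, d: int) -> np.ndarray:
    """Scale memory column i by position_percentage(dist_i, n, k, d).

    Distances are clipped into [1, n] so flank tokens of a mention at a
    document edge (whose distance to the far mention can exceed n by the
    missing flank width) stay inside the formula's stated domain.
    """
    n = m.shape[1]
    p = np.clip(np.asarray(dists, dtype=np.float64), 1, n)
    per = position_percentage(p, n, k, d)
    return m * per[None, :]


def attention_weights(scores: np.ndarray) -> np.ndarray:
    """Normalize relatedness scores to attention weights (softmax).

    Shift-invariant and summing to 1 over the sequence.
    """
    g = np.asarray(scores, dtype=np.float64)
    if g.size == 0:
        raise ValueError("empty score sequence")
    g = g - g.max()
    e = np.exp(g)
    return e / e.sum()


def attention(
    m_k: np.ndarray, e: np.ndarray, layer: LayerParams
) -> tuple[np.ndarray, np.ndarray]:
    """Attention weights and pooled memory for one query.

    ``e`` is the query vector concatenated to every memory column; it is a
    single entity embedding (dual networks) or the concatenation of both
    (single network).  Returns (α, v_att) with Σα = 1.
    """
    d, n = m_k.shape
    if n == 0:
        raise ValueError("empty memory")
    wa_m = layer.wa[:d]
    wa_e = layer.wa[d:]
    if len(wa_e) != len(e):
        raise ValueError("attention parameter / query shape mismatch")
    g = np.tanh(wa_m @ m_k + float(wa_e @ e) + layer.ba)
    alpha = attention_weights(g)
    v_att = m_k @ alpha
    return alpha, v_att


def hop_update(
    e: np.ndarray, v_att: np.ndarray, layer: LayerParams, pooling: str = "sum"
) -> np.ndarray:
    """New query: Wt e ⊕ v_att (sum) or dimension-wise max (Max variant)."""
    transformed = layer.wt @ e
    if pooling == "max":
        return np.maximum(transformed, v_att)
    return transformed + v_att


def predict_label(prob: Sequence[float]) -> int:
    """Argmax over the 2-class distribution; an exact tie goes negative."""
    return 1 if prob[1] > prob[0] else 0


def _softmax2(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class ModelParams:
    """Trainable tensors plus the vocabulary and configuration.

    ``params`` keys: ``emb`` (V×d word table, row 0 = UNK); per layer k
    (0-based) ``wa{k}``/``ba{k}``/``wt{k}`` (suffixes ``_1``/``_2`` under
    separate attention); classifier ``ws``/``bs``; resolved KB tables
    ``ent`` and ``rel`` indexed by the batch (trained only when
    ``finetune_kb_vectors``).
    """

    cfg: ModelConfig
    vocab: dict[str, int]
    params: dict[str, np.ndarray]
    ent_index: dict[str, int] = field(default_factory=dict)   # gene id → row
    rel_index: dict[str, int] = field(default_factory=dict)   # "a|b" → row
    loss_trace: list[float] = field(default_factory=list)

    def layer(self, k: int, network: int = 1) -> LayerParams:
        p = self.params
        if self.cfg.attention_sharing == "separate" and self.cfg.architecture == "dual":
            wa, ba = p[f"wa{k}_{network}"], p[f"ba{k}_{network}"]
        else:
            wa, ba = p[f"wa{k}"], p[f"ba{k}"]
        return LayerParams(wa=wa, ba=float(ba[0]), wt=p[f"wt{k}"])

    def trainable_keys(self) -> list[str]:
        keys = [k for k in self.params if k not in ("ent", "rel")]
        if self.cfg.finetune_kb_vectors:
            keys += [k for k in ("ent", "rel") if k in self.params]
        return keys

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "config.json", "w", encoding="utf-8") as fh:
            json.dump(asdict(self.cfg), fh, indent=2)
        with open(outdir / "vocab.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "words": self.vocab,
                    "entities": self.ent_index,
                    "pairs": self.rel_index,
                    "loss_trace": self.loss_trace,
                },
                fh,
            )
        np.savez(outdir / "params.npz", **self.params)

    @classmethod
    def load(cls, indir: str | Path) -> "ModelParams":
        indir = Path(indir)
        with open(indir / "config.json", encoding="utf-8") as fh:
            cfg = ModelConfig(**json.load(fh))
        with open(indir / "vocab.json", encoding="utf-8") as fh:
            meta = json.load(fh)
        with np.load(indir / "params.npz") as npz:
            params = {k: npz[k] for k in npz.files}
        return cls(
            cfg,
            meta["words"],
            params,
            ent_index=meta.get("entities", {}),
            rel_index=meta.get("pairs", {}),
            loss_trace=meta.get("loss_trace", []),
        )


def init_params(
    cfg: ModelConfig,
    vocab: dict[str, int],
    word_init: Optional[np.ndarray] = None,
    n_entities: int = 0,
    n_relations: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> ModelParams:
    """Random parameter initialization (word rows may be pre-trained)."""
    rng = rng or np.random.default_rng(cfg.seed)
    d = cfg.dim
    V = len(vocab)
    params: dict[str, np.ndarray] = {}
    if word_init is not None:
        if word_init.shape != (V, d):
            raise ValueError("word_init shape mismatch")
        params["emb"] = word_init.astype(np.float64).copy()
    else:
        params["emb"] = rng.normal(0.0, 0.01, (V, d))
    wa_len = 3 * d if cfg.architecture == "single" else 2 * d
    for k in range(cfg.layers):
        if cfg.attention_sharing == "separate" and cfg.architecture == "dual":
            for net in (1, 2):
                params[f"wa{k}_{net}"] = rng.normal(0.0, 1.0 / np.sqrt(wa_len), wa_len)
                params[f"ba{k}_{net}"] = np.zeros(1)
        else:
            params[f"wa{k}"] = rng.normal(0.0, 1.0 / np.sqrt(wa_len), wa_len)
            params[f"ba{k}"] = np.zeros(1)
        params[f"wt{k}"] = rng.normal(0.0, 1.0 / np.sqrt(d), (d, d))
    cdim = cfg.classifier_dim
    params["ws"] = rng.normal(0.0, 1.0 / np.sqrt(cdim), (2, cdim))
    params["bs"] = np.zeros(2)
    if n_entities:
        params["ent"] = np.zeros((n_entities, d))
    if n_relations:
        params["rel"] = np.zeros((n_relations, d))
    return ModelParams(cfg, dict(vocab), params)


# ---------------------------------------------------------------------------
# per-instance forward pass (compositional; used for prediction-time
# attention export and as the reference path for the batched trainer)
# ---------------------------------------------------------------------------

def forward_instance(
    inst: InstanceTensors,
    mp: ModelParams,
    collect_attention: bool = False,
) -> tuple[np.ndarray, list[tuple[int, int, np.ndarray]]]:
    """Probability 2-vector for one instance.

    With ``collect_attention`` also returns (layer, network, α) records,
    layer 1-based, network ∈ {1, 2} (single architecture reports network 1).
    """
    cfg = mp.cfg
    d = cfg.dim
    q1, q2 = inst.e1.copy(), inst.e2.copy()
    att: list[tuple[int, int, np.ndarray]] = []
    for k in range(cfg.layers):
        if cfg.architecture == "dual":
            l1 = mp.layer(k, network=1)
            l2 = mp.layer(k, network=2)
            mw1 = weight_memory(inst.m, inst.dist1, k + 1, d)
            mw2 = weight_memory(inst.m, inst.dist2, k + 1, d)
            a1, v1 = attention(mw1, q1, l1)
            a2, v2 = attention(mw2, q2, l2)
            q1_new = hop_update(q1, v1, l1, cfg.pooling)
            q2_new = hop_update(q2, v2, l2, cfg.pooling)
            q1, q2 = q1_new, q2_new
            if collect_attention:
                att.append((k + 1, 1, a1))
                att.append((k + 1, 2, a2))
        else:
            layer = mp.layer(k)
            n = inst.m.shape[1]
            p1 = np.clip(np.asarray(inst.dist1, dtype=np.float64), 1, n)
            p2 = np.clip(np.asarray(inst.dist2, dtype=np.float64), 1, n)
            per = 0.5 * (
                position_percentage(p1, n, k + 1, d)
                + position_percentage(p2, n, k + 1, d)
            )
            mw = inst.m * per[None, :]
            a, v = attention(mw, np.concatenate([q1, q2]), layer)
            q1_new = hop_update(q1, v, layer, cfg.pooling)
            q2_new = hop_update(q2, v, layer, cfg.pooling)
            q1, q2 = q1_new, q2_new
            if collect_attention:
                att.append((k + 1, 1, a))
    feat = [q1, q2]
    if cfg.use_relation_embedding:
        feat.append(inst.rel)
    logits = mp.params["ws"] @ np.concatenate(feat) + mp.params["bs"]
    return _softmax2(logits), att


# ---------------------------------------------------------------------------
# batched forward/backward for training
# ---------------------------------------------------------------------------

@dataclass
class BatchTensors:
    """Padded minibatch. ``tok`` indexes ``emb``; padded slots have mask 0."""

    tok: np.ndarray       # (B, N) int
    mask: np.ndarray      # (B, N) float, 1 for real tokens
    nlen: np.ndarray      # (B,) true context lengths
    dist1: np.ndarray     # (B, N) float
    dist2: np.ndarray     # (B, N) float
    e1: np.ndarray        # (B,) int index into params["ent"]
    e2: np.ndarray        # (B,) int
    rel: np.ndarray       # (B,) int index into params["rel"]
    y: Optional[np.ndarray] = None   # (B,) labels


def _per_factor(dist, nlen, mask, k1: int, d: int) -> np.ndarray:
    n = nlen[:, None].astype(np.float64)
    p = np.clip(dist, 1, n)
    frac = p / n
    per = (1.0 - frac) - (k1 / d) * (1.0 - 2.0 * frac)
    return per * mask


def forward_batch(mp: ModelParams, batch: BatchTensors):
    """Vectorized forward pass; returns (probs (B,2), cache for backward)."""
    cfg = mp.cfg
    d = cfg.dim
    p = mp.params
    M0 = p["emb"][batch.tok] * batch.mask[..., None]          # (B,N,d)
    E1 = p["ent"][batch.e1]
    E2 = p["ent"][batch.e2]
    Rv = p["rel"][batch.rel]
    cache: dict = {"M0": M0, "layers": [], "batch": batch}
    if cfg.architecture == "dual":
        Q = [E1, E2]
        dists = [batch.dist1, batch.dist2]
        for k in range(cfg.layers):
            lstate = []
            newQ = []
            for j in (0, 1):
                lp = mp.layer(k, network=j + 1)
                wa_m, wa_q = lp.wa[:d], lp.wa[d:]
                per = _per_factor(dists[j], batch.nlen, batch.mask, k + 1, d)
                Mw = M0 * per[..., None]
                z = Mw @ wa_m + (Q[j] @ wa_q)[:, None] + lp.ba
                g = np.tanh(z)
                gm = np.where(batch.mask > 0, g, -1e30)
                gm = gm - gm.max(axis=1, keepdims=True)
                eg = np.exp(gm) * batch.mask
                alpha = eg / eg.sum(axis=1, keepdims=True)
                v = np.einsum("bn,bnd->bd", alpha, Mw)
                Alin = Q[j] @ lp.wt.T
                if cfg.pooling == "max":
                    Qout = np.maximum(Alin, v)
                else:
                    Qout = Alin + v
                lstate.append(
                    {"per": per, "Mw": Mw, "g": g, "alpha": alpha, "v": v,
                     "Qin": Q[j], "Alin": Alin}
                )
                newQ.append(Qout)
            Q = newQ
            cache["layers"].append(lstate)
        feat_parts = [Q[0], Q[1]]
    else:  # single
        Q = [E1, E2]
        for k in range(cfg.layers):
            lp = mp.layer(k)
            wa_m, wa_q1, wa_q2 = lp.wa[:d], lp.wa[d : 2 * d], lp.wa[2 * d :]
            per1 = _per_factor(batch.dist1, batch.nlen, batch.mask, k + 1, d)
            per2 = _per_factor(batch.dist2, batch.nlen, batch.mask, k + 1, d)
            per = 0.5 * (per1 + per2)
            Mw = M0 * per[..., None]
            z = Mw @ wa_m + (Q[0] @ wa_q1)[:, None] + (Q[1] @ wa_q2)[:, None] + lp.ba
            g = np.tanh(z)
            gm = np.where(batch.mask > 0, g, -1e30)
            gm = gm - gm.max(axis=1, keepdims=True)
            eg = np.exp(gm) * batch.mask
            alpha = eg / eg.sum(axis=1, keepdims=True)
            v = np.einsum("bn,bnd->bd", alpha, Mw)
            Alin1 = Q[0] @ lp.wt.T
            Alin2 = Q[1] @ lp.wt.T
            if cfg.pooling == "max":
                Qout1, Qout2 = np.maximum(Alin1, v), np.maximum(Alin2, v)
            else:
                Qout1, Qout2 = Alin1 + v, Alin2 + v
            cache["layers"].append(
                [{"per": per, "Mw": Mw, "g": g, "alpha": alpha, "v": v,
                  "Qin1": Q[0], "Qin2": Q[1], "Alin1": Alin1, "Alin2": Alin2}]
            )
            Q = [Qout1, Qout2]
        feat_parts = [Q[0], Q[1]]
    if cfg.use_relation_embedding:
        feat_parts.append(Rv)
    feat = np.concatenate(feat_parts, axis=1)
    logits = feat @ p["ws"].T + p["bs"]
    probs = _softmax2(logits)
    cache["feat"] = feat
    cache["probs"] = probs
    return probs, cache


def loss_and_grads(mp: ModelParams, batch: BatchTensors):
    """Mean cross-entropy over the batch and analytic parameter gradients."""
    cfg = mp.cfg
    d = cfg.dim
    p = mp.params
    probs, cache = forward_batch(mp, batch)
    y = batch.y
    if y is None:
        raise ValueError("loss requires labels")
    B = len(y)
    picked = np.clip(probs[np.arange(B), y], 1e-12, None)
    loss = float(-np.mean(np.log(picked)))

    grads = {k: np.zeros_like(v) for k, v in p.items()}
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    feat = cache["feat"]
    grads["ws"] += dlogits.T @ feat
    grads["bs"] += dlogits.sum(axis=0)
    dfeat = dlogits @ p["ws"]
    dQ = [dfeat[:, :d].copy(), dfeat[:, d : 2 * d].copy()]
    if cfg.use_relation_embedding:
        dRv = dfeat[:, 2 * d :]
    else:
        dRv = np.zeros((B, d))
    dM0 = np.zeros_like(cache["M0"])

    if cfg.architecture == "dual":
        for k in range(cfg.layers - 1, -1, -1):
            lstate = cache["layers"][k]
            for j in (0, 1):
                st = lstate[j]
                lp = mp.layer(k, network=j + 1)
                wa_m, wa_q = lp.wa[:d], lp.wa[d:]
                dQout = dQ[j]
                if cfg.pooling == "max":
                    take_a = (st["Alin"] >= st["v"]).astype(np.float64)
                    dAlin = dQout * take_a
                    dv = dQout * (1.0 - take_a)
                else:
                    dAlin, dv = dQout, dQout
                grads[f"wt{k}"] += dAlin.T @ st["Qin"]
                dQin = dAlin @ lp.wt
                dalpha = np.einsum("bd,bnd->bn", dv, st["Mw"])
                alpha = st["alpha"]
                dg = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
                dz = dg * (1.0 - st["g"] ** 2)
                dMw = alpha[..., None] * dv[:, None, :] + dz[..., None] * wa_m
                dwa_m = np.einsum("bn,bnd->d", dz, st["Mw"])
                dwa_q = (dz.sum(axis=1)[:, None] * st["Qin"]).sum(axis=0)
                dba = dz.sum()
                if cfg.attention_sharing == "separate":
                    grads[f"wa{k}_{j + 1}"] += np.concatenate([dwa_m, dwa_q])
                    grads[f"ba{k}_{j + 1}"] += dba
                else:
                    grads[f"wa{k}"] += np.concatenate([dwa_m, dwa_q])
                    grads[f"ba{k}"] += dba
                dQin = dQin + dz.sum(axis=1)[:, None] * wa_q
                dM0 += dMw * st["per"][..., None]
                dQ[j] = dQin
    else:
        for k in range(cfg.layers - 1, -1, -1):
            st = cache["layers"][k][0]
            lp = mp.layer(k)
            wa_m = lp.wa[:d]
            wa_q1, wa_q2 = lp.wa[d : 2 * d], lp.wa[2 * d :]
            if cfg.pooling == "max":
                take1 = (st["Alin1"] >= st["v"]).astype(np.float64)
                take2 = (st["Alin2"] >= st["v"]).astype(np.float64)
                dAlin1 = dQ[0] * take1
                dAlin2 = dQ[1] * take2
                dv = dQ[0] * (1 - take1) + dQ[1] * (1 - take2)
            else:
                dAlin1, dAlin2 = dQ[0], dQ[1]
                dv = dQ[0] + dQ[1]
            grads[f"wt{k}"] += dAlin1.T @ st["Qin1"] + dAlin2.T @ st["Qin2"]
            dQin1 = dAlin1 @ lp.wt
            dQin2 = dAlin2 @ lp.wt
            dalpha = np.einsum("bd,bnd->bn", dv, st["Mw"])
            alpha = st["alpha"]
            dg = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
            dz = dg * (1.0 - st["g"] ** 2)
            dMw = alpha[..., None] * dv[:, None, :] + dz[..., None] * wa_m
            dwa_m = np.einsum("bn,bnd->d", dz, st["Mw"])
            dsum = dz.sum(axis=1)[:, None]
            dwa_q1 = (dsum * st["Qin1"]).sum(axis=0)
            dwa_q2 = (dsum * st["Qin2"]).sum(axis=0)
            grads[f"wa{k}"] += np.concatenate([dwa_m, dwa_q1, dwa_q2])
            grads[f"ba{k}"] += dz.sum()
            dQin1 = dQin1 + dsum * wa_q1
            dQin2 = dQin2 + dsum * wa_q2
            dM0 += dMw * st["per"][..., None]
            dQ = [dQin1, dQin2]

    demb = grads["emb"]
    np.add.at(demb, batch.tok, dM0 * batch.mask[..., None])
    if "ent" in grads:
        np.add.at(grads["ent"], batch.e1, dQ[0])
        np.add.at(grads["ent"], batch.e2, dQ[1])
    if "rel" in grads:
        np.add.at(grads["rel"], batch.rel, dRv)
    return loss, grads, probs
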