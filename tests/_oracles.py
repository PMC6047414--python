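"""Independent reference implementations used as test oracles.

Everything here is deliberately written with plain Python loops and scalar
arithmetic, independent of the vectorized code paths it checks.
"""

import math
import re

from memppi.io_formats import canonical_pair
from memppi.preprocessing import segment_and_tokenize

NUMBER_RE = re.compile(r"^[0-9][0-9.,%]*$")
SPECIALS = set("*•†‡§")


def brute_force_candidates(doc, mentions, gold_pairs):
    """Enumerate candidate instances by a double loop with inline rules.

    Returns tuples (doc_id, pair, p1, p2, context, dist1, dist2, label)
    for comparison with the pipeline's candidate generation.  Shares only
    the tokenizer with the implementation under test.
    """
    tdoc = segment_and_tokenize(doc, mentions)
    toks = tdoc.tokens
    out = []
    order = sorted(
        range(len(tdoc.mentions)), key=lambda i: tdoc.mention_positions[i]
    )
    for a in range(len(order)):
        for b in range(a + 1, len(order)):
            i, j = order[a], order[b]
            mi, mj = tdoc.mentions[i], tdoc.mentions[j]
            if mi.gene_id == mj.gene_id:
                continue
            pi = tdoc.mention_positions[i]
            pj = tdoc.mention_positions[j]
            si, sj = toks[pi].sent, toks[pj].sent
            if abs(si - sj) >= 3:
                continue
            if not (3 < pj - pi < 50):
                continue
            window = []
            for t in range(pi - 3, pi):
                if t >= 0:
                    window.append(t)
            for t in range(pi + 1, pj):
                window.append(t)
            for t in range(pj + 1, pj + 4):
                if t < len(toks):
                    window.append(t)
            ctx, dd1, dd2 = [], [], []
            for t in window:
                tk = toks[t]
                if tk.mention_idx is not None:
                    word = "gene0"
                elif NUMBER_RE.match(tk.text):
                    word = "NUMBER"
                else:
                    word = "".join(c for c in tk.text if c not in SPECIALS).lower()
                    if not word:
                        continue
                ctx.append(word)
                dd1.append(max(1, abs(t - pi)))
                dd2.append(max(1, abs(t - pj)))
            if not ctx:
                continue
            pair = canonical_pair(mi.gene_id, mj.gene_id)
            label = 1 if pair in gold_pairs else 0
            out.append(
                (doc.doc_id, pair, pi, pj, tuple(ctx), tuple(dd1), tuple(dd2), label)
            )
    return out


def loop_forward(inst, mp):
    """Scalar loop-based forward pass of the memory-network classifier.

    Handles every variant: dual/single architecture, shared/separate
    attention, sum/max pooling, with/without the relation embedding.
    """
    cfg = mp.cfg
    d = cfg.dim
    n = inst.m.shape[1]
    q1 = [float(x) for x in inst.e1]
    q2 = [float(x) for x in inst.e2]

    def per_factor(p, k):
        p = min(max(p, 1.0), float(n))
        return (1 - p / n) - (k / d) * (1 - 2 * p / n)

    def attend(mw, scores):
        mx = max(scores)
        ex = [math.exp(s - mx) for s in scores]
        tot = sum(ex)
        alpha = [x / tot for x in ex]
        v = [sum(alpha[i] * mw[r][i] for i in range(n)) for r in range(d)]
        return v

    def matvec(W, x):
        return [sum(W[r][c] * x[c] for c in range(len(x))) for r in range(len(W))]

    for k in range(cfg.layers):
        if cfg.architecture == "dual":
            newq = []
            for net, (q, dists) in enumerate(
                [(q1, inst.dist1), (q2, inst.dist2)], start=1
            ):
                lp = mp.layer(k, network=net)
                wa = [float(x) for x in lp.wa]
                mw = [
                    [
                        float(inst.m[r][i]) * per_factor(float(dists[i]), k + 1)
                        for i in range(n)
                    ]
                    for r in range(d)
                ]
                scores = [
                    math.tanh(
                        sum(wa[r] * mw[r][i] for r in range(d))
                        + sum(wa[d + r] * q[r] for r in range(d))
                        + lp.ba
                    )
                    for i in range(n)
                ]
                v = attend(mw, scores)
                wq = matvec(lp.wt.tolist(), q)
                if cfg.pooling == "max":
                    newq.append([max(wq[r], v[r]) for r in range(d)])
                else:
                    newq.append([wq[r] + v[r] for r in range(d)])
            q1, q2 = newq
        else:
            lp = mp.layer(k)
            wa = [float(x) for x in lp.wa]
            mw = [
                [
                    float(inst.m[r][i])
                    * 0.5
                    * (
                        per_factor(float(inst.dist1[i]), k + 1)
                        + per_factor(float(inst.dist2[i]), k + 1)
                    )
                    for i in range(n)
                ]
                for r in range(d)
            ]
            scores = [
                math.tanh(
                    sum(wa[r] * mw[r][i] for r in range(d))
                    + sum(wa[d + r] * q1[r] for r in range(d))
                    + sum(wa[2 * d + r] * q2[r] for r in range(d))
                    + lp.ba
                )
                for i in range(n)
            ]
            v = attend(mw, scores)
            wq1 = matvec(lp.wt.tolist(), q1)
            wq2 = matvec(lp.wt.tolist(), q2)
            if cfg.pooling == "max":
                q1 = [max(wq1[r], v[r]) for r in range(d)]
                q2 = [max(wq2[r], v[r]) for r in range(d)]
            else:
                q1 = [wq1[r] + v[r] for r in range(d)]
                q2 = [wq2[r] + v[r] for r in range(d)]

    feat = q1 + q2
    if cfg.use_relation_embedding:
        feat = feat + [float(x) for x in inst.rel]
    ws = mp.params["ws"].tolist()
    bs = mp.params["bs"].tolist()
    logits = [
        sum(ws[o][c] * feat[c] for c in range(len(feat))) + bs[o] for o in (0, 1)
    ]
    mx = max(logits)
    ex = [math.exp(z - mx) for z in logits]
    tot = sum(ex)
    return [x / tot for x in ex]


def micro_prf(pred_keys, gold_keys):
    """Confusion-count micro scores from two sets of (doc, pair) keys."""
    pred, gold = set(pred_keys), set(gold_keys)
    tp = sum(1 for k in pred if k in gold)
    fp = len(pred) - tp
    fn = sum(1 for k in gold if k not in pred)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f
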