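# memppi

Memory-network extraction of protein–protein interactions affected by
mutations (PPIm) from biomedical abstracts.

## The problem

Knowing which protein–protein interactions are disrupted or altered by a
genetic mutation is central to precision-medicine curation, but the
evidence is buried in free text. Given abstracts whose protein mentions
are already recognized and normalized to Entrez Gene IDs, the task is to
decide, per document, which unordered gene-ID pairs participate in a
mutation-affected interaction. `memppi` implements a complete pipeline for
this document-level relation-extraction task, aimed at text-mining
researchers who want a reproducible, dependency-light (NumPy) reference
implementation with exact analytic gradients.

## The method

1. **Candidate generation.** Document-level labels are projected onto
   every co-occurring mention pair (distant labeling). A pair is kept iff
   its sentence distance is < 3 and its token distance is in (3, 50); its
   context window is the between-span plus three expansion tokens per
   side, with the pair mentions removed, other proteins masked to
   `gene0`, and numbers masked to `NUMBER`.
2. **Knowledge representations.** TransE embeds KB triples (h, r, t) so
   that h + r ≈ t, by minimizing the margin ranking loss
   Σ max(0, γ + ‖h+r−t‖ − ‖h′+r−t′‖) against corrupted triples. A pair's
   relation embedding is the mean vector of its KB relations (zero if the
   pair is absent); entities absent from the KB use averaged word vectors.
3. **Classification.** Two memory networks — one per entity, sharing
   parameters — read the context embeddings m ∈ R^{d×n} through K
   computational layers. Layer k rescales memory column i by the
   position impact per_ik = (1 − p_i/n) − (k/d)(1 − 2p_i/n), attends with
   g_i = tanh(W_a[m_i; e] + b_a), α = softmax(g), v_att = Σ α_i m_i, and
   updates its query e′ = W_t e ⊕ v_att. The final queries and the
   relation embedding feed a 2-way softmax; training is Adam on the mean
   cross-entropy. Ablations (`ae`, `te`, `ae_tr`) and architecture
   variants (`mnm_single`, `mnm_da`, `mnm_max`) are configuration presets.
4. **Post-processing and scoring.** A pair co-mentioned in more than N=2
   sentences is also declared positive (sentence-support rule); rule and
   model positives are merged by set union. Scoring is micro-averaged
   Exact Match on (document, gene-ID pair): pooled TP/FP/FN, then
   P, R, F1.

Real annotated corpora are optional: `memppi.synthetic` generates
PubTator-style abstracts with planted interaction triggers, gold pairs,
a correlated KB, and word vectors, so the whole pipeline runs and is
tested offline. See `docs/methods.md` for modeling details and the
generator's scope.

## Worked example

```python
from memppi import (
    SimConfig, generate_dataset, generate_instances,
    TransEConfig, train_transe, ModelConfig,
)
from memppi.training import (
    TrainConfig, train, predict_instances, aggregate_document,
)
from memppi.postprocess import evaluate_micro

# a 300-document synthetic study: 200 train / 100 held-out
cfg = SimConfig(n_docs=300, dim=32, seed=3,
                trigger_prob=0.9, background_trigger_prob=0.05,
                kb_consistency=0.9)
data = generate_dataset(cfg)
tr, te = data.split(200)
print(len(tr.docs), len(tr.gold), len(data.triples))
# 200 268 391

kb = train_transe(data.triples, TransEConfig(dim=32, epochs=50, seed=1),
                  word_vecs=data.word_vecs, entity_words=data.entity_words)

instances = generate_instances(tr.docs, tr.mentions, tr.gold)
print(len(instances))          # 507 candidate instances
model = train(instances, kb,
              ModelConfig.variant("mnm", layers=2, dim=32, seed=5),
              TrainConfig(epochs=100, seed=5), word_vecs=data.word_vecs)

test_instances = generate_instances(te.docs, te.mentions, te.gold)
preds = predict_instances(test_instances, model, kb,
                          word_vecs=data.word_vecs)
result = evaluate_micro(aggregate_document(preds), te.gold)
print(f"P {result.precision:.3f} R {result.recall:.3f} F1 {result.f1:.3f}")
# P 0.947 R 0.939 F1 0.943
```

The held-out micro-F1 of 0.943 says the classifier recovered nearly all
planted interacting pairs (recall 0.939) while rarely flagging
non-interacting ones (precision 0.947); on this corpus the signal is a
planted trigger word between interacting mentions plus KB membership of
the pair.

The same pipeline is scriptable from the shell:

```sh
memppi simulate --out sim --docs 300 --seed 3 --dim 32
memppi preprocess --docs sim/docs.pubtator --pairs sim/pairs.tsv \
    --mode train --out sim/instances.jsonl
memppi train-kb --triples sim/triples.tsv --word-vecs sim/vectors.txt \
    --dim 32 --epochs 50 --out sim/kb
memppi train --instances sim/instances.jsonl --kb sim/kb \
    --word-vecs sim/vectors.txt --variant mnm --layers 2 --dim 32 \
    --epochs 100 --out sim/model
memppi predict --instances sim/instances.jsonl --model sim/model \
    --word-vecs sim/vectors.txt --out sim/pred.tsv
memppi evaluate --gold sim/pairs.tsv --pred sim/pred.tsv
```

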