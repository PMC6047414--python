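# Methods

`memppi` extracts protein–protein interactions affected by mutations (PPIm)
from abstracts that carry protein-mention annotations normalized to Entrez
Gene IDs. Interactions are annotated at the *document* level as unordered
gene-ID pairs, so the pipeline works by distant labeling: every co-occurring
mention pair of two genes inherits the document label, is classified
independently, and the per-pair decisions are aggregated back to the
document level.

## Candidate generation

Documents are segmented with a deterministic rule (a sentence break after
`[.?!]` + whitespace when the next character is uppercase or a digit) and
tokenized by whitespace splitting with leading/trailing punctuation split
off; a multi-token mention surface is collapsed into a single token. A
mention pair becomes a candidate instance iff its sentence distance is
strictly less than 3 and its token distance lies strictly between 3 and 50.
The instance context is the token span between the pair plus three
expansion tokens on each side; the two pair mentions are removed, other
protein mentions become `gene0`, numeric tokens (`/^[0-9][0-9.,%]*$/`)
become `NUMBER`, special characters such as `*` are dropped, and tokens are
lowercased. Each context token keeps its token-count distance to either
mention slot, measured on the pre-removal token stream with a floor of 1.
Distances are measured between collapsed mention-head tokens *before*
removal; anchoring them after removal would make the 3 < d < 50 rule
self-referential.

## Knowledge representations (TransE)

PPI triples (h, r, t) from a KB export are embedded so that h + r ≈ t.
Training minimizes the margin ranking loss

    L = Σ max(0, γ + ‖h + r − t‖ − ‖h′ + r − t′‖)

over corruptions that replace the head or tail (probability 0.5 each) with
a uniform entity, resampled while the corruption is itself a known triple
(filtered sampling, capped at 100 draws). Entity vectors are initialized as
the average of the word vectors of the entity's mention words and
renormalized to unit L2 after every minibatch; relation vectors start from
N(0, 0.1) per component — order 1 against unit entities — and float free.
Defaults: γ = 1, L2 distance, learning rate 0.01, batch 512, 500 epochs
(desk scale; the toy KBs used in the tests converge in well under 100).

A pair-level relation embedding is the mean of the vectors of all relations
linking the unordered pair in the KB; pairs absent from the KB get the zero
vector. Entities absent from the KB fall back to averaged word vectors of
their mention. Out-of-vocabulary words draw a cached N(0, 0.01) vector
seeded by a hash of the word, so lookups agree between training and
prediction regardless of query order.

## The memory-network classifier

The masked context embeddings form the memory m ∈ R^{d×n}. Two networks —
one per entity — run K computational layers. At layer k (1-based), network
j rescales memory column i by the position-impact factor

    per_ik = (1 − p_i/n) − (k/d)(1 − 2 p_i/n)

with p_i the token distance to entity j's mention (clipped into [1, n]:
a flank token of an edge mention can be farther than n from the *other*
mention when the flank is truncated). It then scores each weighted column
against its query, g_i = tanh(Wa [m_i; e] + ba), normalizes by softmax,
pools v_att = Σ α_i m_i, and updates its query e′ = Wt e + v_att
(dimension-wise sum; the Max variant takes a dimension-wise maximum,
breaking ties toward the transformed query). The two networks share Wa,
ba, Wt at each layer; parameters are untied *across* layers. The final
queries, concatenated with the pair's relation embedding when enabled,
feed a 2-way softmax; prediction is the argmax with an exact tie going to
the negative class (a conservative precision bias for a low-prior
positive class).

Variants: `ae` (averaged-word entities, no relation vector), `te` (TransE
entities only), `ae_tr` (averaged-word entities + relation vector),
`mnm_da` (per-network attention parameters), `mnm_max` (max pooling),
`mnm_single` (one memory; both entity embeddings are concatenated to each
memory column, Wa ∈ R^{1×3d}, and the shared v_att updates both queries).
For the single-network variant the position factor is the mean of the two
per-entity factors, since a single memory cannot be rescaled per network;
its classifier input stays [e′₁; e′₂; e_relation] for comparability.

KB vectors (entity and relation) are frozen inputs by default.
`finetune_kb_vectors=True` promotes the per-gene entity vectors and
per-pair relation vectors that occur in the training set to trainable
tables; the gradient of a pair's relation vector is *not* redistributed
over the KB's shared relation-label vectors — each pair trains its own
copy — which keeps the option simple and the ablations clean.

## Training

Adam with learning rate 0.001 and batch size 100 on the mean cross-entropy
−(1/N) Σ log p(y_l | T_l), probabilities clamped at 1e-12 before the log.
Word embeddings are trainable (initialized from a word2vec-format table
when given, row 0 is a trained UNK); negatives are all candidate pairs
whose gene-ID pair is not in the document's gold set, at natural class
frequencies. Defaults: 60 epochs, no early stopping.

An L2 penalty (default 0.01) is applied to the weight matrices most able
to memorize — word embeddings, the layer transforms Wt, the classifier Ws —
but not to the (2d+1)-parameter attention scorer or the biases, so
attention stays free to sharpen onto informative tokens. A
document-grouped cross-validation harness (`tune_weight_decay`,
candidates {0.003, 0.01, 0.03}) is provided for selecting the penalty on
a new corpus. The built-in variant comparison deliberately does *not*
tune per variant: it pairs both models on the same corpus, KB and default
training configuration, so the measured difference isolates the prior
knowledge inputs rather than the tuning noise — single-fold dev estimates
at a few hundred instances proved noisy enough to occasionally select a
strong penalty that generalized erratically.

Initialization: Wa ~ N(0, 1/√(2d)), Wt ~ N(0, 1/√d), Ws ~ N(0, 1/√c),
biases zero. A random (rather than identity) Wt attenuates the raw entity
vector's path into the classifier; for entities absent from the KB that
vector is an arbitrary id-specific direction, and passing it through at
full magnitude measurably hurts generalization at small corpus sizes.

Decoding: per-instance argmax; a document-level (doc, pair) is positive
iff at least one of its instances is positive, scored by the maximum
instance probability.

## Post-processing and evaluation

The sentence-support rule emits a pair when *more than* N sentences of a
document each contain at least one mention of both genes (N = 2, strict
inequality). Rule and model positives are merged by set union on
(doc, unordered pair), keeping provenance model/rule/both. Evaluation is
micro-averaged Exact Match: TP/FP/FN pooled over all documents on
canonicalized gene-ID pairs, P = TP/(TP+FP), R = TP/(TP+FN),
F = 2PR/(P+R), each defined as 0 when its denominator is 0. Duplicate
predictions within a document are deduplicated with a warning.

## Synthetic data

The generator emulates the statistical structure the pipeline exploits, at
desk scale. Each document plants 2–3 mention-pair placements in 10–13
sentences of 8–14 Zipf-distributed filler tokens (120-word filler
vocabulary); a placement puts two gene mentions in one sentence at token
distance 5–12. A placement is interacting (gold) with probability 0.5;
interacting pairs receive one trigger token — drawn from an
interaction/mutation lexicon (*phosphorylation, mutant, binds, kinase,
interact, complex*) — in the between-span with probability 0.9 by default,
non-interacting placements at a background rate of 0.05. The KB covers
gold pairs at consistency ρ (default 0.9) under 5 PPI relation labels,
plus decoys over non-gold pairs at 0.1 per gold pair. Word vectors are
seeded random unit-norm vectors.

Two design constraints keep the planted signal identifiable rather than
accidental:

* placements within a document sit at least 3 sentences apart, so
  cross-placement mention pairs fail the sentence-distance rule and every
  candidate instance corresponds to exactly one placement — the distant
  document-level labels are then exact instance labels;
* the gene pool (240 genes) is large relative to the number of gold pairs,
  so a pair that is negative in one document is almost never gold in
  another — document labels and the global KB stay consistent, as in the
  real setting where the KB holds tens of thousands of entities. The
  corpus density and small filler vocabulary ensure every lexicon word is
  observed tens of times in a 200-document corpus, standing in for the
  pretrained-embedding regime of real pipelines.

What the generator does *not* emulate: real biomedical prose and syntax,
entity-recognition errors and their missed mentions, multi-sentence
relational phrasing, distribution shift between curated training data and
novel test articles, and homolog/identifier ambiguity. Passing the
end-to-end tests therefore certifies that the implementation recovers a
planted lexical + knowledge-base signal under distant supervision — not
that it would reach any particular score on real corpora.

## Problem sizes in the test suite and acceptance script

End-to-end studies use 200 training / 100 test documents (≈500/250
candidate instances), d = 32, K = 2, TransE for 50 epochs, classifier for
100 epochs; the prior-knowledge comparison averages five corpus seeds
under the paired default configuration. Link-prediction sanity uses a
20-entity / 3-relation / 60-triple cyclic KB whose filtered mean tail rank
is compared against the random-guess expectation (|E|+1)/2. Gradient
checks run at d = 4, n = 5, K = 2 against central finite differences
(relative 1e-4 with an absolute floor of 1e-7 for near-zero components).

## Known limitations

* The scalar per-word position factor follows the printed formula, where
  k is the layer number; the memory-network literature it descends from
  also used a variant indexed by embedding dimension. At K ≪ d the factor
  is nearly layer-independent.
* Strong weight decay (0.03) can trade attention sharpness for accuracy:
  classification then leans on the memory mean and the KB channel while
  the attention distribution flattens. The attention-dump analysis uses
  the default (0.01), where maximal attention lands on planted triggers
  in ≈98% of true positives.
* Distant labeling is taken at face value: every mention pair of a gold
  gene pair is a positive training instance, even occurrences whose local
  context does not express the interaction.
* `mean_rank_tails` ranks tails only; head-side ranking would require the
  symmetric scan and is omitted.
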