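import logging
import math

import numpy as np
import pytest

from memppi.knowledge import KnowledgeStore, TransEConfig, train_transe
from memppi.model import ModelConfig
from memppi.preprocessing import CandidateInstance, generate_instances
from memppi.training import (
    InstancePrediction,
    TrainConfig,
    aggregate_document,
    cross_entropy,
    crossval_folds,
    predict_instances,
    train,
)


class TestCrossEntropy:
    def test_uniform_predictions_give_ln2(self):
        probs = [[0.5, 0.5]] * 4
        assert cross_entropy(probs, [0, 1, 0, 1]) == pytest.approx(math.log(2))

    def test_perfect_predictions_give_zero(self):
        probs = [[1.0, 0.0], [0.0, 1.0]]
        assert cross_entropy(probs, [0, 1]) <= 1e-10

    def test_hand_computed_mean_nll(self):
        probs = [[0.9, 0.1], [0.2, 0.8], [0.6, 0.4]]
        labels = [0, 1, 1]
        expect = -(math.log(0.9) + math.log(0.8) + math.log(0.4)) / 3
        assert cross_entropy(probs, labels) == pytest.approx(expect)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy([[0.5, 0.5]], [0, 1])

    def test_zero_probability_is_clamped(self):
        assert np.isfinite(cross_entropy([[0.0, 1.0]], [0]))


@pytest.fixture(scope="module")
def tiny_study(small_sim):
    """Instances, KB store and word vectors from the shared small corpus."""
    data = small_sim
    kstore = train_transe(
        data.triples,
        TransEConfig(dim=16, epochs=20, seed=1),
        word_vecs=data.word_vecs,
        entity_words=data.entity_words,
    )
    instances = generate_instances(data.docs, data.mentions, data.gold)
    return data, kstore, instances


class TestTrain:
    def test_zero_epochs_returns_initialization(self, tiny_study):
        data, kstore, instances = tiny_study
        cfg = ModelConfig.variant("mnm", layers=2, dim=16, seed=4)
        a = train(instances, kstore, cfg, TrainConfig(epochs=0, seed=4),
                  word_vecs=data.word_vecs)
        b = train(instances, kstore, cfg, TrainConfig(epochs=0, seed=4),
                  word_vecs=data.word_vecs)
        assert a.loss_trace == []
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_loss_decreases_on_learnable_set(self, tiny_study):
        data, kstore, instances = tiny_study
        cfg = ModelConfig.variant("mnm", layers=2, dim=16, seed=4)
        mp = train(instances, kstore, cfg,
                   TrainConfig(epochs=15, seed=4), word_vecs=data.word_vecs)
        assert mp.loss_trace[-1] < mp.loss_trace[0]

    def test_same_seed_gives_identical_traces(self, tiny_study):
        data, kstore, instances = tiny_study
        cfg = ModelConfig.variant("mnm", layers=2, dim=16, seed=4)
        tcfg = TrainConfig(epochs=3, seed=9)
        a = train(instances, kstore, cfg, tcfg, word_vecs=data.word_vecs)
        b = train(instances, kstore, cfg, tcfg, word_vecs=data.word_vecs)
        assert a.loss_trace == b.loss_trace

    def test_single_class_training_warns_but_proceeds(self, tiny_study, caplog):
        data, kstore, instances = tiny_study
        pos_only = [i for i in instances if i.label == 1][:10]
        cfg = ModelConfig.variant("mnm", layers=1, dim=16, seed=4)
        with caplog.at_level(logging.WARNING, logger="memppi"):
            mp = train(pos_only, kstore, cfg, TrainConfig(epochs=1, seed=0),
                       word_vecs=data.word_vecs)
        assert any("single class" in r.message for r in caplog.records)
        assert len(mp.loss_trace) == 1

    def test_empty_training_set_rejected(self, tiny_study):
        _, kstore, _ = tiny_study
        with pytest.raises(ValueError):
            train([], kstore, ModelConfig(), TrainConfig())


@pytest.fixture(scope="module")
def trained(tiny_study):
    data, kstore, instances = tiny_study
    cfg = ModelConfig.variant("mnm", layers=2, dim=16, seed=4)
    mp = train(instances, kstore, cfg,
               TrainConfig(epochs=10, seed=4), word_vecs=data.word_vecs)
    return data, kstore, instances, mp


class TestPredict:
    def test_empty_input_gives_empty_output(self, trained):
        data, kstore, _, mp = trained
        assert predict_instances([], mp, kstore, word_vecs=data.word_vecs) == []

    def test_outputs_are_valid_probabilities_in_order(self, trained):
        data, kstore, instances, mp = trained
        preds = predict_instances(instances, mp, kstore, word_vecs=data.word_vecs)
        assert [p.doc_id for p in preds] == [i.doc_id for i in instances]
        for p in preds:
            assert 0.0 <= p.probability <= 1.0
            assert p.label in (0, 1)

    def test_invariant_to_batch_size(self, trained):
        data, kstore, instances, mp = trained
        a = predict_instances(instances, mp, kstore, word_vecs=data.word_vecs,
                              batch_size=1)
        b = predict_instances(instances, mp, kstore, word_vecs=data.word_vecs,
                              batch_size=7)
        c = predict_instances(instances, mp, kstore, word_vecs=data.word_vecs,
                              batch_size=1000)
        for x, y, z in zip(a, b, c):
            assert x.probability == pytest.approx(y.probability, abs=1e-12)
            assert y.probability == pytest.approx(z.probability, abs=1e-12)
            assert x.label == y.label == z.label


def ip(doc, pair, prob, label):
    return InstancePrediction(doc, pair, prob, label)


class TestAggregation:
    def test_any_positive_instance_flags_the_pair(self):
        preds = [
            ip("d1", ("A", "B"), 0.9, 1),
            ip("d1", ("A", "B"), 0.2, 0),
            ip("d1", ("A", "B"), 0.1, 0),
        ]
        recs = aggregate_document(preds)
        assert len(recs) == 1
        assert recs[0].score == pytest.approx(0.9)
        assert recs[0].source == "model"

    def test_all_negative_instances_drop_the_pair(self):
        preds = [ip("d1", ("A", "B"), 0.2, 0), ip("d1", ("A", "B"), 0.4, 0)]
        assert aggregate_document(preds) == []

    def test_matches_any_oracle_on_random_groups(self, rng):
        pairs = [("1", "2"), ("3", "4"), ("5", "6")]
        for _ in range(25):
            preds = []
            for doc in ("d1", "d2"):
                for pair in pairs:
                    for _ in range(int(rng.integers(1, 4))):
                        prob = float(rng.random())
                        preds.append(ip(doc, pair, prob, int(rng.random() < 0.3)))
            recs = aggregate_document(preds)
            got = {(r.doc_id, r.pair) for r in recs}
            expect = set()
            for p in preds:
                if p.label == 1:
                    expect.add((p.doc_id, p.pair))
            assert got == expect

    def test_monotone_under_instance_flips(self, rng):
        preds = [
            ip("d", ("A", "B"), 0.5, int(rng.random() < 0.5)) for _ in range(6)
        ]
        before = {(r.doc_id, r.pair) for r in aggregate_document(preds)}
        flipped = [ip(p.doc_id, p.pair, p.probability, 1) for p in preds[:1]] + preds[1:]
        after = {(r.doc_id, r.pair) for r in aggregate_document(flipped)}
        assert before <= after


class TestTuneWeightDecay:
    def test_selects_a_candidate_deterministically(self, tiny_study):
        from memppi.training import tune_weight_decay

        data, kstore, instances = tiny_study
        cfg = ModelConfig.variant("mnm", layers=1, dim=16, seed=4)
        tcfg = TrainConfig(epochs=3, seed=4)
        candidates = (0.003, 0.03)
        a = tune_weight_decay(instances, kstore, cfg, tcfg,
                              candidates=candidates, word_vecs=data.word_vecs)
        b = tune_weight_decay(instances, kstore, cfg, tcfg,
                              candidates=candidates, word_vecs=data.word_vecs)
        assert a in candidates
        assert a == b


class TestCrossval:
    def test_folds_partition_documents(self, tiny_study):
        _, _, instances = tiny_study
        folds = crossval_folds(instances, n_folds=5, seed=0)
        assert len(folds) == 5
        all_docs = {i.doc_id for i in instances}
        for fit, dev in folds:
            fit_docs = {i.doc_id for i in fit}
            dev_docs = {i.doc_id for i in dev}
            assert fit_docs | dev_docs == all_docs
            assert not (fit_docs & dev_docs)
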