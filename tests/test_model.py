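import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import loop_forward
from memppi.model import (
    BatchTensors,
    InstanceTensors,
    LayerParams,
    ModelConfig,
    ModelParams,
    attention,
    attention_weights,
    forward_batch,
    forward_instance,
    hop_update,
    init_params,
    loss_and_grads,
    position_percentage,
    predict_label,
    weight_memory,
)

VOCAB = {"<unk>": 0, "a": 1, "b": 2, "c": 3, "d": 4, "e": 5, "f": 6}


def random_model(variant, d=6, K=3, seed=0, **overrides):
    cfg = ModelConfig.variant(variant, dim=d, layers=K, seed=seed, **overrides)
    rng = np.random.default_rng(seed)
    mp = init_params(cfg, VOCAB, n_entities=4, n_relations=3, rng=rng)
    mp.params["ent"] = rng.normal(0, 1, (4, d))
    mp.params["rel"] = rng.normal(0, 1, (3, d))
    return mp, rng


def random_instance(rng, d=6, n=7):
    return InstanceTensors(
        m=rng.normal(0, 1, (d, n)),
        dist1=rng.integers(1, n + 1, n).astype(float),
        dist2=rng.integers(1, n + 1, n).astype(float),
        e1=rng.normal(0, 1, d),
        e2=rng.normal(0, 1, d),
        rel=rng.normal(0, 1, d),
    )


class TestPositionPercentage:
    def test_direct_evaluation(self):
        assert position_percentage(2, 10, 1, 100) == pytest.approx(0.794)

    @pytest.mark.parametrize("k,d", [(1, 100), (3, 100), (2, 8)])
    def test_midpoint_symmetry(self, k, d):
        # p/n = 0.5 kills the layer-dependent term
        assert position_percentage(5, 10, k, d) == pytest.approx(0.5)

    @pytest.mark.parametrize("k,d", [(1, 100), (4, 50)])
    def test_boundary_p_equals_n(self, k, d):
        assert position_percentage(10, 10, k, d) == pytest.approx(k / d)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            position_percentage(1, 0, 1, 10)


class TestWeightMemory:
    def test_matches_columnwise_oracle(self, rng):
        d, n, k = 5, 9, 2
        m = rng.normal(0, 1, (d, n))
        dists = rng.integers(1, n + 2, n)  # may exceed n; clipped
        out = weight_memory(m, dists, k, 100)
        for i in range(n):
            p = min(max(dists[i], 1), n)
            per = (1 - p / n) - (k / 100) * (1 - 2 * p / n)
            np.testing.assert_allclose(out[:, i], m[:, i] * per)


class TestAttention:
    def test_scalar_hand_computation(self):
        layer = LayerParams(wa=np.array([1.0, 1.0]), ba=0.0, wt=np.eye(1))
        m = np.array([[0.5, -0.5]])
        alpha, v = attention(m, np.array([0.5]), layer)
        g1, g2 = math.tanh(1.0), math.tanh(0.0)
        a1 = math.exp(g1) / (math.exp(g1) + math.exp(g2))
        assert alpha[0] == pytest.approx(a1)
        assert v[0] == pytest.approx(a1 * 0.5 + (1 - a1) * -0.5)

    def test_equal_scores_give_uniform_weights(self, rng):
        d, n = 4, 6
        layer = LayerParams(
            wa=np.concatenate([np.zeros(d), rng.normal(0, 1, d)]),
            ba=0.3,
            wt=np.eye(d),
        )
        alpha, _ = attention(rng.normal(0, 1, (d, n)), rng.normal(0, 1, d), layer)
        np.testing.assert_allclose(alpha, np.full(n, 1 / n))

    def test_weights_sum_to_one(self, rng):
        for _ in range(20):
            d, n = 3, int(rng.integers(1, 12))
            layer = LayerParams(wa=rng.normal(0, 2, 2 * d), ba=float(rng.normal()), wt=np.eye(d))
            alpha, _ = attention(rng.normal(0, 1, (d, n)), rng.normal(0, 1, d), layer)
            assert abs(alpha.sum() - 1.0) < 1e-9

    def test_empty_memory_rejected(self):
        layer = LayerParams(wa=np.ones(2), ba=0.0, wt=np.eye(1))
        with pytest.raises(ValueError):
            attention(np.zeros((1, 0)), np.zeros(1), layer)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(-30, 30), min_size=1, max_size=20),
        st.floats(-100, 100),
    )
    def test_normalization_is_shift_invariant(self, scores, c):
        a = attention_weights(np.array(scores))
        b = attention_weights(np.array(scores) + c)
        assert np.allclose(a, b, atol=1e-9)
        assert a.sum() == pytest.approx(1.0)


class TestHopUpdate:
    def test_identity_transform_zero_memory(self, rng):
        e = rng.normal(0, 1, 5)
        layer = LayerParams(wa=np.zeros(10), ba=0.0, wt=np.eye(5))
        np.testing.assert_allclose(hop_update(e, np.zeros(5), layer, "sum"), e)

    def test_max_dominates_both_arguments(self, rng):
        e, v = rng.normal(0, 1, 5), rng.normal(0, 1, 5)
        layer = LayerParams(wa=np.zeros(10), ba=0.0, wt=rng.normal(0, 1, (5, 5)))
        out = hop_update(e, v, layer, "max")
        assert np.all(out >= layer.wt @ e) and np.all(out >= v)

    def test_matches_coordinate_oracle(self, rng):
        e, v = rng.normal(0, 1, 4), rng.normal(0, 1, 4)
        layer = LayerParams(wa=np.zeros(8), ba=0.0, wt=rng.normal(0, 1, (4, 4)))
        s = hop_update(e, v, layer, "sum")
        m = hop_update(e, v, layer, "max")
        for i in range(4):
            row = sum(layer.wt[i, j] * e[j] for j in range(4))
            assert s[i] == pytest.approx(row + v[i])
            assert m[i] == pytest.approx(max(row, v[i]))


class TestForward:
    def test_zero_parameters_give_uniform_probability(self):
        mp, rng = random_model("mnm", d=4, K=2)
        for k in mp.params:
            mp.params[k] = np.zeros_like(mp.params[k])
        inst = random_instance(rng, d=4, n=5)
        prob, _ = forward_instance(inst, mp)
        np.testing.assert_allclose(prob, [0.5, 0.5])

    def test_single_hop_equals_manual_composition(self):
        mp, rng = random_model("mnm", d=5, K=1)
        inst = random_instance(rng, d=5, n=6)
        prob, _ = forward_instance(inst, mp)
        lp = mp.layer(0)
        mw1 = weight_memory(inst.m, inst.dist1, 1, 5)
        mw2 = weight_memory(inst.m, inst.dist2, 1, 5)
        _, v1 = attention(mw1, inst.e1, lp)
        _, v2 = attention(mw2, inst.e2, lp)
        q1 = hop_update(inst.e1, v1, lp, "sum")
        q2 = hop_update(inst.e2, v2, lp, "sum")
        logits = mp.params["ws"] @ np.concatenate([q1, q2, inst.rel]) + mp.params["bs"]
        expect = np.exp(logits - logits.max())
        expect /= expect.sum()
        np.testing.assert_allclose(prob, expect, atol=1e-12)

    def test_permuting_memory_leaves_output_unchanged(self):
        mp, rng = random_model("mnm", d=4, K=3)
        inst = random_instance(rng, d=4, n=8)
        prob, _ = forward_instance(inst, mp)
        perm = rng.permutation(8)
        inst_p = InstanceTensors(
            m=inst.m[:, perm],
            dist1=inst.dist1[perm],
            dist2=inst.dist2[perm],
            e1=inst.e1,
            e2=inst.e2,
            rel=inst.rel,
        )
        prob_p, _ = forward_instance(inst_p, mp)
        np.testing.assert_allclose(prob, prob_p, atol=1e-12)

    def test_shared_attention_swap_symmetry(self):
        """Swapping entities together with their distances swaps the final
        queries exactly when the two networks share parameters."""
        mp, rng = random_model("mnm", d=4, K=3)
        inst = random_instance(rng, d=4, n=6)
        swapped = InstanceTensors(
            m=inst.m, dist1=inst.dist2, dist2=inst.dist1,
            e1=inst.e2, e2=inst.e1, rel=inst.rel,
        )

        def final_queries(x):
            q1, q2 = x.e1.copy(), x.e2.copy()
            for k in range(mp.cfg.layers):
                lp = mp.layer(k)
                mw1 = weight_memory(x.m, x.dist1, k + 1, 4)
                mw2 = weight_memory(x.m, x.dist2, k + 1, 4)
                _, v1 = attention(mw1, q1, lp)
                _, v2 = attention(mw2, q2, lp)
                q1, q2 = hop_update(q1, v1, lp), hop_update(q2, v2, lp)
            return q1, q2

        q1, q2 = final_queries(inst)
        s1, s2 = final_queries(swapped)
        np.testing.assert_allclose(q1, s2, atol=1e-12)
        np.testing.assert_allclose(q2, s1, atol=1e-12)

    @pytest.mark.parametrize(
        "variant", ["mnm", "ae", "mnm_da", "mnm_max", "mnm_single"]
    )
    def test_matches_loop_reference(self, variant):
        """Vectorized forward equals an independent scalar-loop reference."""
        mp, rng = random_model(variant, d=6, K=3, seed=8)
        for i in range(10):
            inst = random_instance(rng, d=6, n=int(rng.integers(1, 12)))
            prob, _ = forward_instance(inst, mp)
            ref = loop_forward(inst, mp)
            np.testing.assert_allclose(prob, ref, atol=1e-10)

    def test_attention_weights_normalized_every_layer(self):
        mp, rng = random_model("mnm", d=5, K=4)
        for _ in range(10):
            inst = random_instance(rng, d=5, n=int(rng.integers(1, 10)))
            _, att = forward_instance(inst, mp, collect_attention=True)
            assert len(att) == 2 * mp.cfg.layers
            for _, _, alpha in att:
                assert abs(alpha.sum() - 1.0) < 1e-9


class TestPredictLabel:
    @pytest.mark.parametrize(
        "prob,label", [((0.7, 0.3), 0), ((0.3, 0.7), 1), ((0.5, 0.5), 0)]
    )
    def test_argmax_with_negative_tie_break(self, prob, label):
        assert predict_label(np.array(prob)) == label


def make_batch(rng, mp, B=3, N=5):
    d = mp.cfg.dim
    tok = rng.integers(1, len(VOCAB), (B, N))
    mask = np.ones((B, N))
    mask[1, N - 1] = 0
    if B > 2:
        mask[2, N - 2 :] = 0
    nlen = mask.sum(axis=1).astype(np.int64)
    return BatchTensors(
        tok=tok,
        mask=mask,
        nlen=nlen,
        dist1=rng.integers(1, N + 1, (B, N)).astype(float),
        dist2=rng.integers(1, N + 1, (B, N)).astype(float),
        e1=rng.integers(0, 4, B),
        e2=rng.integers(0, 4, B),
        rel=rng.integers(0, 3, B),
        y=rng.integers(0, 2, B),
    )


class TestGradients:
    @pytest.mark.parametrize(
        "variant,finetune",
        [
            ("mnm", False),
            ("ae", False),
            ("mnm_da", False),
            ("mnm_max", False),
            ("mnm_single", False),
            ("mnm", True),
        ],
    )
    def test_analytic_matches_finite_differences(self, variant, finetune):
        """Every trainable tensor's gradient agrees with central differences
        on a d=4, n=5, K=2 batch (relative 1e-4, absolute floor 1e-7 for
        near-zero components)."""
        mp, rng = random_model(variant, d=4, K=2, seed=1, finetune_kb_vectors=finetune)
        batch = make_batch(rng, mp, B=3, N=5)
        _, grads, _ = loss_and_grads(mp, batch)
        eps = 1e-6
        for key in mp.trainable_keys():
            P = mp.params[key]
            it = np.nditer(P, flags=["multi_index"])
            count = 0
            while not it.finished and count < 25:
                ij = it.multi_index
                orig = P[ij]
                P[ij] = orig + eps
                lp, _, _ = loss_and_grads(mp, batch)
                P[ij] = orig - eps
                lm, _, _ = loss_and_grads(mp, batch)
                P[ij] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[key][ij]
                rel = abs(num - ana) / max(abs(num) + abs(ana), 1e-8)
                assert rel < 1e-4 or abs(num - ana) < 1e-7, (key, ij, num, ana)
                count += 1
                it.iternext()


class TestBatching:
    @pytest.mark.parametrize("variant", ["mnm", "mnm_max", "mnm_single", "mnm_da"])
    def test_padded_batch_equals_per_instance_forward(self, variant):
        mp, rng = random_model(variant, d=5, K=2, seed=2)
        batch = make_batch(rng, mp, B=3, N=6)
        probs, _ = forward_batch(mp, batch)
        emb = mp.params["emb"]
        for b in range(3):
            n = int(batch.nlen[b])
            inst = InstanceTensors(
                m=emb[batch.tok[b, :n]].T,
                dist1=batch.dist1[b, :n],
                dist2=batch.dist2[b, :n],
                e1=mp.params["ent"][batch.e1[b]],
                e2=mp.params["ent"][batch.e2[b]],
                rel=mp.params["rel"][batch.rel[b]],
            )
            prob, _ = forward_instance(inst, mp)
            np.testing.assert_allclose(probs[b], prob, atol=1e-10)


class TestModelParamsIO:
    def test_save_load_roundtrip(self, tmp_path):
        mp, _ = random_model("mnm_da", d=4, K=2)
        mp.ent_index = {"7157": 0}
        mp.rel_index = {"4193|7157": 0}
        mp.loss_trace = [0.7, 0.5]
        mp.save(tmp_path / "model")
        back = ModelParams.load(tmp_path / "model")
        assert back.cfg == mp.cfg
        assert back.vocab == mp.vocab
        assert back.ent_index == mp.ent_index
        assert back.loss_trace == mp.loss_trace
        for k in mp.params:
            np.testing.assert_array_equal(back.params[k], mp.params[k])
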