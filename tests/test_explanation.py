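"""Exemplar synthesis, saliency and the end-to-end explanation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from latexpl import (DecisionRule, ExplainConfig, Explanation,
                     PremiseCondition, compute_saliency, explain,
                     generate_counter_exemplars, generate_exemplars,
                     select_counter_exemplar)

K = 6


class StubModel:
    latent_dim = K

    def decode(self, Z):
        Z = np.atleast_2d(Z)
        img = np.zeros((len(Z), 4, 4, 3))
        img.reshape(len(Z), -1)[:, :K] = Z
        return img

    def discriminate(self, Z):
        return np.full(len(np.atleast_2d(Z)), 0.9)


class SignBB:
    """class 1 iff latent coordinate 0 (read from the image) > 0."""

    classes_ = np.array([0, 1])

    def predict(self, images):
        z0 = np.asarray(images).reshape(len(images), -1)[:, 0]
        p1 = 1 / (1 + np.exp(-4 * z0))
        return (z0 > 0).astype(int), np.column_stack([1 - p1, p1])


class Label0BB:
    classes_ = np.array([0, 1])

    def predict(self, images):
        n = len(images)
        return np.zeros(n, dtype=int), np.tile([1.0, 0.0], (n, 1))


class TestGenerateExemplars:
    def test_degenerate_rule_returns_immediately(self):
        # empty-premise rule + constant label-0 black box: every draw
        # qualifies, so exactly n_ex exemplars come back
        rule = DecisionRule((), 0)
        out = generate_exemplars(StubModel(), Label0BB(), rule,
                                 np.zeros(K), n_ex=5, seed=1)
        assert len(out) == 5

    def test_labels_and_premises_respected(self):
        rule = DecisionRule((PremiseCondition(0, ">", 0.0),), 1)
        model, bb = StubModel(), SignBB()
        out = generate_exemplars(model, bb, rule, np.full(K, 0.5),
                                 n_ex=6, seed=2)
        labels, _ = bb.predict(out)
        assert (labels == 1).all()
        # generating latents are embedded in the stub images
        lat = out.reshape(len(out), -1)[:, :K]
        assert (lat[:, 0] > 0.0).all()

    def test_budget_exhaustion_warns(self):
        # rule requires coord 0 > 0 but the black box always says 0
        rule = DecisionRule((PremiseCondition(0, ">", 0.0),), 1)
        with pytest.warns(RuntimeWarning):
            out = generate_exemplars(StubModel(), Label0BB(), rule,
                                     np.zeros(K), n_ex=3, seed=0,
                                     budget_factor=2)
        assert len(out) < 3

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            generate_exemplars(StubModel(), SignBB(), DecisionRule((), 0),
                               np.zeros(K), n_ex=0, seed=0)


class TestGenerateCounterExemplars:
    def test_latents_satisfy_their_rule(self):
        phi = [DecisionRule((PremiseCondition(0, "<=", 0.0),), 0)]
        model, bb = StubModel(), SignBB()
        lat, img, p = generate_counter_exemplars(
            model, bb, phi, np.full(K, 0.5), n_ce=4, seed=3)
        assert all(phi[0].satisfied_by(h) for h in lat)
        labels, _ = bb.predict(img)
        assert (labels == 0).all()

    def test_empty_phi_rejected(self):
        with pytest.raises(ValueError):
            generate_counter_exemplars(StubModel(), SignBB(), [],
                                       np.zeros(K), n_ce=1, seed=0)


class TestSelectCounterExemplar:
    def test_singleton(self, rng):
        img = rng.random((1, 4, 4, 3))
        out = select_counter_exemplar(np.zeros((1, K)), img,
                                      np.array([[0.3, 0.7]]),
                                      np.zeros(K), y_x=0)
        np.testing.assert_array_equal(out, img[0])

    def test_distance_tie_broken_by_alt_probability(self):
        lat = np.array([[1.0, 0, 0, 0, 0, 0], [0, 1.0, 0, 0, 0, 0]])
        imgs = np.stack([np.zeros((2, 2, 3)), np.ones((2, 2, 3))])
        probs = np.array([[0.6, 0.4], [0.2, 0.8]])
        out = select_counter_exemplar(lat, imgs, probs, np.zeros(K), y_x=0)
        np.testing.assert_array_equal(out, imgs[1])

    def test_matches_brute_force_sort(self, rng):
        lat = rng.normal(0, 1, (10, K))
        imgs = rng.random((10, 3, 3, 3))
        probs = rng.dirichlet([1, 1, 1], size=10)
        z = rng.normal(0, 1, K)
        out = select_counter_exemplar(lat, imgs, probs, z, y_x=1)
        d = np.linalg.norm(lat - z, axis=1)
        alt = probs.copy()
        alt[:, 1] = -np.inf
        ranked = sorted(range(10), key=lambda i: (d[i], -alt[i].max()))
        np.testing.assert_array_equal(out, imgs[ranked[0]])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_counter_exemplar(np.empty((0, K)), np.empty((0, 2, 2, 3)),
                                    np.empty((0, 2)), np.zeros(K), 0)


class TestComputeSaliency:
    def test_identical_exemplars_give_zero(self, rng):
        x = rng.random((5, 5, 3))
        s = compute_saliency(x, np.stack([x, x, x]))
        np.testing.assert_array_equal(s, np.zeros((5, 5)))

    def test_single_exemplar_is_difference(self, rng):
        x = rng.random((4, 4, 3))
        h = rng.random((4, 4, 3))
        np.testing.assert_allclose(compute_saliency(x, h[None]),
                                   (x - h).mean(axis=-1), atol=1e-12)

    def test_three_exemplar_toy_median(self):
        x = np.array([[[1.0], [0.5]], [[0.0], [0.25]]])  # 2x2x1
        hs = np.stack([x - 0.1, x + 0.3, x + 0.1])
        s = compute_saliency(x, hs)
        for i in range(2):
            for j in range(2):
                diffs = sorted([x[i, j, 0] - h[i, j, 0] for h in hs])
                assert s[i, j] == pytest.approx(diffs[1], abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            compute_saliency(rng.random((4, 4, 3)),
                             rng.random((2, 5, 5, 3)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(hnp.arrays(float, (3, 4, 4, 3),
                      elements=st.floats(0, 1, width=32)))
    def test_median_property_on_random_stacks(self, stack):
        x = stack[0]
        s = compute_saliency(x, stack)
        brute = np.median(x[None] - stack, axis=0).mean(axis=-1)
        np.testing.assert_allclose(s, brute, atol=1e-12)


class TestExplanationSerialization:
    def test_json_roundtrip(self, rng):
        exp = Explanation(
            rule=DecisionRule((PremiseCondition(7, ">", -1.01),), 1),
            counter_rules=[DecisionRule((PremiseCondition(7, "<=", -1.01),),
                                        0)],
            exemplars=rng.random((2, 4, 4, 3)).round(6),
            counter_exemplars=rng.random((1, 4, 4, 3)).round(6),
            saliency=rng.normal(0, 1, (4, 4)).round(6),
            neighborhood_counts={0: 41, 1: 59},
            label=1, fidelity=0.93)
        back = Explanation.from_json(exp.to_json())
        assert back.rule == exp.rule
        assert back.counter_rules == exp.counter_rules
        np.testing.assert_allclose(back.exemplars, exp.exemplars)
        np.testing.assert_allclose(back.saliency, exp.saliency)
        assert back.neighborhood_counts == exp.neighborhood_counts
        assert back.label == exp.label


class TestEndToEnd:
    @pytest.fixture(scope="class")
    def one_explanation(self, desk_model, toy_bb, heldout):
        x = heldout.images[0]
        cfg = ExplainConfig(n_neighborhood=60)
        return x, explain(x, toy_bb, desk_model, cfg, seed=5)

    def test_explanation_invariants(self, one_explanation, toy_bb):
        x, exp = one_explanation
        assert exp.saliency.shape == x.shape[:2]
        labels, _ = toy_bb.predict(exp.exemplars)
        assert (labels == exp.label).all()
        if len(exp.counter_exemplars):
            clabels, _ = toy_bb.predict(exp.counter_exemplars)
            assert (clabels != exp.label).all()
        assert sum(exp.neighborhood_counts.values()) > 0

    def test_deterministic_rerun(self, desk_model, toy_bb, heldout):
        x = heldout.images[1]
        cfg = ExplainConfig(n_neighborhood=40, n_exemplars=2,
                            n_counter_exemplars=1)
        e1 = explain(x, toy_bb, desk_model, cfg, seed=17)
        e2 = explain(x, toy_bb, desk_model, cfg, seed=17)
        assert e1.rule == e2.rule
        np.testing.assert_array_equal(e1.saliency, e2.saliency)
        np.testing.assert_array_equal(e1.exemplars, e2.exemplars)
        assert e1.neighborhood_counts == e2.neighborhood_counts
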