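"""Objective components: analytic identities, componentwise oracle,
reduction to the baseline, and gradient flow through the regularizers."""

import numpy as np
import pytest

from ggnes import (AtlasGraph, ClassExplanationLabel, GlobalExplanation,
                   GraphDataset, LossWeights, consistency_regularizer,
                   explanation_distance, explanation_loss, sparsity_regularizer,
                   total_objective, train_baseline, train_ggnes)
from ggnes import autodiff as ad
from ggnes.training import TrainConfig


class TestDistance:
    def test_identical_inputs_give_zero(self, rng):
        v = rng.random(7)
        assert explanation_distance(v, v, "absolute") == 0.0
        assert explanation_distance(v, v, "squared") == 0.0

    def test_hand_cases(self):
        assert explanation_distance(np.array([1.0, 0.0]), np.array([0.0, 1.0]),
                                    "absolute") == 1.0
        assert explanation_distance(np.array([1.0, 0.0]), np.array([0.0, 1.0]),
                                    "squared") == 1.0
        assert explanation_distance(np.array([1.0, 0, 0, 0]), np.zeros(4),
                                    "absolute") == 0.25

    def test_shape_mismatch_and_bad_kind(self):
        with pytest.raises(ValueError, match="shape"):
            explanation_distance(np.zeros(2), np.zeros(3))
        with pytest.raises(ValueError, match="kind"):
            explanation_distance(np.zeros(2), np.zeros(2), "cosine")


class TestConsistency:
    def test_constant_node_explanation_gives_zero(self, rng):
        e = rng.random((4, 4))
        a = rng.random((2, 4, 4))
        assert consistency_regularizer(np.full(4, 0.3), e, a) == 0.0

    def test_two_node_hand_case(self):
        a = np.array([[[0.0, 1.0], [1.0, 0.0]]])
        e = np.array([[0.0, 1.0], [1.0, 0.0]])
        m = np.array([0.0, 1.0])
        # ordered pairs (0,1) and (1,0): 2 * (1*1*1) / (2*4) = 0.25
        assert consistency_regularizer(m, e, a) == pytest.approx(0.25, abs=1e-12)

    def test_duplicated_samples_average_to_same_value(self, rng):
        a1 = rng.random((1, 5, 5))
        m, e = rng.random(5), rng.random((5, 5))
        one = consistency_regularizer(m, e, a1)
        two = consistency_regularizer(m, e, np.concatenate([a1, a1]))
        assert one == pytest.approx(two, rel=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="empty class"):
            consistency_regularizer(np.zeros(3), np.zeros((3, 3)),
                                    np.zeros((0, 3, 3)))

    def test_nonnegative_on_random_inputs(self, rng):
        for _ in range(20):
            val = consistency_regularizer(rng.random(6), rng.random((6, 6)),
                                          rng.random((3, 6, 6)))
            assert val >= 0.0


class TestSparsity:
    def test_zeros_give_zero(self):
        assert sparsity_regularizer(np.zeros(4), np.zeros((4, 4))) == 0.0

    def test_all_ones_node_vector(self):
        assert sparsity_regularizer(np.ones(4), np.zeros((4, 4))) == 1.0

    def test_two_edge_entries(self):
        e = np.zeros((2, 2))
        e[0, 1] = e[1, 0] = 1.0
        assert sparsity_regularizer(np.zeros(2), e) == 0.5


class TestExplanationLoss:
    def _globals(self, node, edge=None):
        g = GlobalExplanation(normalized=True)
        g.node = node
        g.edge = edge or {}
        return g

    def test_perfect_match_is_zero(self):
        mask = np.array([1.0, 0.0, 1.0])
        labels = ClassExplanationLabel(node_mask={0: mask})
        assert explanation_loss(self._globals({0: mask}), labels, LossWeights()) == 0.0

    def test_node_only_class_skips_edge_term(self):
        labels = ClassExplanationLabel(node_mask={0: np.array([0.0, 1.0])})
        g = self._globals({0: np.array([1.0, 0.0])}, {0: np.ones((2, 2)) - np.eye(2)})
        w = LossWeights(alpha_n=1, alpha_e=1)
        assert explanation_loss(g, labels, w) == pytest.approx(1.0)

    def test_doubling_alpha_n_doubles_node_only_loss(self):
        labels = ClassExplanationLabel(node_mask={0: np.array([0.0, 1.0])})
        g = self._globals({0: np.array([1.0, 0.0])})
        l1 = explanation_loss(g, labels, LossWeights(alpha_n=1, alpha_e=0))
        l2 = explanation_loss(g, labels, LossWeights(alpha_n=2, alpha_e=0))
        assert l2 == pytest.approx(2 * l1)

    def test_no_annotation_warns_and_returns_zero(self):
        labels = ClassExplanationLabel()
        with pytest.warns(UserWarning, match="no annotated class"):
            assert explanation_loss(self._globals({}), labels, LossWeights()) == 0.0


def _toy_dataset():
    """2 samples, N=2, one class each."""
    a0 = np.array([[0.0, 1.0], [1.0, 0.0]])
    a1 = np.array([[0.0, 0.3], [0.3, 0.0]])
    x = np.array([[1.0, 0.5], [0.2, 1.0]])
    samples = [AtlasGraph(a0, x, 0, "a"), AtlasGraph(a1, x, 1, "b")]
    labels = ClassExplanationLabel(
        node_mask={0: np.array([1.0, 0.0]), 1: np.array([0.0, 1.0])},
        edge_mask={0: a0.copy(), 1: a0.copy()})
    return GraphDataset(samples, 2), labels


class TestTotalObjective:
    def test_zero_weights_reduce_to_mean_cross_entropy(self, small_dataset):
        from ggnes.backbone import BackboneParams, cross_entropy, forward_tensors

        dataset, masks = small_dataset
        params = BackboneParams.init(dataset.d_in, dataset.n_classes, seed=0)
        cfg = TrainConfig(weights=LossWeights(0, 0, 0, 0))
        loss, comp = total_objective(params, dataset, masks, cfg)
        _, _, logits = forward_tensors(ad.tensor(dataset.adjacency_stack()),
                                       ad.tensor(dataset.feature_stack()), params)
        ce = cross_entropy(logits, dataset.labels())
        assert loss.item() == pytest.approx(ce.item(), abs=1e-12)
        assert "L_att_node" not in comp

    def test_components_match_independent_recomputation(self):
        """Every objective component re-derived with detached numpy pieces."""
        from ggnes.aggregation import normalize_explanation
        from ggnes.backbone import BackboneParams, predict_proba
        from ggnes.training import _class_globals

        dataset, labels = _toy_dataset()
        params = BackboneParams.init(2, 2, hidden_dims=(3, 3), seed=2)
        w = LossWeights(alpha_n=1.0, alpha_e=0.7, beta=0.4, gamma=0.2)
        cfg = TrainConfig(weights=w)
        loss, comp = total_objective(params, dataset, labels, cfg)

        probs = predict_proba(params, dataset)
        ce = -np.log(probs[np.arange(2), dataset.labels()]).mean()

        node_t, edge_t = _class_globals(params, dataset, cfg, True, True,
                                        create_graph=False)
        expected = ce
        for c in (0, 1):
            m_c = np.asarray(normalize_explanation(node_t[c].data))
            e_c = np.asarray(normalize_explanation(edge_t[c].data))
            expected += w.alpha_n * np.abs(m_c - labels.node_mask[c]).mean()
            expected += w.alpha_e * np.abs(e_c - labels.edge_mask[c]).mean()
            idx = dataset.indices_of_class(c)
            expected += w.beta * consistency_regularizer(
                m_c, e_c, dataset.adjacency_stack()[idx])
            expected += w.gamma * sparsity_regularizer(m_c, e_c)
        assert loss.item() == pytest.approx(expected, abs=1e-10)

    def test_consistency_weight_changes_backbone_gradient(self):
        """The consistency term feeds back into the weights (autodiff probe)."""
        from ggnes.backbone import BackboneParams

        dataset, labels = _toy_dataset()
        params = BackboneParams.init(2, 2, hidden_dims=(3, 3), seed=1)
        grads = {}
        for beta in (0.0, 1.0):
            cfg = TrainConfig(weights=LossWeights(0, 0, beta, 0))
            loss, _ = total_objective(params, dataset, labels, cfg)
            grads[beta] = np.concatenate(
                [g.data.ravel() for g in ad.grad(loss, params.trainable())])
        assert not np.allclose(grads[0.0], grads[1.0])


class TestReduction:
    def test_zero_weight_training_reproduces_staged_baseline(self, small_dataset):
        """train_ggnes with all explanation weights 0 is bit-identical to
        baseline training followed by a fresh-optimizer fine-tune."""
        dataset, masks = small_dataset
        cfg = TrainConfig(mode="avg", weights=LossWeights(0, 0, 0, 0),
                          epochs=40, supervised_epochs=25, seed=3)
        state = train_ggnes(dataset, masks, cfg)
        p1, _ = train_baseline(dataset, epochs=40, seed=3)
        p2, _ = train_baseline(dataset, epochs=25, seed=3, params=p1)
        for a, b in zip(state.backbone.trainable(), p2.trainable()):
            assert np.array_equal(a.data, b.data)
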