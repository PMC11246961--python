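"""Saliency correctness: finite-difference oracles, symmetry, equivariance,
nonnegativity, and the differentiability contract."""

import numpy as np
import pytest

from ggnes import AtlasGraph, local_edge_explanation, local_node_explanation
from ggnes import autodiff as ad
from ggnes.backbone import BackboneParams
from ggnes.explainers import batch_saliency, default_layer
from helpers import (fd_logit_grad_wrt_adj, fd_logit_grad_wrt_layer,
                     random_graph, stable_fd)


def _graph(rng, n):
    g = random_graph(rng, n)
    return g, AtlasGraph(g["adj"], g["x"], 0, "t")


class TestGradientOracles:
    @pytest.mark.parametrize("trial", range(10))
    def test_node_gradients_match_finite_differences(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(4, 7))
        params = BackboneParams.init(2, 2, hidden_dims=(5, 4), seed=trial)
        g, graph = _graph(rng, n)
        layer, c = 1, int(rng.integers(0, 2))
        fd, ok = stable_fd(fd_logit_grad_wrt_layer, g, params, layer, c)
        fd[~ok] = 0.0  # exclude entries whose FD stencil straddles a kink
        expected = np.sqrt((np.maximum(fd, 0.0) ** 2).sum(axis=1))
        got = local_node_explanation(params, graph, c, layer=layer).node_scores
        rows = ok.all(axis=1)
        hot = rows & (expected > 1e-6)
        assert np.allclose(got[hot], expected[hot], rtol=1e-3)
        cold = rows & ~hot
        assert np.allclose(got[cold], expected[cold], atol=1e-5)

    @pytest.mark.parametrize("trial", range(10))
    def test_edge_gradients_match_finite_differences(self, trial):
        rng = np.random.default_rng(200 + trial)
        n = int(rng.integers(4, 7))
        params = BackboneParams.init(2, 2, hidden_dims=(5, 4), seed=trial + 50)
        g, graph = _graph(rng, n)
        c = int(rng.integers(0, 2))
        fd, ok = stable_fd(fd_logit_grad_wrt_adj, g, params, c)  # directed
        ok = ok & ok.T  # both directions must be kink-free
        expected = (np.maximum(fd, 0) + np.maximum(fd.T, 0)) / 2.0
        np.fill_diagonal(expected, 0.0)
        got = local_edge_explanation(params, graph, c).edge_scores
        hot = ok & (expected > 1e-6)
        assert np.allclose(got[hot], expected[hot], rtol=1e-3)
        cold = ok & ~hot & ~np.eye(n, dtype=bool)
        assert np.allclose(got[cold], expected[cold], atol=1e-5)

    def test_symmetric_fd_perturbation_equals_twice_symmetrized_score(self):
        """Perturbing (n,m) and (m,n) together gives g_nm + g_mn."""
        rng = np.random.default_rng(7)
        params = BackboneParams.init(2, 2, hidden_dims=(5, 4), seed=3)
        g, graph = _graph(rng, 5)
        fd = fd_logit_grad_wrt_adj(g, params, 0)
        got = local_edge_explanation(params, graph, 0).edge_scores
        n, m = 1, 3
        if fd[n, m] > 1e-6 and fd[m, n] > 1e-6:  # both directions positive
            sym_fd = fd[n, m] + fd[m, n]
            assert np.isclose(2 * got[n, m], sym_fd, rtol=1e-3)


class TestStructure:
    @pytest.mark.parametrize("method", ["gradient", "guided_bp", "grad_cam"])
    def test_scores_nonnegative_and_edge_symmetric(self, method, rng, tiny_params):
        g, graph = _graph(rng, 6)
        node = local_node_explanation(tiny_params, graph, 1, method=method)
        edge = local_edge_explanation(tiny_params, graph, 1, method=method)
        assert node.node_scores.min() >= 0
        assert edge.edge_scores.min() >= 0
        assert np.array_equal(edge.edge_scores, edge.edge_scores.T)
        assert np.all(np.diag(edge.edge_scores) == 0)

    @pytest.mark.parametrize("method", ["gradient", "guided_bp", "grad_cam"])
    def test_zero_head_gives_zero_scores(self, method, rng):
        params = BackboneParams.init(2, 2, hidden_dims=(5, 4), seed=1)
        params.head_weight.data[:] = 0.0
        params.head_bias.data[:] = 0.0
        g, graph = _graph(rng, 5)
        assert local_node_explanation(params, graph, 0, method=method).node_scores.max() == 0
        assert local_edge_explanation(params, graph, 0, method=method).edge_scores.max() == 0

    def test_node_scores_equivariant_under_permutation(self, rng, tiny_params):
        g, graph = _graph(rng, 6)
        pi = rng.permutation(6)
        permuted = AtlasGraph(g["adj"][np.ix_(pi, pi)], g["x"][pi], 0, "p")
        s0 = local_node_explanation(tiny_params, graph, 0).node_scores
        s1 = local_node_explanation(tiny_params, permuted, 0).node_scores
        assert np.allclose(s0[pi], s1, atol=1e-8)

    def test_edge_scores_equivariant_under_permutation(self, rng, tiny_params):
        g, graph = _graph(rng, 6)
        pi = rng.permutation(6)
        permuted = AtlasGraph(g["adj"][np.ix_(pi, pi)], g["x"][pi], 0, "p")
        e0 = local_edge_explanation(tiny_params, graph, 0).edge_scores
        e1 = local_edge_explanation(tiny_params, permuted, 0).edge_scores
        assert np.allclose(e0[np.ix_(pi, pi)], e1, atol=1e-8)

    def test_unknown_method_and_bad_layer_raise(self, rng, tiny_params):
        g, graph = _graph(rng, 4)
        with pytest.raises(ValueError, match="unknown method"):
            local_node_explanation(tiny_params, graph, 0, method="lrp")
        with pytest.raises(ValueError, match="layer"):
            local_node_explanation(tiny_params, graph, 0, layer=9)

    def test_default_layer_is_below_the_pooled_layer(self, tiny_params):
        assert default_layer(tiny_params) == tiny_params.n_layers - 1


@pytest.mark.parametrize("method", ["gradient", "guided_bp", "grad_cam"])
def test_scores_remain_differentiable_in_backbone_weights(method, rng):
    """The mean saliency admits a nonzero gradient w.r.t. some weight —
    the property that makes explanation supervision trainable."""
    params = BackboneParams.init(2, 2, hidden_dims=(5, 4), seed=0)
    g = random_graph(rng, 6)
    node, edge = batch_saliency(params, g["adj"][None], g["x"][None], 0,
                                method=method, create_graph=True)
    for scores in (node, edge):
        assert scores.data.max() > 0  # non-degenerate saliency on this net
        grads = ad.grad(scores.mean(), params.trainable())
        assert any(np.abs(t.data).max() > 0 for t in grads)
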