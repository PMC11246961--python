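"""Concept explainer: binarization, activations, formulas, metrics,
projection, and a scaled-down end-to-end fit."""

import itertools

import numpy as np
import pytest
import sympy

from ggnes import (ConceptAssignment, Formula, GLGConfig, binarize_explanation,
                   concept_activation, concept_purity, fidelity, fit_glg,
                   formula_accuracy, representative_element)
from ggnes.concepts import ConceptModel, extract_formulas
from ggnes.explainers import LocalExplanation


def _edge_local(entries, n=5, sid="s", c=0):
    m = np.zeros((n, n))
    for (i, j), v in entries.items():
        m[i, j] = m[j, i] = v
    return LocalExplanation(sid, c, 1, "gradient", edge_scores=m)


class TestBinarize:
    def test_single_nonzero_edge_kept(self):
        sub = binarize_explanation(_edge_local({(0, 1): 0.7}), top_fraction=0.5)
        assert sub.kept_edges == ((0, 1),) and sub.kept_nodes == (0, 1)
        assert not sub.degenerate

    def test_top_fraction_cut(self):
        loc = _edge_local({(0, 1): 4, (0, 2): 3, (1, 3): 2, (2, 3): 1})
        sub = binarize_explanation(loc, top_fraction=0.5)
        assert set(sub.kept_edges) == {(0, 1), (0, 2)}

    def test_tie_at_cut_broken_lexicographically(self):
        loc = _edge_local({(0, 2): 1.0, (1, 3): 1.0, (0, 1): 5.0})
        sub = binarize_explanation(loc, top_fraction=0.5)  # keep 2 of 3
        assert set(sub.kept_edges) == {(0, 1), (0, 2)}

    def test_all_zero_scores_flagged_degenerate(self):
        sub = binarize_explanation(_edge_local({}))
        assert sub.degenerate and sub.kept_edges == ()

    def test_requires_edge_scores(self):
        loc = LocalExplanation("s", 0, 1, "gradient", node_scores=np.ones(3))
        with pytest.raises(ValueError):
            binarize_explanation(loc)


class TestActivation:
    def test_embedding_at_prototype_is_near_one_hot(self):
        protos = np.array([[0.0, 0.0], [5.0, 5.0], [9.0, 0.0]])
        memb = concept_activation(np.array([5.0, 5.0]), protos)
        assert memb.argmax() == 1 and memb[1] > 0.95
        assert abs(memb.sum() - 1.0) < 1e-12

    def test_equidistant_prototypes_split_evenly_tie_to_lower_index(self):
        protos = np.array([[1.0, 0.0], [-1.0, 0.0]])
        memb = concept_activation(np.array([0.0, 0.0]), protos)
        assert np.allclose(memb, [0.5, 0.5])
        assert ConceptAssignment.from_membership(memb[None]).hard[0] == 0

    def test_invariant_to_constant_distance_shift(self, rng):
        e = rng.normal(size=3)
        protos = rng.normal(size=(4, 3))
        d = np.sqrt(((e[None] - protos) ** 2).sum(axis=1))
        soft = np.exp(-d) / np.exp(-d).sum()
        shifted = np.exp(-(d + 7.0)) / np.exp(-(d + 7.0)).sum()
        assert np.allclose(soft, shifted)
        assert np.allclose(concept_activation(e, protos), soft)


class TestFormula:
    @pytest.mark.parametrize("m,seed", [(2, 0), (3, 1), (3, 2), (4, 3)])
    def test_print_parse_round_trip_on_full_truth_table(self, m, seed):
        rng = np.random.default_rng(seed)
        patterns = list(itertools.product([0, 1], repeat=m))
        minterms = [list(p) for p in patterns if rng.random() < 0.5]
        if not minterms or len(minterms) == len(patterns):
            minterms = [list(patterns[0])]
        expr = sympy.logic.SOPform(sympy.symbols(f"P0:{m}"), minterms)
        f = Formula(expr, m)
        g = Formula.from_string(str(f), m)
        for bits in patterns:
            assert f.evaluate(bits) == g.evaluate(bits)

    def test_printed_style_uses_logic_symbols(self):
        f = Formula.from_string("P0 ∨ (P1 ∧ P2)", 3)
        assert str(f) in ("P0 ∨ (P1 ∧ P2)", "(P1 ∧ P2) ∨ P0")
        assert f.evaluate([1, 0, 0]) and f.evaluate([0, 1, 1])
        assert not f.evaluate([0, 1, 0])


class TestMetrics:
    def test_purity_of_three_to_one_cluster(self):
        assign = ConceptAssignment(np.eye(2)[[0, 0, 0, 0]], np.zeros(4, int))
        mean, sd = concept_purity(assign, ["A", "A", "A", "B"])
        assert mean == 0.75 and sd == 0.0

    def test_single_label_clusters_are_pure(self):
        hard = np.array([0, 0, 1, 1])
        assign = ConceptAssignment(np.eye(2)[hard], hard)
        assert concept_purity(assign, ["A", "A", "B", "B"]) == (1.0, 0.0)

    def test_evenly_mixed_cluster_is_half(self):
        hard = np.zeros(4, int)
        assign = ConceptAssignment(np.eye(2)[hard], hard)
        mean, _ = concept_purity(assign, ["A", "A", "B", "B"])
        assert mean == 0.5

    def test_fidelity_and_accuracy_counts(self):
        assert fidelity([1, 1, 0, 0], [1, 1, 0, 0]) == 1.0
        assert fidelity([1, 1], [0, 0]) == 0.0
        assert fidelity([1, 1, 0, 0], [1, 1, 0, 1]) == 0.75
        assert formula_accuracy([1, 0, 1, 0, 1], [1, 0, 1, 0, 0]) == 0.8
        with pytest.raises(ValueError):
            fidelity([1, 0], [1, 0, 1])


def _manual_model(m=2, n=6, formulas=None):
    from ggnes.autodiff import Tensor

    rng = np.random.default_rng(0)
    model = ConceptModel(
        m=m, q=3, n_classes=2, n_nodes=n,
        enc_w1=Tensor(rng.normal(size=(n, 4)), requires_grad=True),
        enc_w2=Tensor(rng.normal(size=(4, 3)), requires_grad=True),
        logic_w=Tensor(rng.normal(size=(m, 2)), requires_grad=True),
        logic_b=Tensor(np.zeros(2), requires_grad=True),
        prototypes=Tensor(rng.normal(size=(m, 3)), requires_grad=True))
    if formulas:
        model.formulas = {c: Formula.from_string(s, m) for c, s in formulas.items()}
    return model


class TestProjection:
    def test_constant_cluster_projects_to_its_indicator(self):
        from ggnes.concepts import project_node_explanation

        model = _manual_model(formulas={0: "P0", 1: "P1"})
        node_ind = np.array([[1, 1, 1, 0, 0, 0]] * 3 + [[0, 0, 0, 1, 1, 0]] * 3, float)
        memb = np.eye(2)[[0, 0, 0, 1, 1, 1]]
        hard = memb.argmax(axis=1)
        out = project_node_explanation(model, 0, memb, node_ind, hard)
        assert np.allclose(out, [1, 1, 1, 0, 0, 0])

    def test_disjunction_takes_union_support(self):
        from ggnes.concepts import project_node_explanation

        model = _manual_model(formulas={0: "P0 ∨ P1", 1: "P1"})
        node_ind = np.array([[1, 1, 0, 0, 0, 0]] * 2 + [[0, 0, 1, 1, 0, 0]] * 2, float)
        memb = np.eye(2)[[0, 0, 1, 1]]
        out = project_node_explanation(model, 0, memb, node_ind, memb.argmax(1))
        assert set(np.nonzero(out)[0]) == {0, 1, 2, 3}
        assert out.max() == 1.0

    def test_formula_without_positive_literal_warns_and_zeroes(self):
        from ggnes.concepts import project_node_explanation

        model = _manual_model(formulas={0: "¬P0", 1: "P0"})
        node_ind = np.ones((2, 6))
        memb = np.eye(2)[[0, 1]]
        with pytest.warns(UserWarning, match="no positive literal"):
            out = project_node_explanation(model, 0, memb, node_ind, memb.argmax(1))
        assert out.max() == 0.0


class TestRepresentative:
    def _subgraphs(self):
        return [binarize_explanation(_edge_local({(0, i + 1): 1.0 + i}, n=6,
                                                 sid=f"s{i}"))
                for i in range(4)]

    def test_matches_exhaustive_scan(self):
        model = _manual_model()
        subs = self._subgraphs()
        emb = model.embed_subgraphs(subs)
        for j in range(model.m):
            d = np.linalg.norm(emb - model.prototypes.data[j], axis=1)
            assert representative_element(j, subs, model) is subs[int(d.argmin())]

    def test_single_element_collection(self):
        model = _manual_model()
        subs = self._subgraphs()[:1]
        assert representative_element(0, subs, model) is subs[0]
        assert representative_element(1, subs, model) is subs[0]

    def test_empty_collection_raises(self):
        with pytest.raises(ValueError):
            representative_element(0, [], _manual_model())


class TestEmbedding:
    def test_identical_subgraphs_embed_identically(self):
        model = _manual_model()
        a = binarize_explanation(_edge_local({(0, 1): 1.0, (1, 2): 0.5}, n=6, sid="a"))
        b = binarize_explanation(_edge_local({(0, 1): 1.0, (1, 2): 0.5}, n=6, sid="b"))
        emb = model.embed_subgraphs([a, b])
        assert np.allclose(emb[0], emb[1])

    def test_embedding_dimension_matches_config(self):
        model = _manual_model()
        subs = [binarize_explanation(_edge_local({(0, 1): 1.0}, n=6))]
        assert model.embed_subgraphs(subs).shape == (1, model.q)


class TestFitGLG:
    def test_degenerate_single_class_predictions_give_tautology_fidelity(self):
        locals_ = [_edge_local({(0, 1): 1.0 + 0.1 * i}, sid=f"s{i}") for i in range(6)]
        preds = np.zeros(6, int)
        model = fit_glg(locals_, preds, m=2, config=GLGConfig(epochs=50, seed=0),
                        n_classes=2)
        subs = [binarize_explanation(l, model.top_fraction) for l in locals_]
        assign = model.assign(subs)
        assert fidelity(model.formula_predictions(assign), preds) == 1.0

    def test_warns_when_m_exceeds_distinct_structures(self):
        locals_ = [_edge_local({(0, 1): 1.0}, sid=f"s{i}") for i in range(4)]
        with pytest.warns(UserWarning, match="distinct"):
            fit_glg(locals_, np.zeros(4, int), m=3,
                    config=GLGConfig(epochs=5, seed=0), n_classes=2)

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError):
            fit_glg([_edge_local({(0, 1): 1.0})], [0], m=1)

    def test_deterministic_given_seed(self):
        locals_ = [_edge_local({(0, 1): 1.0}, sid="a", c=0),
                   _edge_local({(2, 3): 1.0}, sid="b", c=1)] * 3
        preds = np.array([0, 1] * 3)
        m1 = fit_glg(locals_, preds, 2, GLGConfig(epochs=40, seed=4), n_classes=2)
        m2 = fit_glg(locals_, preds, 2, GLGConfig(epochs=40, seed=4), n_classes=2)
        assert np.array_equal(m1.prototypes.data, m2.prototypes.data)
        assert {c: str(f) for c, f in m1.formulas.items()} == \
            {c: str(f) for c, f in m2.formulas.items()}


def test_extract_formulas_tautology_when_layer_predicts_one_class():
    model = _manual_model()
    model.logic_w.data[:] = 0.0
    model.logic_b.data[:] = [5.0, 0.0]  # class 0 always wins
    formulas = extract_formulas(model)
    assert formulas[0].expr is sympy.true
    assert formulas[1].expr is sympy.false
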