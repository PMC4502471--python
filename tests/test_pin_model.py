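"""Transitivity and co-expression evidence, conditional models, posterior."""

import numpy as np
import pytest
from scipy import stats

import spliceonet as sn
from spliceonet.pin_model import ConditionalModel, _transitivity_matrix

def net_from_neighbors(na, nb):
    edges = [("a", x) for x in na] + [("b", x) for x in nb]
    return sn.InteractionNetwork(nodes={"a", "b"}, edges=edges)


class TestTransitivity:
    def test_identical_neighborhoods(self):
        net = net_from_neighbors({"x", "y", "z"}, {"x", "y", "z"})
        assert sn.compute_transitivity(net, "a", "b") == 1.0

    def test_disjoint_neighborhoods(self):
        net = net_from_neighbors({"x", "y"}, {"w", "z"})
        assert sn.compute_transitivity(net, "a", "b") == 0.0

    def test_shared_vs_exclusive_ratio(self):
        net = net_from_neighbors({"x", "y", "z"}, {"y", "z", "w"})
        assert sn.compute_transitivity(net, "a", "b") == pytest.approx(0.5)

    def test_empty_neighborhoods_give_zero(self):
        net = sn.InteractionNetwork(nodes={"a", "b"})
        assert sn.compute_transitivity(net, "a", "b") == 0.0

    def test_direct_edge_contributes_nothing(self):
        base = net_from_neighbors({"x", "y", "z"}, {"y", "z", "w"})
        with_edge = base.copy()
        with_edge.add_edge("a", "b")
        assert (sn.compute_transitivity(base, "a", "b")
                == sn.compute_transitivity(with_edge, "a", "b"))

    def test_errors(self):
        net = net_from_neighbors({"x"}, {"x"})
        with pytest.raises(ValueError):
            sn.compute_transitivity(net, "a", "a")
        with pytest.raises(KeyError):
            sn.compute_transitivity(net, "a", "missing")

    def test_matrix_route_agrees_with_pairwise(self):
        rng = np.random.default_rng(7)
        nodes = [f"N{k}" for k in range(15)]
        edges = [(nodes[i], nodes[j]) for i in range(15) for j in range(i + 1, 15)
                 if rng.random() < 0.3]
        net = sn.InteractionNetwork(nodes=nodes, edges=edges)
        ids = nodes[:10]
        T = _transitivity_matrix(net, ids)
        for i in range(10):
            for j in range(i + 1, 10):
                assert T[i, j] == pytest.approx(
                    sn.compute_transitivity(net, ids[i], ids[j]), abs=1e-12)


class TestCoexpression:
    def expr(self):
        return sn.ExpressionMatrix(
            ["g1", "g2", "g3", "g4", "flat"], ["s1", "s2", "s3"],
            [[1, 2, 3], [2, 4, 6], [-1, -2, -3], [1, 2, 4], [5, 5, 5]])

    def test_identical_profiles(self):
        assert sn.compute_coexpression(self.expr(), "g1", "g2") == pytest.approx(1.0)

    def test_negated_profile(self):
        assert sn.compute_coexpression(self.expr(), "g1", "g3") == pytest.approx(-1.0)

    def test_formula_value(self):
        r = sn.compute_coexpression(self.expr(), "g1", "g4")
        assert r == pytest.approx(0.982, abs=1e-3)
        # independent route
        assert r == pytest.approx(stats.pearsonr([1, 2, 3], [1, 2, 4])[0], abs=1e-12)

    def test_missing_gene_and_zero_variance(self):
        assert sn.compute_coexpression(self.expr(), "g1", "absent") is None
        assert sn.compute_coexpression(self.expr(), "g1", "flat") is None


class TestDecoyNetwork:
    def random_net(self, seed=0, n=50, p=0.12):
        rng = np.random.default_rng(seed)
        nodes = [f"N{k}" for k in range(n)]
        edges = [(nodes[i], nodes[j]) for i in range(n) for j in range(i + 1, n)
                 if rng.random() < p]
        return sn.InteractionNetwork(nodes=nodes, edges=edges)

    def test_degrees_and_edge_count_preserved(self):
        net = self.random_net()
        decoy = sn.make_decoy_network(net, seed=1)
        assert decoy.n_edges == net.n_edges
        assert decoy.nodes == net.nodes
        assert all(decoy.degree(v) == net.degree(v) for v in net.nodes)

    def test_deterministic_per_seed(self):
        net = self.random_net()
        assert (sn.make_decoy_network(net, seed=1).edges
                == sn.make_decoy_network(net, seed=1).edges)
        assert (sn.make_decoy_network(net, seed=1).edges
                != sn.make_decoy_network(net, seed=2).edges)

    def test_star_returned_unchanged_with_warning(self):
        star = sn.InteractionNetwork(edges=[("c", f"l{k}") for k in range(4)])
        with pytest.warns(UserWarning, match="no double-edge swap"):
            decoy = sn.make_decoy_network(star, seed=0)
        assert decoy.edges == star.edges

    def test_too_few_edges_rejected(self):
        net = sn.InteractionNetwork(edges=[("a", "b")])
        with pytest.raises(ValueError):
            sn.make_decoy_network(net, seed=0)


class TestConditionalModel:
    def uniform_model(self, prior=0.5):
        return ConditionalModel(
            t_edges=np.linspace(0, 1, 3), c_edges=np.linspace(-1, 1, 3),
            lik_t=np.full((2, 2), 0.5), lik_c=np.full((2, 2), 0.5),
            prior=prior, smoothing=1.0)

    def test_likelihoods_sum_to_one(self, pipelines):
        _, _, model, _ = pipelines[1]
        np.testing.assert_allclose(model.lik_t.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(model.lik_c.sum(axis=1), 1.0, atol=1e-9)

    def test_prior_auto_is_edge_density(self):
        # 10 nodes, 9 edges -> 9 / 45
        nodes = [f"N{k}" for k in range(10)]
        edges = [(nodes[k], nodes[k + 1]) for k in range(9)]
        net = sn.InteractionNetwork(nodes=nodes, edges=edges)
        model = sn.fit_conditional_models(net, None, seed=0)
        assert model.prior == pytest.approx(9 / 45)

    def test_true_class_has_higher_transitivity(self, pipelines):
        # clean modular network: edges share module partners, decoy edges do not
        _, bench, _, _ = pipelines[1]
        net = bench.true_net
        decoy = sn.make_decoy_network(net, seed=1)
        t1 = np.mean([sn.compute_transitivity(net, a, b)
                      for a, b in net.edge_list()])
        t0 = np.mean([sn.compute_transitivity(net, a, b)
                      for a, b in decoy.edge_list()])
        assert t1 > t0

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            sn.fit_conditional_models(sn.InteractionNetwork(nodes={"a", "b"}),
                                      None, seed=0)

    def test_missing_expression_disables_c_channel(self):
        nodes = [f"N{k}" for k in range(6)]
        edges = [(nodes[i], nodes[j]) for i in range(6) for j in range(i + 1, 6)
                 if (i + j) % 2]
        net = sn.InteractionNetwork(nodes=nodes, edges=edges)
        expr = sn.ExpressionMatrix(["zz"], ["s1", "s2", "s3"], [[1, 2, 3]])
        model = sn.fit_conditional_models(net, expr, seed=0)
        assert not model.c_enabled

    def test_json_roundtrip(self, tmp_path, pipelines):
        _, _, model, _ = pipelines[1]
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ConditionalModel.from_json(path)
        np.testing.assert_allclose(back.lik_t, model.lik_t)
        np.testing.assert_allclose(back.lik_c, model.lik_c)
        assert back.prior == model.prior

    def test_uninformative_evidence_returns_prior(self):
        model = self.uniform_model(prior=0.3)
        ev = sn.PairEvidence("a", "b", t=0.7, c=0.2)
        assert sn.posterior_pin(ev, model) == pytest.approx(0.3)

    def test_known_likelihood_ratio(self):
        # prior 0.5, T-ratio 3, C-ratio 1 -> 3/(3+1)
        model = ConditionalModel(
            t_edges=np.linspace(0, 1, 3), c_edges=np.linspace(-1, 1, 3),
            lik_t=np.array([[0.25, 0.75], [0.75, 0.25]]),
            lik_c=np.full((2, 2), 0.5), prior=0.5, smoothing=1.0)
        ev = sn.PairEvidence("a", "b", t=0.9, c=0.0)  # T in high bin: ratio 0.25/0.75
        assert sn.posterior_pin(ev, model) == pytest.approx(0.25 / (0.25 + 0.75))
        ev = sn.PairEvidence("a", "b", t=0.1, c=0.0)  # low bin: ratio 0.75/0.25 = 3
        assert sn.posterior_pin(ev, model) == pytest.approx(0.75)

    def test_missing_c_uses_t_only(self):
        model = ConditionalModel(
            t_edges=np.linspace(0, 1, 3), c_edges=np.linspace(-1, 1, 3),
            lik_t=np.array([[0.25, 0.75], [0.75, 0.25]]),
            lik_c=np.array([[0.9, 0.1], [0.1, 0.9]]), prior=0.5, smoothing=1.0)
        with_c = sn.posterior_pin(sn.PairEvidence("a", "b", t=0.1, c=0.9), model)
        without = sn.posterior_pin(sn.PairEvidence("a", "b", t=0.1, c=None), model)
        assert without == pytest.approx(0.75)
        assert with_c != pytest.approx(without)

    def test_posterior_monotone_in_likelihood_ratio(self):
        rng = np.random.default_rng(5)
        raw = rng.uniform(0.1, 1.0, size=(2, 10))
        lik_t = raw / raw.sum(axis=1, keepdims=True)
        raw = rng.uniform(0.1, 1.0, size=(2, 8))
        lik_c = raw / raw.sum(axis=1, keepdims=True)
        model = ConditionalModel(np.linspace(0, 1, 11), np.linspace(-1, 1, 9),
                                 lik_t, lik_c, prior=0.4, smoothing=1.0)
        centers_t = (model.t_edges[:-1] + model.t_edges[1:]) / 2
        centers_c = (model.c_edges[:-1] + model.c_edges[1:]) / 2
        pts = [(t, c) for t in centers_t for c in centers_c]
        lr = [model.t_likelihood(t, 1) / model.t_likelihood(t, 0)
              * model.c_likelihood(c, 1) / model.c_likelihood(c, 0)
              for t, c in pts]
        post = [sn.posterior_pin(sn.PairEvidence("a", "b", t=t, c=c), model)
                for t, c in pts]
        order = np.argsort(lr)
        assert np.all(np.diff(np.array(post)[order]) >= -1e-12)

    def test_smoothing_keeps_posterior_strictly_inside_unit_interval(self, pipelines):
        _, _, _, pnet = pipelines[1]
        off_diag = pnet.pin[~np.eye(pnet.n, dtype=bool)]
        assert off_diag.min() > 0
        assert off_diag.max() < 1


class TestBuildPsNetwork:
    def test_pair_count_small(self, pipelines):
        _, bench, model, _ = pipelines[1]
        ids = bench.catalog.ids[:4]
        pnet = sn.build_ps_network(ids, bench.observed_net, bench.expr, model)
        iu = np.triu_indices(4, 1)
        assert len(pnet.pin[iu]) == 6

    def test_full_catalog_pair_count(self, pipelines):
        # 630 proteins -> 198,135 scored pairs
        _, bench, model, _ = pipelines[1]
        ids = [f"G{i:03d}" for i in range(630)]
        pnet = sn.build_ps_network(ids, bench.observed_net, None, model)
        iu = np.triu_indices(pnet.n, 1)
        assert pnet.pin[iu].size == 198135

    def test_matrix_invariants(self, pipelines):
        _, _, _, pnet = pipelines[1]
        np.testing.assert_array_equal(pnet.pin, pnet.pin.T)
        assert pnet.pin.min() >= 0 and pnet.pin.max() <= 1
        assert np.all(np.diag(pnet.pin) == 0)

    def test_invariant_to_catalog_order(self, pipelines):
        _, bench, model, _ = pipelines[1]
        ids = bench.catalog.ids[:12]
        pnet1 = sn.build_ps_network(ids, bench.observed_net, bench.expr, model)
        rev = list(reversed(ids))
        pnet2 = sn.build_ps_network(rev, bench.observed_net, bench.expr, model)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                assert pnet1.get(a, b) == pytest.approx(pnet2.get(a, b), abs=1e-12)

    def test_tiny_catalog_rejected(self, pipelines):
        _, bench, model, _ = pipelines[1]
        with pytest.raises(ValueError):
            sn.build_ps_network(["P001"], bench.observed_net, None, model)

    def test_direct_edge_removal_leaves_scores_nearly_unchanged(self, pipelines):
        # residuals from dropping one direct edge are dominated by zeros
        _, bench, model, pnet = pipelines[1]
        a, b = bench.observed_net.edge_list()[0]
        pruned = bench.observed_net.copy()
        pruned.remove_edge(a, b)
        pnet2 = sn.build_ps_network(bench.catalog, pruned, bench.expr, model)
        frac, _ = sn.residual_comparison(pnet, pnet2, eps=0.1)
        iu = np.triu_indices(pnet.n, 1)
        assert np.median(np.abs(pnet.pin - pnet2.pin)[iu]) < 0.1
        assert frac > 0.99
        # the pair's own score moves only through third parties
        assert pnet2.get(a, b) == pytest.approx(pnet.get(a, b), abs=1e-12)
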