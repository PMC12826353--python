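"""Fusion graphs, adaptive fused-LASSO path, BIC selection."""

import numpy as np
import pandas as pd
import pytest

import loalfuse as lf
from loalfuse._solvers import (
    FusedSolution,
    fit_fused_logistic,
    fit_logistic,
    fused_objective,
    kkt_residual_fused,
    neg_loglik,
)
from loalfuse.fusion import FusedCandidate, FusionGraph, fit_fused

from _oracles import brute_force_fused


def _two_time_design(n=80, seed=6, shared=True):
    """Two-time design with one baseline covariate selected at both times."""
    rng = np.random.default_rng(seed)
    x0 = rng.standard_normal(n)
    b0, b1 = (1.0, 1.0) if shared else (1.5, -0.5)
    a0 = rng.binomial(1, 1 / (1 + np.exp(-b0 * x0)), n).astype(np.int8)
    a1 = rng.binomial(
        1, 1 / (1 + np.exp(-(b1 * x0 + 0.5 * a0 - 0.2))), n
    ).astype(np.int8)
    data = lf.LongitudinalData(
        L=[pd.DataFrame({"X0": x0}), pd.DataFrame(index=range(n))],
        A=[a0, a1],
        Y=rng.standard_normal(n),
    )
    design = lf.build_pooled_design(data)
    active = [int(j) for j in design.shrink_idx]
    return design, active


class TestGraph:
    def test_baseline_clique_single_edge(self, loal_fit_a):
        design = loal_fit_a.design
        graph = lf.build_fusion_graph(design, loal_fit_a.active, family="clique")
        c0_nodes = [j for j in graph.nodes if design.columns[j].name == "C0"]
        assert len(c0_nodes) == 2
        assert graph.edges == [tuple(sorted(c0_nodes))]

    def test_chain_on_three_times(self):
        """Baseline variable selected at three model times: chain has 2 edges."""
        rng = np.random.default_rng(2)
        n = 60
        x = rng.standard_normal(n)
        A = [rng.binomial(1, 0.5, n).astype(np.int8) for _ in range(3)]
        data = lf.LongitudinalData(
            L=[pd.DataFrame({"X": x})] + [pd.DataFrame(index=range(n))] * 2,
            A=A,
            Y=rng.standard_normal(n),
        )
        design = lf.build_pooled_design(data)
        active = [int(j) for j in design.shrink_idx]
        chain = lf.build_fusion_graph(design, active, family="chain")
        clique = lf.build_fusion_graph(design, active, family="clique")
        assert len(chain.edges) == 2
        assert len(clique.edges) == 3
        taus = sorted(
            tuple(design.columns[j].tau for j in e) for e in chain.edges
        )
        assert taus == [(0, 1), (1, 2)]

    def test_lag_rule_for_time_varying(self):
        """Repeated measurements of one variable fuse only at equal lag."""
        rng = np.random.default_rng(3)
        n = 50
        L = [pd.DataFrame({f"Z{t}": rng.standard_normal(n)}) for t in range(3)]
        A = [rng.binomial(1, 0.5, n).astype(np.int8) for _ in range(3)]
        data = lf.LongitudinalData(L=L, A=A, Y=rng.standard_normal(n))
        design = lf.build_pooled_design(data)
        active = [
            j
            for j in design.shrink_idx
            if design.columns[j].t is not None and design.columns[j].t > 0
        ]
        fam = {"Z1": "Z", "Z2": "Z"}
        graph = lf.build_fusion_graph(design, active, variable_family=fam)
        # lag-0 coefficients: Z1 in model 1, Z2 in model 2 -> one edge
        lag0 = [(u, v) for u, v in graph.edges]
        assert len(lag0) == 1
        (u, v) = lag0[0]
        cu, cv = design.columns[u], design.columns[v]
        assert cu.tau - cu.t == cv.tau - cv.t

    def test_isolated_node_is_not_an_error(self, loal_fit_a):
        graph = lf.build_fusion_graph(loal_fit_a.design, loal_fit_a.active)
        c1 = [
            j for j in graph.nodes
            if loal_fit_a.design.columns[j].name == "C1"
        ]
        assert c1 and all(c1[0] not in e for e in graph.edges)

    def test_self_edges_rejected(self):
        with pytest.raises(ValueError, match="self-edges"):
            FusionGraph(nodes=[1, 2], edges=[(1, 1)])


class TestFusionWeights:
    @pytest.mark.parametrize(
        "d, gamma1, expected",
        [(1.0, 2.5, 1.0), (0.5, 2.5, 2.0**2.5), (2.0, 1.0, 0.5)],
    )
    def test_closed_forms(self, d, gamma1, expected):
        graph = FusionGraph(nodes=[0, 1], edges=[(0, 1)])
        w = lf.fusion_weights(np.array([1.3, 1.3 + d]), graph, gamma1)
        assert w[0] == pytest.approx(expected, rel=1e-12)

    def test_equal_refits_capped_with_warning(self):
        graph = FusionGraph(nodes=[0, 1], edges=[(0, 1)])
        with pytest.warns(UserWarning, match="capped"):
            w = lf.fusion_weights(np.array([0.7, 0.7]), graph, 2.5)
        assert w[0] == 1e12

    def test_gamma1_must_be_positive(self):
        graph = FusionGraph(nodes=[0, 1], edges=[(0, 1)])
        with pytest.raises(ValueError, match="gamma1"):
            lf.fusion_weights(np.array([0.0, 1.0]), graph, 0.0)


class TestFusedPath:
    def test_lambda1_zero_is_restricted_mle(self):
        design, active = _two_time_design()
        graph = lf.build_fusion_graph(design, active)
        ew = np.ones(len(graph.edges))
        cands = fit_fused(design, active, graph, ew, lambda1_grid=[0.0])
        cols = np.sort(np.concatenate([design.unpenalized_idx, active]))
        mle = fit_logistic(design.X[:, cols], design.y)
        assert np.allclose(cands[0].alpha_star[cols], mle, atol=1e-8)

    def test_full_fusion_limit_equals_shared_parameter_mle(self):
        design, active = _two_time_design(shared=True)
        graph = lf.build_fusion_graph(design, active)
        (u, v) = graph.edges[0]
        ew = np.ones(1)
        cands = fit_fused(design, active, graph, ew, lambda1_grid=[1e6])
        cand = cands[0]
        assert cand.alpha_star[u] == cand.alpha_star[v]
        # independent shared-parameter fit: the two columns summed
        cols = np.sort(np.concatenate([design.unpenalized_idx, active]))
        Xs = design.X[:, cols].copy()
        pos = {int(j): i for i, j in enumerate(cols)}
        Xm = np.column_stack(
            [
                Xs[:, [i for i in range(Xs.shape[1]) if i not in (pos[u], pos[v])]],
                Xs[:, pos[u]] + Xs[:, pos[v]],
            ]
        )
        shared = fit_logistic(Xm, design.y)
        assert cand.alpha_star[u] == pytest.approx(shared[-1], abs=1e-7)

    def test_kkt_certificate_on_path(self):
        design, active = _two_time_design(shared=False)
        graph = lf.build_fusion_graph(design, active)
        ew = lf.fusion_weights(np.array([1.5, 0.3, -0.5]), FusionGraph(nodes=[0, 1], edges=[(0, 1)]))
        cols = np.sort(np.concatenate([design.unpenalized_idx, active]))
        pos = {int(j): i for i, j in enumerate(cols)}
        X, y = design.X[:, cols], design.y
        edges_r = [(pos[u], pos[v]) for u, v in graph.edges]
        for lam1 in (0.1, 1.0, 10.0):
            sol = fit_fused_logistic(X, y, edges_r, ew, lam1)
            assert kkt_residual_fused(X, y, sol, lam1, edges_r, ew) <= 1e-6

    @pytest.mark.parametrize("lam1", [0.3, 2.0, 20.0])
    def test_brute_force_oracle_equivalence(self, lam1):
        design, active = _two_time_design(shared=False)
        graph = lf.build_fusion_graph(design, active)
        ew = np.array([0.8])
        cols = np.sort(np.concatenate([design.unpenalized_idx, active]))
        pos = {int(j): i for i, j in enumerate(cols)}
        X, y = design.X[:, cols], design.y
        edges_r = [(pos[u], pos[v]) for u, v in graph.edges]
        sol = fit_fused_logistic(X, y, edges_r, ew, lam1)
        obj = fused_objective(X, y, sol.coef, lam1, np.array(edges_r), ew)
        obj_star = brute_force_fused(X, y, edges_r, ew, lam1)
        assert obj == pytest.approx(obj_star, abs=1e-6)

    def test_no_extra_sparsity(self, loal_fit_a):
        design = loal_fit_a.design
        graph = lf.build_fusion_graph(design, loal_fit_a.active)
        fused = lf.select_by_bic(
            design, loal_fit_a.active, graph, loal_fit_a.alpha_refit
        )
        for cand in fused.candidates:
            nz = {j for j in design.shrink_idx if cand.alpha_star[j] != 0.0}
            assert nz == set(loal_fit_a.active)

    def test_df_monotone_on_fixture(self):
        design, active = _two_time_design(shared=True)
        graph = lf.build_fusion_graph(design, active)
        ew = np.ones(len(graph.edges))
        cands = fit_fused(
            design, active, graph, ew, lambda1_grid=np.geomspace(1e-3, 1e4, 10)
        )
        dfs = [c.df for c in cands]
        assert all(a >= b for a, b in zip(dfs[:-1], dfs[1:]))


class TestBICSelection:
    def test_tie_prefers_fewer_df(self):
        a = FusedCandidate(2.5, 0.1, np.zeros(2), [[0], [1]], -10.0, 6, 0.0, 0.0)
        b = FusedCandidate(2.5, 0.5, np.zeros(2), [[0, 1]], -10.0, 5, 0.0, 0.0)
        order = sorted([a, b], key=lambda c: (c.bic, c.df, -c.lam1))
        assert order[0].df == 5

    def test_single_gamma1_reduces_to_1d_search(self, loal_fit_a):
        design = loal_fit_a.design
        graph = lf.build_fusion_graph(design, loal_fit_a.active)
        fused = lf.select_by_bic(
            design, loal_fit_a.active, graph, loal_fit_a.alpha_refit,
            gamma1_grid=(2.5,),
        )
        assert {c.gamma1 for c in fused.candidates} == {2.5}
        assert fused.best.bic == min(c.bic for c in fused.candidates)

    def test_permutation_equivariance(self):
        """Relabeling the two covariate columns permutes the fused solution."""
        design, active = _two_time_design(shared=False, seed=10)
        graph = lf.build_fusion_graph(design, active)
        refit = np.zeros(len(design.columns))
        cols = np.sort(np.concatenate([design.unpenalized_idx, active]))
        refit[cols] = fit_logistic(design.X[:, cols], design.y)
        fused = lf.select_by_bic(design, active, graph, refit)
        # swap the two node columns in X and active order; solution must swap too
        u, v = graph.nodes
        design2 = lf.PooledDesign(
            X=design.X.copy(), y=design.y, columns=list(design.columns),
            row_tau=design.row_tau, row_subject=design.row_subject,
            process=design.process, n_times=design.n_times,
            n_subjects=design.n_subjects,
        )
        design2.X[:, [u, v]] = design2.X[:, [v, u]]
        refit2 = refit.copy()
        refit2[[u, v]] = refit2[[v, u]]
        fused2 = lf.select_by_bic(design2, active, graph, refit2)
        assert fused2.alpha_star[u] == pytest.approx(fused.alpha_star[v], abs=1e-7)
        assert fused2.alpha_star[v] == pytest.approx(fused.alpha_star[u], abs=1e-7)
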