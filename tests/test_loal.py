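"""Pooled design, adaptive weights, penalized path and balance tuning."""

import numpy as np
import pandas as pd
import pytest

import loalfuse as lf
from loalfuse._solvers import l1_objective, kkt_residual_l1, fit_weighted_l1
from loalfuse.loal import PositivityError, _cumulative_stabilized_weights

from _oracles import brute_force_weighted_l1


def _small_design(n=60, p_shrink=3, seed=5):
    """Tiny single-time pooled design with p_shrink shrinkable columns."""
    rng = np.random.default_rng(seed)
    L = pd.DataFrame(
        {f"X{k}": rng.standard_normal(n) for k in range(p_shrink)}
    )
    lp = 0.8 * L["X0"] - 0.5 * L["X1"]
    a = rng.binomial(1, 1 / (1 + np.exp(-lp)), n).astype(np.int8)
    data = lf.LongitudinalData(L=[L], A=[a], Y=rng.standard_normal(n))
    return lf.build_pooled_design(data)


class TestPooledDesign:
    def test_single_time_reduction(self):
        design = _small_design(p_shrink=2)
        kinds = [(c.tau, c.kind, c.name) for c in design.columns]
        assert kinds == [
            (0, "intercept", "const"),
            (0, "covariate", "X0"),
            (0, "covariate", "X1"),
        ]
        assert list(design.shrink_idx) == [1, 2]

    def test_two_time_full_history_column_count(self, data_a):
        design = lf.build_pooled_design(data_a)
        assert len(design.columns) == 9  # 2 intercepts + 2 + 4 covariates + A0
        n_int = sum(c.kind == "intercept" for c in design.columns)
        n_cov = sum(c.kind == "covariate" for c in design.columns)
        n_tr = sum(c.kind == "treatment" for c in design.columns)
        assert (n_int, n_cov, n_tr) == (2, 6, 1)
        # shrinkable set excludes intercepts and treatment slots
        assert all(design.columns[j].kind == "covariate" for j in design.shrink_idx)

    def test_time0_rows_have_zero_time1_blocks(self, data_a):
        design = lf.build_pooled_design(data_a)
        rows0 = design.row_tau == 0
        cols1 = [j for j, c in enumerate(design.columns) if c.tau == 1]
        assert np.all(design.X[np.ix_(rows0, cols1)] == 0.0)

    def test_future_covariate_rejected(self, data_a):
        with pytest.raises(ValueError, match="future"):
            lf.build_pooled_design(data_a, history_spec={0: ["C1"]})

    def test_censoring_machinery_is_shared(self, data_a):
        """Relabeling treatment as censoring gives the identical design/fit."""
        relabeled = lf.LongitudinalData(
            L=data_a.L, A=data_a.A, Y=data_a.Y, C=list(data_a.A),
            standardization=data_a.standardization,
        )
        d_t = lf.build_pooled_design(data_a, process="treatment")
        d_c = lf.build_pooled_design(relabeled, process="censoring", absorbing=False)
        np.testing.assert_array_equal(d_t.X, d_c.X)
        np.testing.assert_array_equal(d_t.y, d_c.y)

    def test_absorbing_drops_post_event_rows(self, data_a):
        relabeled = lf.LongitudinalData(
            L=data_a.L, A=data_a.A, Y=data_a.Y, C=list(data_a.A),
        )
        d = lf.build_pooled_design(relabeled, process="censoring")  # absorbing
        at_risk_1 = d.row_subject[d.row_tau == 1]
        assert np.all(data_a.A[0][at_risk_1] == 0)


class TestAdaptiveWeights:
    @pytest.mark.parametrize(
        "b, gamma, expected",
        [
            (1.0, 2.5, 1.0),
            (0.5, 2.5, 2.0**2.5),
            (-2.0, 2.5, 2.0**-2.5),
            (2.0, 1.5, 2.0**-1.5),
        ],
    )
    def test_closed_forms(self, b, gamma, expected, data_a):
        design = lf.build_pooled_design(data_a, history_spec={0: ["C0"], 1: []})
        beta = lf.WorkingCoefficients(
            beta={0: pd.Series({"const": 1.0, "C0": b}), 1: pd.Series({"const": 1.0})},
            gamma=gamma,
        )
        pen = lf.adaptive_weights(beta, design)
        j = design.column_index(0, "C0")
        assert pen[j] == pytest.approx(expected, rel=1e-12)
        assert pen[design.column_index(0, "const")] == 0.0

    def test_zero_beta_capped_with_warning(self, data_a):
        design = lf.build_pooled_design(data_a, history_spec={0: ["C0"], 1: []})
        beta = lf.WorkingCoefficients(
            beta={0: pd.Series({"const": 1.0, "C0": 0.0}), 1: pd.Series({"const": 0.0})},
        )
        with pytest.warns(UserWarning, match="capped"):
            pen = lf.adaptive_weights(beta, design)
        assert pen[design.column_index(0, "C0")] == 1e12


class TestPath:
    def test_lambda_zero_matches_unpenalized_mle(self, data_a, beta_a):
        import statsmodels.api as sm

        design = lf.build_pooled_design(data_a)
        pen = lf.adaptive_weights(beta_a, design)
        coef = fit_weighted_l1(design.X, design.y, pen, 0.0)
        ref = sm.GLM(design.y, design.X, family=sm.families.Binomial()).fit()
        assert np.allclose(coef, ref.params, atol=1e-6)

    def test_largest_lambda_empties_active_set(self, loal_fit_a):
        assert np.all(loal_fit_a.coefs[0, loal_fit_a.design.shrink_idx] == 0.0)

    def test_kkt_holds_along_path(self, loal_fit_a):
        assert loal_fit_a.kkt_residuals().max() <= 1e-6

    @pytest.mark.parametrize("lam_frac", [0.0, 0.05, 0.3, 1.0])
    def test_brute_force_oracle_equivalence(self, lam_frac):
        design = _small_design()
        pen = np.zeros(len(design.columns))
        pen[design.shrink_idx] = [1.0, 2.0, 0.7]
        from loalfuse._solvers import lambda_max

        lam = lam_frac * lambda_max(design.X, design.y, pen)
        coef = fit_weighted_l1(design.X, design.y, pen, lam)
        obj = l1_objective(design.X, design.y, coef, lam, pen)
        obj_star = brute_force_weighted_l1(design.X, design.y, pen, lam)
        assert obj == pytest.approx(obj_star, abs=1e-6)

    def test_ascending_grid_rejected(self, data_a, beta_a):
        design = lf.build_pooled_design(data_a)
        pen = lf.adaptive_weights(beta_a, design)
        with pytest.raises(ValueError, match="descending"):
            lf.fit_loal_path(design, pen, lambdas=[0.1, 1.0])


class TestBalance:
    def test_hand_computed_fixture(self):
        """Unit weights: score = sum |beta| * |mean difference| by hand."""
        L = pd.DataFrame({"X": [1.0, 2.0, 3.0, -1.0, 0.0, 1.0]})
        a = np.array([1, 1, 1, 0, 0, 0], dtype=np.int8)
        data = lf.LongitudinalData(L=[L], A=[a], Y=np.zeros(6))
        design = lf.build_pooled_design(data)
        beta = lf.WorkingCoefficients(
            beta={0: pd.Series({"const": 0.0, "X": 0.8})}
        )
        alpha = np.zeros(len(design.columns))  # p = 0.5 everywhere -> weights 1
        score = lf.balance_score(data, alpha, design, beta)
        assert score == pytest.approx(0.8 * abs(2.0 - 0.0), rel=1e-12)

    def test_score_linear_in_beta_weights(self, data_a, beta_a, loal_fit_a):
        alpha = loal_fit_a.alpha_refit
        design = loal_fit_a.design
        s1 = lf.balance_score(data_a, alpha, design, beta_a)
        doubled = lf.WorkingCoefficients(
            beta={t: 2.0 * b for t, b in beta_a.beta.items()}, gamma=beta_a.gamma
        )
        s2 = lf.balance_score(data_a, alpha, design, doubled)
        assert s2 == pytest.approx(2.0 * s1, rel=1e-10)

    def test_true_weights_balance_randomized_treatment(self):
        """Randomized treatment: balance score vanishes as n grows."""
        rng = np.random.default_rng(8)
        scores = []
        for n in (500, 32_000):
            x = rng.standard_normal(n) + 0.5
            a = rng.binomial(1, 0.5, n).astype(np.int8)
            data = lf.LongitudinalData(L=[pd.DataFrame({"X": x})], A=[a], Y=np.zeros(n))
            design = lf.build_pooled_design(data)
            beta = lf.WorkingCoefficients(beta={0: pd.Series({"const": 0.0, "X": 1.0})})
            scores.append(
                lf.balance_score(data, np.zeros(len(design.columns)), design, beta)
            )
        assert scores[1] < scores[0]
        assert scores[1] < 0.02

    def test_positivity_violation_raises(self, data_a, beta_a):
        design = lf.build_pooled_design(data_a)
        alpha = np.zeros(len(design.columns))
        alpha[design.column_index(0, "C0")] = 80.0  # probabilities hit 0/1
        with pytest.raises(PositivityError, match="time 0"):
            lf.balance_score(data_a, alpha, design, beta_a)

    def test_stabilized_weights_mean_one_under_truth(self, spec_a):
        """With true propensities and marginal numerators, E(w_t) = 1."""
        data = lf.generate(spec_a, 100_000, 13)
        design = lf.build_pooled_design(data)
        # overwrite fitted probabilities with the generating truth
        probs = data.true_propensity
        w = np.empty((data.n, 2))
        A = np.column_stack(data.A).astype(float)
        marg = A.mean(axis=0)
        num = np.where(A == 1, marg, 1 - marg)
        den = np.where(A == 1, probs, 1 - probs)
        w = np.cumprod(num / den, axis=1)
        for t in range(2):
            assert abs(w[:, t].mean() - 1.0) < 3 * w[:, t].std() / np.sqrt(data.n)


class TestSelection:
    def test_zero_score_lambda_selected(self, loal_fit_a):
        assert loal_fit_a.balance is not None
        sel = loal_fit_a.balance[loal_fit_a.lambda_index]
        assert sel == np.nanmin(loal_fit_a.balance)

    def test_tie_breaks_to_largest_lambda(self, data_a, beta_a):
        """Duplicate grid points force an exact tie; the larger index wins."""
        design = lf.build_pooled_design(data_a)
        pen = lf.adaptive_weights(beta_a, design)
        from loalfuse._solvers import lambda_max

        lmax = lambda_max(design.X, design.y, pen) * (1 + 1e-6)
        fit = lf.fit_loal_path(design, pen, lambdas=[lmax, lmax * 0.999999, 0.05])
        fit = lf.select_lambda_and_refit(fit, data_a, beta_a)
        if fit.balance[0] == fit.balance[1]:
            assert fit.lambda_index != 1

    def test_scenario1_selects_confounders_not_instruments(self, loal_fit_a):
        names = {
            (loal_fit_a.design.columns[j].tau, loal_fit_a.design.columns[j].name)
            for j in loal_fit_a.active
        }
        assert (0, "C0") in names and (1, "C0") in names and (1, "C1") in names
        assert not any(nm in ("I0", "I1") for _, nm in names)

    def test_refit_zero_outside_active_and_unpenalized(self, loal_fit_a):
        design = loal_fit_a.design
        allowed = set(loal_fit_a.active) | set(design.unpenalized_idx)
        for j, v in enumerate(loal_fit_a.alpha_refit):
            if j not in allowed:
                assert v == 0.0
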