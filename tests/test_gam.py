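"""Penalized GAM: bases, fitting, pooling, sampling, elimination."""

import copy
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import riskdist as rd
from riskdist import gam
from riskdist.gam import (GamSpec, GamTermSpec, _second_difference_penalty,
                          bspline_basis)


def _logistic_frame(n=800, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "x1": rng.integers(0, 2, n).astype(float),
        "x2": rng.integers(0, 2, n).astype(float),
        "x3": rng.integers(0, 2, n).astype(float),
    })
    eta = -1.0 + 0.8 * df.x1 - 0.5 * df.x2 + 0.3 * df.x3
    df["died"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return df


BINARY_SPECS = {f"x{i}": rd.VariableSpec(f"x{i}", "binary",
                                         allowed_categories=(0, 1),
                                         base_category=0)
                for i in (1, 2, 3)}


class TestBasis:
    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=0.0, max_value=10.0))
    def test_partition_of_unity(self, x):
        B = bspline_basis(np.array([x]), 0.0, 10.0)
        assert B.shape == (1, 10)
        assert B.sum() == pytest.approx(1.0, abs=1e-9)

    def test_out_of_range_inputs_clamp(self):
        B_low = bspline_basis(np.array([-5.0]), 0.0, 10.0)
        B_edge = bspline_basis(np.array([0.0]), 0.0, 10.0)
        assert np.allclose(B_low, B_edge)

    def test_continuous_variable_gets_ten_columns(self, small_world):
        spec = GamSpec((GamTermSpec("spline", ("sodium",)),))
        info = gam.fit_design_info(small_world["cohort"].df, spec,
                                   small_world["cohort"].specs)
        assert info.n_columns == 11  # intercept + 10 splines

    def test_binary_variable_gets_one_column(self, small_world):
        spec = GamSpec((GamTermSpec("categorical", ("arrhythmia",),
                                    penalty=1.0),))
        info = gam.fit_design_info(small_world["cohort"].df, spec,
                                   small_world["cohort"].specs)
        assert info.n_columns == 2  # intercept + 1 dummy

    def test_tensor_block_is_product_of_marginals(self, small_world):
        df = small_world["cohort"].df
        spec = GamSpec((GamTermSpec("spline", ("bun",)),
                        GamTermSpec("spline", ("creatinine",)),
                        GamTermSpec("tensor", ("bun", "creatinine"))))
        info = gam.fit_design_info(df, spec, small_world["cohort"].specs)
        X = gam.build_design(df.head(5), info)
        b1 = X[:, 1:11]
        b2 = X[:, 11:21]
        tensor = X[:, 21:121]
        expect = np.einsum("ij,ik->ijk", b1, b2).reshape(5, -1)
        assert np.allclose(tensor, expect)
        # tensor rows also sum to one: product of two partitions of unity
        assert np.allclose(tensor.sum(axis=1), 1.0)

    def test_missing_value_raises_design_error(self, small_world):
        df = small_world["cohort"].df.head(5).copy()
        df.loc[2, "sodium"] = np.nan
        spec = GamSpec((GamTermSpec("spline", ("sodium",)),))
        info = gam.fit_design_info(small_world["cohort"].df, spec,
                                   small_world["cohort"].specs)
        with pytest.raises(rd.DesignError, match="sodium"):
            gam.build_design(df, info)

    def test_term_spec_invariants(self):
        with pytest.raises(rd.FitError):
            GamTermSpec("tensor", ("a",))
        with pytest.raises(rd.FitError):
            GamTermSpec("spline", ("a",), penalty=-1)
        with pytest.raises(rd.FitError):
            GamSpec((GamTermSpec("spline", ("a",)),
                     GamTermSpec("spline", ("a",))))


class TestBinomialFit:
    def test_matches_unpenalized_logistic_oracle(self):
        """With zero penalties on a plain dummy design, penalized IRLS
        agrees with a statsmodels GLM fit to 4 decimals (n=500)."""
        import statsmodels.api as sm

        df = _logistic_frame(500, seed=1)
        spec = GamSpec(tuple(GamTermSpec("categorical", (f"x{i}",), penalty=0.0)
                             for i in (1, 2, 3)))
        fit = gam.fit_binomial_gam(df, spec, variable_specs=BINARY_SPECS)
        X = sm.add_constant(df[["x1", "x2", "x3"]].to_numpy())
        oracle = sm.GLM(df["died"].to_numpy(), X,
                        family=sm.families.Binomial()).fit()
        assert np.allclose(fit.coef, oracle.params, atol=1e-4)
        assert np.allclose(np.sqrt(np.diag(fit.cov)), oracle.bse, atol=1e-4)

    def test_single_class_outcome_raises(self):
        df = _logistic_frame(100, seed=2)
        df["died"] = 0.0
        spec = GamSpec((GamTermSpec("categorical", ("x1",), penalty=1.0),))
        with pytest.raises(rd.DegenerateOutcomeError):
            gam.fit_binomial_gam(df, spec, variable_specs=BINARY_SPECS)

    def test_predicted_risks_in_unit_interval(self, small_world):
        df = small_world["cohort"].df
        spec = gam.default_risk_terms(small_world["cohort"].specs)
        fit = gam.fit_binomial_gam(df, spec,
                                   variable_specs=small_world["cohort"].specs)
        p = gam.predict_risk(fit, df)
        assert np.all((p > 0) & (p < 1))

    def _curvature(self, fit, term_label):
        for enc in fit.info.encodings:
            if enc.term.label == term_label:
                c = fit.coef[enc.sl]
                D2 = _second_difference_penalty(len(c))
                return float(c @ D2 @ c)
        raise AssertionError(term_label)

    def test_infinite_penalty_limit_is_straight_line(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.uniform(0, 1, 2000)})
        eta = -2 + 3 * (df.x - 0.5) ** 2 * 4
        df["died"] = (rng.random(2000) < 1 / (1 + np.exp(-eta))).astype(float)
        specs = {"x": rd.VariableSpec("x", "continuous")}
        heavy = GamSpec((GamTermSpec("spline", ("x",), penalty=1e9),))
        fit = gam.fit_binomial_gam(df, heavy, variable_specs=specs)
        assert self._curvature(fit, "spline(x)") < 1e-6

    def test_penalty_monotonicity(self):
        """More second-derivative penalty never increases a term's
        curvature norm."""
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x": rng.uniform(0, 1, 2000)})
        eta = -2 + np.sin(6 * df.x)
        df["died"] = (rng.random(2000) < 1 / (1 + np.exp(-eta))).astype(float)
        specs = {"x": rd.VariableSpec("x", "continuous")}
        curvatures = []
        for lam in (0.1, 10.0, 1000.0):
            spec = GamSpec((GamTermSpec("spline", ("x",), penalty=lam),))
            fit = gam.fit_binomial_gam(df, spec, variable_specs=specs)
            curvatures.append(self._curvature(fit, "spline(x)"))
        assert curvatures[0] >= curvatures[1] >= curvatures[2]


class TestPooling:
    def _one_coef_fit(self, coef, var):
        df = _logistic_frame(120, seed=5)
        spec = GamSpec((GamTermSpec("categorical", ("x1",), penalty=0.0),))
        base = gam.fit_binomial_gam(df, spec, variable_specs=BINARY_SPECS)
        fit = copy.deepcopy(base)
        fit.coef = np.array([0.0, coef])
        fit.cov = np.diag([0.0, var])
        return fit

    def test_hand_worked_rubin_example(self):
        """coefs {0.2, 0.4}, variances {0.01, 0.03}: pooled mean 0.3,
        pooled variance 0.02 + (1 + 1/2) x 0.02 = 0.05."""
        pooled = gam.pool_fits([self._one_coef_fit(0.2, 0.01),
                                self._one_coef_fit(0.4, 0.03)])
        assert pooled.coef[1] == pytest.approx(0.3)
        assert pooled.cov[1, 1] == pytest.approx(0.05)

    def test_single_fit_pools_to_itself(self):
        fit = self._one_coef_fit(0.7, 0.02)
        pooled = gam.pool_fits([fit])
        assert np.allclose(pooled.coef, fit.coef)
        assert np.allclose(pooled.cov, fit.cov)

    def test_identical_fits_have_zero_between_variance(self):
        fits = [self._one_coef_fit(0.5, 0.02) for _ in range(4)]
        pooled = gam.pool_fits(fits)
        assert np.allclose(pooled.between_cov, 0)
        assert np.allclose(pooled.cov, pooled.within_cov)

    def test_pooled_variance_dominates_within_variance(self, small_bundle):
        pooled = small_bundle.model
        assert np.all(np.diag(pooled.cov) >= np.diag(pooled.within_cov) - 1e-12)

    def test_mismatched_term_maps_raise(self):
        a = self._one_coef_fit(0.2, 0.01)
        df = _logistic_frame(120, seed=5)
        spec = GamSpec((GamTermSpec("categorical", ("x2",), penalty=0.0),))
        b = gam.fit_binomial_gam(df, spec, variable_specs=BINARY_SPECS)
        with pytest.raises(rd.PoolingError):
            gam.pool_fits([a, b])


class TestCoefficientSampling:
    def test_zero_covariance_returns_the_mean(self):
        df = _logistic_frame(300, seed=6)
        spec = GamSpec((GamTermSpec("categorical", ("x1",), penalty=0.0),))
        fit = gam.fit_binomial_gam(df, spec, variable_specs=BINARY_SPECS)
        fit.cov = np.zeros_like(fit.cov)
        draws = gam.sample_coefficients(fit, 7, seed=0)
        assert draws.shape == (7, 2)
        assert np.allclose(draws, fit.coef)

    def test_requested_draw_count(self, small_bundle):
        draws = gam.sample_coefficients(small_bundle.model, 5, seed=1)
        assert draws.shape[0] == 5

    def test_sample_mean_matches_posterior_mean(self):
        df = _logistic_frame(500, seed=7)
        spec = GamSpec(tuple(GamTermSpec("categorical", (f"x{i}",), penalty=0.0)
                             for i in (1, 2, 3)))
        fit = gam.fit_binomial_gam(df, spec, variable_specs=BINARY_SPECS)
        draws = gam.sample_coefficients(fit, 100_000, seed=2)
        se = np.sqrt(np.diag(fit.cov) / 100_000)
        assert np.all(np.abs(draws.mean(axis=0) - fit.coef) < 3.5 * se + 1e-12)


class TestBackwardElimination:
    def _frame_with_noise(self, seed):
        rng = np.random.default_rng(seed)
        n = 3000
        df = pd.DataFrame({
            "strong": rng.normal(0, 1, n),
            "medium": rng.normal(0, 1, n),
            "noise": rng.normal(0, 1, n),
        })
        eta = -2 + 1.2 * df.strong + 0.5 * df.medium
        df["died"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        specs = {k: rd.VariableSpec(k, "continuous")
                 for k in ("strong", "medium", "noise")}
        spec = GamSpec(tuple(GamTermSpec("spline", (v,), penalty=10.0)
                             for v in ("strong", "medium", "noise")))
        return df, spec, specs

    def test_zero_removals_is_identity(self):
        df, spec, specs = self._frame_with_noise(0)
        assert gam.backward_eliminate(spec, df, 0, specs) is spec

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_noise_removed_before_signal(self, seed):
        df, spec, specs = self._frame_with_noise(seed)
        reduced = gam.backward_eliminate(spec, df, 1, specs)
        assert set(reduced.variables) == {"strong", "medium"}

    def test_removal_count(self):
        df, spec, specs = self._frame_with_noise(3)
        reduced = gam.backward_eliminate(spec, df, 2, specs)
        assert len(reduced.variables) == 1

    def test_cannot_empty_the_model(self):
        df, spec, specs = self._frame_with_noise(4)
        with pytest.raises(ValueError):
            gam.backward_eliminate(spec, df, 3, specs)


class TestPartialDependence:
    def test_default_levels_and_nesting(self, small_bundle):
        pd_out = gam.partial_dependence(small_bundle.model, "sodium", seed=3)
        assert set(pd_out["bands"]) == {95, 70, 45, 20}
        lo95, hi95 = pd_out["bands"][95]
        lo20, hi20 = pd_out["bands"][20]
        assert np.all(lo95 <= lo20 + 1e-12)
        assert np.all(hi20 <= hi95 + 1e-12)
        for level in (70, 45):
            lo, hi = pd_out["bands"][level]
            assert np.all((lo95 <= lo + 1e-12) & (hi <= hi95 + 1e-12))

    def test_zero_covariance_collapses_bands(self, small_bundle):
        model = copy.deepcopy(small_bundle.model)
        model.cov = np.zeros_like(model.cov)
        out = gam.partial_dependence(model, "lactate", seed=1)
        for lo, hi in out["bands"].values():
            assert np.allclose(lo, hi)
            assert np.allclose(lo, out["median"])

    def test_unknown_variable_raises(self, small_bundle):
        with pytest.raises(ValueError, match="not in the model"):
            gam.partial_dependence(small_bundle.model, "shoe_size")


class TestSerialization:
    def test_pooled_round_trip_preserves_predictions(self, small_bundle):
        model = small_bundle.model
        d = gam.pooled_to_dict(model)
        back = gam.pooled_from_dict(d)
        ref = model.info.reference_frame(10)
        ref["sodium"] = np.linspace(125, 148, 10)
        assert np.allclose(back.linear_predictor(ref),
                           model.linear_predictor(ref))
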