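"""Two-stage multiple imputation: counts, determinism, propriety."""

import warnings

import numpy as np
import pandas as pd
import pytest

import riskdist as rd
from riskdist.impute import LAB_VARIABLES, lab_imputer_terms


class TestImputationCountRule:
    @pytest.mark.parametrize("frac,expected", [
        (0.272, 28),   # the study's incomplete fraction
        (0.0, 1),
        (1.0, 100),
        (0.005, 1),
        (0.011, 2),
    ])
    def test_ceiling_rule(self, frac, expected):
        assert rd.choose_n_imputations(frac) == expected

    @pytest.mark.parametrize("frac", [-0.1, 1.2])
    def test_out_of_range_fraction_raises(self, frac):
        with pytest.raises(ValueError):
            rd.choose_n_imputations(frac)


@pytest.fixture(scope="module")
def observed_prepared(observed_cohort):
    thr = rd.fit_winsor_thresholds(observed_cohort)
    prepared = rd.apply_winsor(
        rd.add_missingness_indicators(observed_cohort), thr)
    return prepared, thr


class TestRunMice:
    def test_fully_observed_cohort_yields_identical_copies(self, small_world):
        cfg = rd.ImputationConfig(m_mice=3, seed=1)
        cohort = rd.add_missingness_indicators(small_world["cohort"])
        out = rd.run_mice(cohort, cfg)
        assert len(out) == 3
        for c in out[1:]:
            pd.testing.assert_frame_equal(c.df, out[0].df)

    def test_deterministic_given_seed(self, observed_prepared):
        prepared, _ = observed_prepared
        cfg = rd.ImputationConfig(m_mice=2, seed=9)
        a = rd.run_mice(prepared, cfg)
        b = rd.run_mice(prepared, cfg)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.df, y.df)

    def test_observed_cells_invariant_and_draws_vary(self, observed_prepared):
        prepared, _ = observed_prepared
        cfg = rd.ImputationConfig(m_mice=2, seed=9)
        out = rd.run_mice(prepared, cfg)
        base = prepared.df
        mask = base["heart_rate"].notna()
        for c in out:
            assert np.array_equal(c.df.loc[mask, "heart_rate"],
                                  base.loc[mask, "heart_rate"])
            assert not c.df["heart_rate"].isna().any()
        miss = ~mask
        assert not np.array_equal(out[0].df.loc[miss, "heart_rate"],
                                  out[1].df.loc[miss, "heart_rate"])

    def test_wholly_missing_variable_raises(self, observed_prepared):
        prepared, _ = observed_prepared
        broken = prepared.copy()
        broken.df["potassium"] = np.nan
        with pytest.raises(rd.ImputationError, match="potassium"):
            rd.run_mice(broken, rd.ImputationConfig(m_mice=1))

    def test_imputed_mean_tracks_pre_deletion_truth(self, big_world):
        """Under MAR deletion at a substantial rate, the post-imputation
        sodium mean stays close to the fully-observed mean."""
        cohort = big_world["cohort"]
        truth = cohort.df["sodium"].mean()
        cfg = rd.GeneratorConfig(n_cases=20000, n_hospitals=186, seed=11,
                                 missingness_rates={"sodium": 0.3})
        obs = rd.inject_missingness(cohort, cfg)
        obs = rd.add_missingness_indicators(obs)
        out = rd.run_mice(obs, rd.ImputationConfig(m_mice=2, seed=4))
        se = cohort.df["sodium"].std() / np.sqrt(len(cohort.df))
        for c in out:
            assert abs(c.df["sodium"].mean() - truth) < 4 * se

    def test_outcome_inclusion_reduces_imputation_bias(self, small_world):
        """A covariate driven mostly by the outcome is imputed with less
        attenuation when the outcome joins its conditional model."""
        cohort = small_world["cohort"].copy()
        rng = np.random.default_rng(0)
        died = cohort.df["died"].to_numpy(float)
        cohort.df["wcc"] = 8.0 + 4.0 * died + rng.normal(0, 1, len(died))
        mask = rng.random(len(died)) < 0.4
        cohort.df.loc[mask, "wcc"] = np.nan
        cohort = rd.add_missingness_indicators(cohort)
        gaps = {}
        for flag in (True, False):
            cfg = rd.ImputationConfig(m_mice=1, seed=2,
                                      include_outcome_in_mice=flag)
            done = rd.run_mice(cohort, cfg)[0].df
            imp = done.loc[mask, "wcc"]
            d = died[mask]
            gaps[flag] = imp[d == 1].mean() - imp[d == 0].mean()
        assert gaps[True] > gaps[False] + 0.5
        assert gaps[True] == pytest.approx(4.0, abs=1.5)


class TestCategoricalImputation:
    def test_no_missing_nominals_is_identity(self, small_world):
        cfg = rd.ImputationConfig(m_mice=1)
        cohort = rd.add_missingness_indicators(small_world["cohort"])
        done = rd.run_mice(cohort, cfg)[0]
        out = rd.impute_categoricals(done, cohort.specs, cfg)
        pd.testing.assert_frame_equal(out.df, done.df)

    def test_imputed_frequencies_match_observed_under_mcar(self, big_world):
        cfg_g = rd.GeneratorConfig(n_cases=20000, n_hospitals=186, seed=11,
                                   missingness_mechanism="MCAR")
        obs = rd.inject_missingness(big_world["cohort"], cfg_g)
        obs = rd.add_missingness_indicators(obs)
        cfg = rd.ImputationConfig(m_mice=1, seed=6)
        done = rd.run_mice(obs, cfg)[0]
        out = rd.impute_categoricals(done, obs.specs, cfg)
        assert not out.df["indication"].isna().any()
        mask = obs.df["indication"].isna()
        obs_freq = obs.df["indication"].value_counts(normalize=True)
        imp_freq = out.df.loc[mask, "indication"].value_counts(normalize=True)
        for cat in obs_freq.index[:5]:
            assert abs(imp_freq.get(cat, 0) - obs_freq[cat]) < 0.03, cat

    def test_single_category_variable_fills_with_it(self, small_world):
        cfg = rd.ImputationConfig(m_mice=1, seed=1)
        cohort = rd.add_missingness_indicators(small_world["cohort"])
        cohort.df["malignancy"] = "none"
        cohort.df.loc[:10, "malignancy"] = np.nan
        done = rd.run_mice(cohort, cfg)[0]
        out = rd.impute_categoricals(done, cohort.specs, cfg)
        assert (out.df["malignancy"] == "none").all()


class TestLabImputers:
    def test_outcome_flag_controls_covariates(self, observed_prepared):
        prepared, thr = observed_prepared
        cfg = rd.ImputationConfig(m_mice=1, seed=3)
        done = rd.impute_categoricals(
            rd.run_mice(prepared, cfg)[0], prepared.specs, cfg)
        off = rd.fit_lab_imputer(done, "albumin", cfg, prepared.specs, thr)
        assert "died" not in off.model.info.spec.variables
        cfg_on = rd.ImputationConfig(m_mice=1, seed=3,
                                     include_outcome_in_lab=True)
        on = rd.fit_lab_imputer(done, "albumin", cfg_on, prepared.specs, thr)
        assert "died" in on.model.info.spec.variables

    def test_zero_variance_target_is_fit_error(self, observed_prepared):
        prepared, thr = observed_prepared
        cfg = rd.ImputationConfig(m_mice=1, seed=3)
        done = rd.impute_categoricals(
            rd.run_mice(prepared, cfg)[0], prepared.specs, cfg)
        done.df["albumin"] = 30.0
        with pytest.raises(rd.FitError):
            rd.fit_lab_imputer(done, "albumin", cfg, prepared.specs, thr)

    def test_linear_signal_recovered_at_noise_scale(self, small_world):
        """With albumin = linear(bun) + noise, held-out RMSE approaches the
        generative noise scale."""
        cohort = rd.add_missingness_indicators(small_world["cohort"].copy())
        rng = np.random.default_rng(5)
        noise_sd = 2.0
        cohort.df["albumin"] = (45.0 - 0.4 * cohort.df["bun"]
                                + rng.normal(0, noise_sd, len(cohort.df)))
        cfg = rd.ImputationConfig(m_mice=1, seed=3)
        train = rd.CompletedDataset(cohort.df.iloc[:2400].copy(), 0)
        model = rd.fit_lab_imputer(train, "albumin", cfg, cohort.specs)
        hold = cohort.df.iloc[2400:]
        pred = model.model.linear_predictor(hold)
        rmse = float(np.sqrt(np.mean((pred - hold["albumin"]) ** 2)))
        assert rmse < 1.1 * noise_sd
        assert rmse > 0.8 * noise_sd

    def test_draws_respect_observed_and_degenerate_posterior(
            self, observed_prepared):
        prepared, thr = observed_prepared
        cfg = rd.ImputationConfig(m_mice=1, seed=3)
        done = rd.impute_categoricals(
            rd.run_mice(prepared, cfg)[0], prepared.specs, cfg)
        model = rd.fit_lab_imputer(done, "albumin", cfg, prepared.specs, thr)
        draws = rd.draw_lab_imputations(model, done, 3, seed=1)
        assert len(draws) == 3
        mask = done.df["albumin"].notna()
        for d in draws:
            assert np.array_equal(d.df.loc[mask, "albumin"],
                                  done.df.loc[mask, "albumin"])
            assert not d.df["albumin"].isna().any()
        # degenerate posterior: no coefficient draw, no residual noise
        point = [rd.draw_lab_imputations(model, done, 1, seed=s,
                                         coefficient_uncertainty=False,
                                         residual_noise=False)[0]
                 for s in (1, 2)]
        pd.testing.assert_frame_equal(point[0].df, point[1].df)

    def test_coefficient_uncertainty_widens_draws(self, observed_prepared):
        prepared, thr = observed_prepared
        cfg = rd.ImputationConfig(m_mice=1, seed=3)
        done = rd.impute_categoricals(
            rd.run_mice(prepared, cfg)[0], prepared.specs, cfg)
        model = rd.fit_lab_imputer(done, "albumin", cfg, prepared.specs, thr)
        miss = done.df["albumin"].isna()
        k = 40

        def draw_var(coef_unc):
            ds = rd.draw_lab_imputations(model, done, k, seed=11,
                                         coefficient_uncertainty=coef_unc)
            vals = np.stack([d.df.loc[miss, "albumin"].to_numpy() for d in ds])
            return vals.var(axis=0).mean()

        assert draw_var(True) >= draw_var(False)

    def test_no_missing_targets_gives_identical_copies(self, small_world):
        cohort = rd.add_missingness_indicators(small_world["cohort"])
        cfg = rd.ImputationConfig(m_mice=1, seed=3)
        done = rd.CompletedDataset(cohort.df.copy(), 0)
        model = rd.fit_lab_imputer(done, "lactate", cfg, cohort.specs)
        draws = rd.draw_lab_imputations(model, done, 4, seed=2)
        for d in draws:
            pd.testing.assert_frame_equal(d.df, done.df)


class TestFullPipelineCounts:
    def test_total_completed_datasets_is_m_times_k(self, observed_prepared):
        prepared, thr = observed_prepared
        cfg = rd.ImputationConfig(m_mice=3, k_lab=2, seed=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            completed, pooled = rd.impute_cohort(prepared, cfg, thr)
        assert len(completed) == 6
        assert sorted(c.provenance for c in completed) == [
            (i, j) for i in range(3) for j in range(2)]
        assert set(pooled) == set(LAB_VARIABLES)
        for c in completed:
            assert not c.df[list(prepared.specs)].isna().any().any()

    def test_between_imputation_variance_zero_when_fully_observed(
            self, small_world):
        cohort = rd.add_missingness_indicators(small_world["cohort"])
        cfg = rd.ImputationConfig(m_mice=2, k_lab=2, seed=8)
        completed, _ = rd.impute_cohort(cohort, cfg)
        for c in completed[1:]:
            pd.testing.assert_frame_equal(c.df, completed[0].df)
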