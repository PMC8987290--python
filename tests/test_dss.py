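"""Decision support: classification, predictors, Gibbs sampler, pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spacersim import dss


class TestClassification:
    @pytest.mark.parametrize(
        "duo,sto,bow,th,expected",
        [
            (5.0, 20.0, 20.0, 10.0, "P1"),
            (5.0, 7.0, 20.0, 10.0, "P2"),
            (15.0, 7.0, 20.0, 10.0, "P3"),
            (15.0, 20.0, 20.0, 10.0, "P3"),
            (5.0, 20.0, 7.0, 10.0, "P2"),
        ],
    )
    def test_worked_cases(self, duo, sto, bow, th, expected):
        assert dss.classify_scenario(duo, sto, bow, th) == expected

    @given(
        st.floats(-50, 50), st.floats(-50, 50), st.floats(-50, 50), st.floats(-50, 50)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_partition_is_exhaustive_and_exclusive(self, duo, sto, bow, th):
        assert dss.classify_scenario(duo, sto, bow, th) in ("P1", "P2", "P3")


class TestNN:
    def test_exact_linear_targets_are_learned(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 20, (60, 3))
        y = 40.0 + 2.0 * x[:, 0] - 1.0 * x[:, 1] + 0.5 * x[:, 2]
        model = dss.train_maxbed_nn(x, y, seed=0)
        assert model.test_rmse_gy <= 0.5

    def test_rmse_brackets_the_noise_floor(self):
        rng = np.random.default_rng(1)
        sigma = 2.0
        x = rng.uniform(0, 20, (200, 3))
        y = 40.0 + 2.0 * x[:, 0] + rng.normal(0, sigma, 200)
        model = dss.train_maxbed_nn(x, y, seed=1)
        assert 0.5 * sigma <= model.test_rmse_gy <= 2.0 * sigma

    def test_same_seed_identical_weights(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 20, (40, 3))
        y = x.sum(axis=1)
        a = dss.train_maxbed_nn(x, y, seed=3)
        b = dss.train_maxbed_nn(x, y, seed=3)
        wa = a.pipeline.named_steps["mlpregressor"].coefs_
        wb = b.pipeline.named_steps["mlpregressor"].coefs_
        for u, v in zip(wa, wb):
            np.testing.assert_array_equal(u, v)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            dss.train_maxbed_nn(np.ones((10, 3)), np.ones(10))


class TestThresholdModel:
    def test_exact_inversion(self):
        x = np.linspace(0, 20, 12)
        model = dss.fit_threshold_model(x, 40.0 + 2.0 * x)
        mu, sd = model.l1cc_threshold(70.0)
        assert mu == pytest.approx(15.0)
        assert sd == pytest.approx(0.0, abs=1e-9)
        assert model.r_squared == pytest.approx(1.0)

    def test_threshold_increases_with_desired_bed(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 20, 30)
        y = 40 + 2 * x + rng.normal(0, 2, 30)
        model = dss.fit_threshold_model(x, y)
        assert model.l1cc_threshold(80.0)[0] > model.l1cc_threshold(60.0)[0]

    def test_negative_slope_flagged_unusable(self):
        x = np.linspace(0, 10, 10)
        model = dss.fit_threshold_model(x, 50.0 - 2.0 * x)
        assert not model.usable
        with pytest.raises(dss.UnusableThresholdModel):
            model.l1cc_threshold(70.0)


class TestGibbs:
    def test_diffuse_prior_matches_ols_within_one_percent(self):
        rng = np.random.default_rng(0)
        n = 500
        X = rng.integers(0, 2, n).astype(float)
        dl = rng.uniform(0, 10, n)
        y = 2.0 - 1.0 * X + 0.5 * dl + 0.3 * X * dl + rng.normal(0, 1, n)
        model = dss.fit_bayes_lm(X, dl, y, n_draws=10000, seed=1)
        D = np.column_stack([np.ones(n), X, dl, X * dl])
        ols = np.linalg.lstsq(D, y, rcond=None)[0]
        np.testing.assert_allclose(model.posterior_mean(), ols, rtol=0.01, atol=0.01)

    def test_recovery_within_three_posterior_sd(self):
        rng = np.random.default_rng(5)
        n = 200
        true = np.array([2.0, -1.0, 0.5, 0.3])
        X = rng.integers(0, 2, n).astype(float)
        dl = rng.uniform(0, 10, n)
        D = np.column_stack([np.ones(n), X, dl, X * dl])
        y = D @ true + rng.normal(0, 1, n)
        model = dss.fit_bayes_lm(X, dl, y, n_draws=5000, seed=2)
        mean = model.posterior_mean()
        sd = model.beta_draws.std(axis=0)
        assert np.all(np.abs(mean - true) <= 3 * sd)

    def test_rank_deficient_design_names_columns(self):
        n = 50
        X = np.ones(n)  # indicator constant -> collinear with intercept
        dl = np.linspace(0, 5, n)
        with pytest.raises(ValueError, match="collinear"):
            dss.fit_bayes_lm(X, dl, dl * 2, n_draws=10)

    def test_draw_count_as_configured(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, 30).astype(float)
        dl = rng.uniform(0, 5, 30)
        y = 1 + dl + rng.normal(0, 0.5, 30)
        model = dss.fit_bayes_lm(X, dl, y, n_draws=500, burn_in=100, seed=3)
        assert model.n_draws == 500
        assert np.all(model.sigma2_draws > 0)


def _degenerate_models(beta, th_mu):
    bayes = dss.BayesianSpacerModel(
        beta_draws=np.tile(beta, (100, 1)),
        sigma2_draws=np.full(100, 1e-20),
        n_obs=100,
        seed=0,
    )
    threshold = dss.ThresholdModel(
        intercept=40.0,
        slope=2.0,
        cov_params=np.zeros((2, 2)),
        dof=10,
        r_squared=1.0,
        usable=True,
    )
    # desired BED such that (bed - 40) / 2 == th_mu
    desired = 40.0 + 2.0 * th_mu
    return bayes, threshold, desired


class TestPrediction:
    def test_point_mass_limit_reproduces_linear_form(self):
        beta = np.array([3.0, -1.0, 0.8, 0.2])
        bayes, threshold, desired = _degenerate_models(beta, th_mu=12.0)
        pre = 7.0  # dl = 5
        out = dss.predict_delta_maxbed(bayes, "P1", threshold, pre, desired, seed=0)
        assert out["mle_gy"] == pytest.approx(3.0 + 0.8 * 5.0, abs=1e-6)
        out2 = dss.predict_delta_maxbed(bayes, "P2", threshold, pre, desired, seed=0)
        assert out2["mle_gy"] == pytest.approx((3.0 - 1.0) + (0.8 + 0.2) * 5.0, abs=1e-6)

    def test_clamped_when_already_separated(self):
        beta = np.array([3.0, -1.0, 0.8, 0.2])
        bayes, threshold, desired = _degenerate_models(beta, th_mu=6.0)
        out = dss.predict_delta_maxbed(bayes, "P1", threshold, 10.0, desired, seed=0)
        assert out["mle_gy"] == pytest.approx(3.0, abs=1e-6)  # dl clamps to 0

    def test_less_separation_needs_more_gain(self):
        rng = np.random.default_rng(0)
        n = 300
        X = rng.integers(0, 2, n).astype(float)
        dl = rng.uniform(0, 10, n)
        y = 2.0 + 1.5 * dl + rng.normal(0, 1.0, n)
        bayes = dss.fit_bayes_lm(X, dl, y, n_draws=4000, seed=1)
        threshold = dss.fit_threshold_model(
            np.linspace(0, 20, 30), 40 + 2 * np.linspace(0, 20, 30)
        )
        lo = dss.predict_delta_maxbed(bayes, "P1", threshold, 4.0, 70.0, seed=2)
        hi = dss.predict_delta_maxbed(bayes, "P1", threshold, 12.0, 70.0, seed=2)
        assert lo["mle_gy"] > hi["mle_gy"]

    def test_p3_short_circuits_to_zero(self):
        beta = np.array([3.0, -1.0, 0.8, 0.2])
        bayes, threshold, desired = _degenerate_models(beta, 12.0)
        out = dss.predict_delta_maxbed(bayes, "P3", threshold, 5.0, desired)
        assert out["mle_gy"] == 0.0 and not out["beneficial"]


class TestPipeline:
    def _models(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 20, (40, 3))
        y = 40.0 + 2.0 * x.min(axis=1)
        nn = dss.train_maxbed_nn(x, y, seed=0)
        threshold = dss.fit_threshold_model(x.min(axis=1), y)
        n = 200
        X = rng.integers(0, 2, n).astype(float)
        dl = rng.uniform(0, 10, n)
        yy = 2 + 1.2 * dl - 0.5 * X + rng.normal(0, 1, n)
        bayes = dss.fit_bayes_lm(X, dl, yy, n_draws=3000, seed=1)
        return nn, threshold, bayes

    def test_p3_case_reports_not_beneficial(self):
        nn, threshold, bayes = self._models()
        report = dss.dss_pipeline(
            {"duodenum": 30.0, "stomach": 2.0, "bowel": 25.0},
            {"D1D2": 30.0, "D3": 30.0, "D4": 30.0},
            nn, threshold, bayes, desired_bed_gy=90.0,
        )
        assert report["scenario_class"] == "P3"
        assert report["predicted_delta_maxbed"]["mle_gy"] == 0.0
        assert "not beneficial" in report["verdict"]

    def test_well_separated_case_needs_no_spacer(self):
        nn, threshold, bayes = self._models()
        report = dss.dss_pipeline(
            {"duodenum": 19.0, "stomach": 19.0, "bowel": 19.0},
            {"D1D2": 19.0, "D3": 19.0, "D4": 19.0},
            nn, threshold, bayes, desired_bed_gy=60.0,
        )
        assert report["verdict"].startswith("spacer unnecessary")
        assert report["predicted_delta_maxbed"] is None

    def test_d1d2_only_case_recommends_s1(self):
        nn, threshold, bayes = self._models()
        report = dss.dss_pipeline(
            {"duodenum": 4.0, "stomach": 25.0, "bowel": 25.0},
            {"D1D2": 4.0, "D3": 20.0, "D4": 22.0},
            nn, threshold, bayes, desired_bed_gy=70.0,
        )
        assert report["scenario_class"] == "P1"
        assert report["recommended_scenario"] == "S1"

    @pytest.mark.parametrize(
        "sections,expected",
        [
            ({"D1D2": 3.0, "D3": 3.0, "D4": 20.0}, "S2"),
            ({"D1D2": 3.0, "D3": 20.0, "D4": 3.0}, "S3"),
            ({"D1D2": 20.0, "D3": 20.0, "D4": 20.0}, None),
        ],
    )
    def test_scenario_recommendation_covers_limiting_sections(self, sections, expected):
        assert dss.recommend_scenario(sections, 10.0) == expected
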