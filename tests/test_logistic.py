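"""Covariate encoding and logistic maximum likelihood against closed forms
and an independent GLM implementation."""

import numpy as np
import pandas as pd
import pytest

from radonrisk import DesignSpec, encode_covariates, fit_logistic, wald_or_ci
from radonrisk.logistic import LogisticFit, SeparationError, bernoulli_loglik


def _mini_cohort() -> pd.DataFrame:
    """Six hand-written subjects across two sites."""
    return pd.DataFrame(
        {
            "id": range(6),
            "is_case": [1, 0, 1, 0, 1, 0],
            "site": ["A", "A", "A", "B", "B", "B"],
            "sex": ["male", "female", "male", "female", "male", "female"],
            "age": [65.0, 55.0, 70.0, 60.0, 50.0, 80.0],
            "smoking_status": ["never", "former", "current", "never", "former", "current"],
            "age_start_smoking": [0.0, 18.0, 16.0, 0.0, 20.0, 15.0],
            "years_since_quit": [0.0, 10.0, 0.0, 0.0, 5.0, 0.0],
            "pack_years": [0.0, 20.0, 40.0, 0.0, 10.0, 55.0],
            "histology": ["AdenoLC", "", "SCLC", "", "SqCLC", ""],
            "sir": [30.0, 60.0, 90.0, 45.0, 120.0, 70.0],
        }
    )


class TestEncodeCovariates:
    def test_matrix_matches_hand_encoding(self):
        X, y = encode_covariates(_mini_cohort())
        expected = pd.DataFrame(
            {
                "site_A": [1.0, 1, 1, 0, 0, 0],
                "site_B": [0.0, 0, 0, 1, 1, 1],
                "male": [1.0, 0, 1, 0, 1, 0],
                "age_c60": [5.0, -5, 10, 0, -10, 20],
                "smoke_former": [0.0, 1, 0, 0, 1, 0],
                "smoke_current": [0.0, 0, 1, 0, 0, 1],
                "age_start_smoking": [0.0, 18, 16, 0, 20, 15],
                "years_since_quit": [0.0, 10, 0, 0, 5, 0],
                "pack_years": [0.0, 20, 40, 0, 10, 55],
            }
        )
        pd.testing.assert_frame_equal(X, expected, check_like=False)
        assert list(y) == [1, 0, 1, 0, 1, 0]

    def test_site_block_is_exclusive_indicator(self):
        X, _ = encode_covariates(_mini_cohort())
        site_block = X[["site_A", "site_B"]].to_numpy()
        assert np.all(site_block.sum(axis=1) == 1.0)

    def test_never_smoker_reference_coding(self):
        X, _ = encode_covariates(_mini_cohort())
        never_rows = X.iloc[[0, 3]]
        assert (never_rows[["smoke_former", "smoke_current", "pack_years",
                            "age_start_smoking"]] == 0).all().all()

    def test_single_class_site_raises_naming_site(self):
        frame = _mini_cohort()
        frame.loc[frame["site"] == "B", "is_case"] = 1
        with pytest.raises(SeparationError, match="'B'"):
            encode_covariates(frame)

    def test_adjustment_subset(self):
        X, _ = encode_covariates(_mini_cohort(), DesignSpec(adjust=("sex", "age")))
        assert list(X.columns) == ["site_A", "site_B", "male", "age_c60"]


def _randomized_cohort(n_copies: int, seed: int) -> pd.DataFrame:
    """Replicated mini cohort with jittered continuous covariates and a
    random outcome, so the full design is comfortably full rank."""
    big = pd.concat([_mini_cohort()] * n_copies, ignore_index=True)
    big["id"] = range(len(big))
    rng = np.random.default_rng(seed)
    n = len(big)
    big["age"] = big["age"] + rng.normal(0, 3, n)
    ever = big["smoking_status"] != "never"
    big.loc[ever, "age_start_smoking"] += rng.uniform(-2, 2, int(ever.sum()))
    former = big["smoking_status"] == "former"
    big.loc[former, "years_since_quit"] += rng.uniform(0, 5, int(former.sum()))
    big.loc[ever, "pack_years"] += rng.uniform(0, 10, int(ever.sum()))
    big["is_case"] = (rng.random(n) < 0.5).astype(int)
    return big


def _expand_2x2(n11, n10, n01, n00):
    """cases/controls exposed (x=1) then unexposed (x=0)."""
    x = np.r_[np.ones(n11 + n10), np.zeros(n01 + n00)]
    y = np.r_[np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)]
    X = pd.DataFrame({"const": np.ones_like(x), "exposed": x})
    return X, y.astype(int)


class TestFitLogistic:
    def test_2x2_slope_equals_log_cross_product(self):
        # printed bin counts: 200-<250 (75 cases/30 controls) vs
        # 50-<75 (3171/2195)
        X, y = _expand_2x2(75, 30, 3171, 2195)
        fit = fit_logistic(X, y)
        expected = np.log((75 * 2195) / (30 * 3171))
        assert fit.params["exposed"] == pytest.approx(expected, abs=1e-5)
        assert np.exp(fit.params["exposed"]) == pytest.approx(1.7306, abs=2e-4)

    def test_loglik_matches_independent_reevaluation(self):
        X, y = encode_covariates(_mini_cohort(), DesignSpec(adjust=("sex", "age")))
        fit = fit_logistic(X, y)
        eta = X.to_numpy() @ fit.params.to_numpy()
        assert fit.loglik == pytest.approx(bernoulli_loglik(y, eta), rel=1e-12)
        ll_hand = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        assert fit.loglik == pytest.approx(ll_hand, rel=1e-9)

    def test_aic_identity(self):
        X, y = _expand_2x2(40, 25, 60, 80)
        fit = fit_logistic(X, y)
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik, abs=1e-10)

    def test_constant_response_raises(self):
        X = pd.DataFrame({"const": np.ones(10)})
        with pytest.raises(SeparationError):
            fit_logistic(X, np.ones(10, int))

    def test_rank_deficiency_raises(self):
        X = pd.DataFrame({"a": np.arange(10.0), "b": 2 * np.arange(10.0)})
        with pytest.raises(np.linalg.LinAlgError):
            fit_logistic(X, np.r_[np.ones(5, int), np.zeros(5, int)])

    def test_separation_flagged(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.astype(int)  # perfectly separated
        X = pd.DataFrame({"const": np.ones(20), "x": x})
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_logistic(X, y)
        assert fit.separation

    def test_matches_statsmodels_glm(self):
        sm = pytest.importorskip("statsmodels.api")
        big = _randomized_cohort(n_copies=20, seed=0)
        X, y = encode_covariates(big)
        fit = fit_logistic(X, y)
        ref = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params, atol=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)
        np.testing.assert_allclose(
            fit.cov.to_numpy(), ref.cov_params(), rtol=1e-4, atol=1e-8
        )

    def test_offset_shifts_linear_predictor(self):
        sm = pytest.importorskip("statsmodels.api")
        X, y = _expand_2x2(50, 40, 30, 60)
        off = np.linspace(-0.5, 0.5, len(y))
        fit = fit_logistic(X, y, offset=off)
        ref = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial(), offset=off).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params, atol=1e-6)

    def test_age_shift_moves_only_intercepts(self):
        big = _randomized_cohort(n_copies=30, seed=3)
        X1, y = encode_covariates(big)
        fit1 = fit_logistic(X1, y)
        shifted = big.copy()
        shifted["age"] = shifted["age"] + 10.0
        X2, _ = encode_covariates(shifted)
        fit2 = fit_logistic(X2, y)
        non_intercept = [c for c in X1.columns if not c.startswith("site_")]
        np.testing.assert_allclose(
            fit1.params[non_intercept], fit2.params[non_intercept], atol=1e-6
        )

    def test_saturated_2x2_or_equals_cross_product_exactly(self):
        X, y = _expand_2x2(12, 7, 9, 16)
        fit = fit_logistic(X, y)
        assert np.exp(fit.params["exposed"]) == pytest.approx((12 * 16) / (7 * 9), rel=1e-7)


class TestWaldOrCi:
    def _fit(self, est=0.54839, se=0.1):
        return LogisticFit(
            params=pd.Series([est], index=["x"]),
            cov=pd.DataFrame([[se ** 2]], index=["x"], columns=["x"]),
            loglik=0.0, aic=2.0, n_params=1, converged=True, separation=False,
            n_iter=1, n_obs=10,
        )

    def test_hand_arithmetic_interval(self):
        orr, lo, hi, p = wald_or_ci(self._fit(), [1.0])
        assert orr == pytest.approx(np.exp(0.54839), rel=1e-9)
        # hand arithmetic: exp(0.54839 -/+ 1.959964 * 0.1) = (1.4225, 2.1051)
        assert lo == pytest.approx(np.exp(0.54839 - 1.959964 * 0.1), rel=1e-6)
        assert hi == pytest.approx(np.exp(0.54839 + 1.959964 * 0.1), rel=1e-6)
        assert (lo, hi) == pytest.approx((1.423, 2.104), abs=2e-3)
        assert p < 0.0001

    def test_zero_contrast_degenerate(self):
        orr, lo, hi, p = wald_or_ci(self._fit(), [0.0])
        assert (orr, lo, hi) == (1.0, 1.0, 1.0)

    @pytest.mark.parametrize("level", [0.0, 1.0, -0.5, 1.5])
    def test_invalid_level_raises(self, level):
        with pytest.raises(ValueError):
            wald_or_ci(self._fit(), [1.0], level=level)
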