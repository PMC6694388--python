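"""GLM core: closed-form limits, likelihood oracles, statsmodels
cross-check, and the comparison metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import payrisk as pr
from payrisk.glm import ConvergenceError


def empty_X(n):
    return pd.DataFrame(index=range(n))


class TestFit:
    @pytest.mark.parametrize("spec", list(pr.DEFAULT_SPECS.values()),
                             ids=lambda s: f"{s.family}-{s.link}")
    def test_intercept_only_fitted_mean_is_sample_mean(self, spec):
        """All three family/link pairs share the score equation
        sum(y - mu) = 0 under an intercept-only model."""
        y = np.array([1.0, 2.0, 3.0])
        fit = pr.fit_glm(empty_X(3), y, spec)
        mean = fit.predict(empty_X(3))[0]
        assert mean == pytest.approx(2.0, rel=1e-10)
        if spec.link == "log":
            assert fit.params["const"] == pytest.approx(math.log(2.0))
        else:
            assert fit.params["const"] == pytest.approx(2.0)

    def test_duplicate_column_raises_rank_error(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.random(50)})
        X["b"] = X["a"]
        y = rng.gamma(2.0, 100.0, 50) + 1
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            pr.fit_glm(X, y, pr.GLMSpec("gamma", "log"))

    def test_gamma_log_matches_statsmodels(self):
        """Independent IRLS implementation agrees with statsmodels on
        coefficients and standard errors."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(4)
        n = 2_000
        X = pd.DataFrame({"x1": rng.binomial(1, 0.3, n).astype(float),
                          "x2": rng.normal(0, 1, n)})
        mu = np.exp(8.0 + 0.4 * X["x1"] - 0.2 * X["x2"])
        y = rng.gamma(2.0, mu / 2.0)
        ours = pr.fit_glm(X, y, pr.GLMSpec("gamma", "log"))
        ref = sm.GLM(
            y, sm.add_constant(X),
            family=sm.families.Gamma(link=sm.families.links.Log()),
        ).fit()
        np.testing.assert_allclose(ours.params.to_numpy(),
                                   ref.params.to_numpy(), rtol=1e-6)
        np.testing.assert_allclose(ours.bse.to_numpy(),
                                   ref.bse.to_numpy(), rtol=1e-4)
        assert ours.dispersion == pytest.approx(ref.scale, rel=1e-6)

    def test_identity_link_stays_positive(self):
        """Step-halving keeps identity-link Gamma means positive on data
        engineered to push a naive Newton step below zero."""
        rng = np.random.default_rng(9)
        n = 500
        x = rng.binomial(1, 0.5, n).astype(float)
        mu = 200.0 + 4_000.0 * x
        y = rng.gamma(1.0 / 0.8, 0.8 * mu)
        fit = pr.fit_glm(pd.DataFrame({"x": x}), y,
                         pr.GLMSpec("gamma", "identity"))
        assert (fit.predict(pd.DataFrame({"x": x})) > 0).all()
        assert fit.converged

    def test_nonpositive_outcome_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pr.fit_glm(empty_X(3), np.array([1.0, 0.0, 2.0]),
                       pr.GLMSpec("gamma", "log"))

    def test_coefficient_recovery_gamma_log(self, hf_bundle_5k, hf_cohort_5k):
        """Fitted coefficients land within 3 reported SEs of the
        generator's truth (no hospital heterogeneity)."""
        b, coh = hf_bundle_5k, hf_cohort_5k
        d = pr.build_design(coh, b,
                            pr.Scheme("codes_index_history",
                                      pr.CodeMaps(code_to_cc={})))
        fit = pr.fit_glm(d.X.astype(float), coh["payment_w"],
                         pr.DEFAULT_SPECS["HF"])
        tb = b.truth.true_beta["HF"]
        truth = {"const": tb.intercept, "age_75_84": tb.age_75_84,
                 "age_85p": tb.age_85p}
        truth.update({f"{c}__{ch}": v
                      for (c, ch), v in tb.code_effects.items()})
        for k, v in truth.items():
            assert abs(fit.params[k] - v) < 3 * fit.bse[k], k


class TestLoglik:
    def test_gamma_exponential_closed_form(self):
        spec = pr.GLMSpec("gamma", "log")
        assert pr.loglik(spec, [1.0], [1.0], 1.0) == pytest.approx(-1.0)

    def test_inverse_gaussian_at_mean_closed_form(self):
        spec = pr.GLMSpec("inverse_gaussian", "log")
        y, phi = 3.0, 0.4
        expected = -0.5 * math.log(2 * math.pi * phi * y ** 3)
        assert pr.loglik(spec, [y], [y], phi) == pytest.approx(expected,
                                                               rel=1e-12)

    def test_matches_scipy_density_summation(self):
        """Brute-force oracle: sum scipy logpdfs on a 5-row fixture."""
        y = np.array([120.0, 85.0, 310.0, 55.0, 190.0])
        mu = np.array([100.0, 100.0, 250.0, 70.0, 150.0])
        phi = 0.6
        ours = pr.loglik(pr.GLMSpec("gamma", "log"), y, mu, phi)
        oracle = stats.gamma.logpdf(y, a=1 / phi, scale=phi * mu).sum()
        assert ours == pytest.approx(oracle, rel=1e-10)

        phi_ig = 0.002
        ours_ig = pr.loglik(pr.GLMSpec("inverse_gaussian", "log"), y, mu,
                            phi_ig)
        # scipy's invgauss(mu=m, scale=s) has mean m*s and lambda = s
        oracle_ig = stats.invgauss.logpdf(
            y, mu=mu * phi_ig, scale=1 / phi_ig).sum()
        assert ours_ig == pytest.approx(oracle_ig, rel=1e-10)


class TestPseudoR2:
    def test_null_model_is_zero(self):
        y = np.array([10.0, 20.0, 15.0, 40.0])
        fit = pr.fit_glm(empty_X(4), y, pr.GLMSpec("gamma", "log"))
        assert pr.pseudo_r2(fit) == pytest.approx(0.0, abs=1e-12)

    def test_nested_models_monotone(self):
        rng = np.random.default_rng(2)
        n = 3_000
        X = pd.DataFrame({"x1": rng.binomial(1, 0.4, n).astype(float),
                          "x2": rng.binomial(1, 0.2, n).astype(float)})
        mu = np.exp(9.0 + 0.5 * X["x1"] + 0.3 * X["x2"])
        y = rng.gamma(2.0, mu / 2.0)
        small = pr.fit_glm(X[["x1"]], y, pr.GLMSpec("gamma", "log"))
        big = pr.fit_glm(X, y, pr.GLMSpec("gamma", "log"))
        assert pr.pseudo_r2(big) >= pr.pseudo_r2(small)

    def test_matches_hand_computed_ratio(self):
        rng = np.random.default_rng(5)
        n = 400
        X = pd.DataFrame({"x": rng.binomial(1, 0.5, n).astype(float)})
        y = rng.gamma(2.0, np.exp(8.0 + 0.6 * X["x"]) / 2.0)
        fit = pr.fit_glm(X, y, pr.GLMSpec("gamma", "log"))
        mu = fit.predict(X)
        l1 = pr.loglik(fit.spec, y, mu, fit.dispersion)
        l0 = pr.loglik(fit.spec, y, float(y.mean()), fit.dispersion)
        assert pr.pseudo_r2(fit) == pytest.approx(1 - l1 / l0, rel=1e-10)

    def test_likelihood_ratio_invariant_to_outcome_rescaling(self):
        """Under y -> c*y with a log link, both log-likelihoods shift by
        -n*ln(c), so the model-null difference is exactly invariant (and
        slope coefficients are unchanged)."""
        rng = np.random.default_rng(6)
        n = 500
        X = pd.DataFrame({"x": rng.binomial(1, 0.5, n).astype(float)})
        y = rng.gamma(2.0, np.exp(8.0 + 0.5 * X["x"]) / 2.0)
        f1 = pr.fit_glm(X, y, pr.GLMSpec("gamma", "log"))
        f2 = pr.fit_glm(X, 3.5 * y, pr.GLMSpec("gamma", "log"))
        assert f2.params["x"] == pytest.approx(f1.params["x"], rel=1e-8)
        d1 = f1.loglik - f1.null_loglik
        d2 = f2.loglik - f2.null_loglik
        assert d2 == pytest.approx(d1, rel=1e-8)


class TestRmse:
    def test_exact_cases_and_oracle(self):
        assert pr.rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert pr.rmse([1.0, 3.0], [2.0, 2.0]) == 1.0
        rng = np.random.default_rng(1)
        p, a = rng.random(100), rng.random(100)
        assert pr.rmse(p, a) == pytest.approx(
            math.sqrt(np.mean((p - a) ** 2)), rel=1e-12)
        with pytest.raises(ValueError):
            pr.rmse([1.0], [1.0, 2.0])
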