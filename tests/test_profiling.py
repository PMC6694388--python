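"""Hierarchical GLM, RSP identities, bootstrap, categorization and the
category-shift accounting."""

import numpy as np
import pandas as pd
import pytest

import payrisk as pr
from payrisk.profiling import CATEGORIES


@pytest.fixture(scope="module")
def hier_data(hf_bundle_5k, hf_cohort_5k, toy_maps):
    d = pr.build_design(hf_cohort_5k, hf_bundle_5k,
                        pr.Scheme("hcc_pooled", toy_maps))
    return (d.X.astype(float), hf_cohort_5k["payment_w"].to_numpy(),
            hf_cohort_5k["hospital_id"].to_numpy())


class TestHierarchicalFit:
    def test_tau_zero_generator_shrinks_alpha(self, hier_data):
        """The shared bundle has no hospital heterogeneity: tau-hat is
        near 0 and the shrunken intercepts are pinned near 0."""
        X, y, h = hier_data
        fit = pr.fit_hierarchical(X, y, h, pr.DEFAULT_SPECS["HF"])
        assert fit.tau < 0.05
        assert np.max(np.abs(fit.alpha)) < 0.05

    def test_single_hospital_rejected(self, hier_data):
        X, y, _ = hier_data
        with pytest.raises(ValueError, match="2 hospitals"):
            pr.fit_hierarchical(X, y, np.ones(len(y)), pr.DEFAULT_SPECS["HF"])

    def test_beta_recovery_with_random_intercepts(self):
        """tau and the fixed effects are recovered on a generator with
        true hospital effects (smaller-scale companion of the acceptance
        check)."""
        cfg = pr.SimConfig(
            n_patients=6_000, n_hospitals=60, seed=55,
            condition_mix={"HF": 1.0},
            hospital_volume_dist={"fixed": 100}, re_sd=0.2,
            code_catalog=pr.make_catalog(poa_all_yes=True),
            frac_short_enrollment=0.0, frac_under_65=0.0,
        )
        b = pr.generate_bundle(cfg)
        coh = pr.build_cohort(b, "HF", winsor_q=1.0)
        d = pr.build_design(coh, b, pr.Scheme("hcc_separate",
                                              pr.load_toy_maps()))
        fit = pr.fit_hierarchical(d.X.astype(float),
                                  coh["payment_w"].to_numpy(),
                                  coh["hospital_id"].to_numpy(),
                                  pr.DEFAULT_SPECS["HF"])
        assert 0.12 < fit.tau < 0.28
        tb = b.truth.true_beta["HF"]
        assert abs(fit.beta["const"] - tb.intercept) < 0.1


class TestRsp:
    def test_zero_alpha_gives_national_mean(self, hier_data):
        X, y, h = hier_data
        fit = pr.fit_hierarchical(X, y, h, pr.DEFAULT_SPECS["HF"])
        fit.alpha[:] = 0.0
        prof = pr.rsp(fit, X, h, national_mean=17_000.0)
        assert np.allclose(prof["rsp"], 17_000.0)

    def test_log_link_ratio_is_exp_alpha(self, hier_data):
        """Multiplicative link identity: P/E = exp(alpha) regardless of
        case mix."""
        X, y, h = hier_data
        fit = pr.fit_hierarchical(X, y, h, pr.DEFAULT_SPECS["HF"])
        fit.alpha[:] = np.log(1.1)
        prof = pr.rsp(fit, X, h, national_mean=10_000.0)
        assert np.allclose(prof["rsp"], 11_000.0)

    def test_identity_link_matches_hand_summed_oracle(self):
        """2 hospitals x 3 cases with printed coefficients."""
        X = pd.DataFrame({"x": [1.0, 0.0, 1.0, 0.0, 0.0, 1.0]})
        h = np.array([1, 1, 1, 2, 2, 2])
        fit = pr.HierFit(
            spec=pr.GLMSpec("gamma", "identity"),
            beta=pd.Series({"const": 100.0, "x": 50.0}),
            alpha=pd.Series({1: 20.0, 2: -10.0}),
            tau=15.0, dispersion=0.3, n_iter=1, converged=True,
        )
        prof = pr.rsp(fit, X, h, national_mean=120.0)
        # hospital 1: pred (170,120,170)=460, exp (150,100,150)=400
        assert prof.loc[1, "predicted"] == pytest.approx(460.0)
        assert prof.loc[1, "expected"] == pytest.approx(400.0)
        assert prof.loc[1, "rsp"] == pytest.approx(460 / 400 * 120)
        # hospital 2: pred (90,90,140)=320, exp (100,100,150)=350
        assert prof.loc[2, "rsp"] == pytest.approx(320 / 350 * 120)

    def test_e_weighted_rsp_recovers_national_mean(self, hier_data):
        """Calibration: sum(P) tracks sum(y), so the E-weighted mean RSP
        equals the national mean within 1%."""
        X, y, h = hier_data
        fit = pr.fit_hierarchical(X, y, h, pr.DEFAULT_SPECS["HF"])
        nm = float(np.mean(y))
        prof = pr.rsp(fit, X, h, nm)
        weighted = float(np.average(prof["rsp"], weights=prof["expected"]))
        assert weighted == pytest.approx(nm, rel=0.01)


class TestBootstrap:
    def test_two_replicates_hit_min_max(self, hier_data):
        X, y, h = hier_data
        ci = pr.bootstrap_ci(pd.DataFrame(X), y, h, pr.DEFAULT_SPECS["HF"],
                             n_boot=2, seed=5)
        sampled = ci[ci["n_draws"] >= 2]
        assert len(sampled) > 0
        with pytest.raises(ValueError):
            pr.bootstrap_ci(pd.DataFrame(X), y, h, pr.DEFAULT_SPECS["HF"],
                            n_boot=1)

    def test_deterministic_given_seed(self, hier_data):
        X, y, h = hier_data
        kw = dict(spec=pr.DEFAULT_SPECS["HF"], n_boot=8, seed=3)
        a = pr.bootstrap_ci(pd.DataFrame(X), y, h, **kw)
        b = pr.bootstrap_ci(pd.DataFrame(X), y, h, **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_never_sampled_hospital_left_uncategorized(self, hier_data):
        X, y, h = hier_data
        ci = pr.bootstrap_ci(pd.DataFrame(X), y, h, pr.DEFAULT_SPECS["HF"],
                             n_boot=2, seed=5)
        prof = pd.DataFrame({
            "n_cases": 100, "rsp": 17_000.0,
            "ci_lower": ci["ci_lower"], "ci_upper": ci["ci_upper"],
        })
        out = pr.categorize(prof, national_mean=17_000.0)
        missing = ci["n_draws"] == 0
        if missing.any():
            assert out.loc[missing, "category"].isna().all()


class TestCategorize:
    def make_prof(self, n_cases, lo, hi):
        return pd.DataFrame({"n_cases": [n_cases], "rsp": [(lo + hi) / 2],
                             "ci_lower": [lo], "ci_upper": [hi]})

    @pytest.mark.parametrize("lo,hi,expect", [
        (1.02, 1.10, "higher"),
        (0.90, 0.95, "lower"),
        (0.95, 1.05, "no_different"),
        (1.00, 1.10, "no_different"),  # CI touching the mean is not above it
    ])
    def test_rules(self, lo, hi, expect):
        m = 10_000.0
        prof = self.make_prof(40, lo * m, hi * m)
        out = pr.categorize(prof, m)
        assert out["category"].iloc[0] == expect

    def test_below_25_cases_uncategorized(self):
        prof = self.make_prof(24, 10_200.0, 11_000.0)
        out = pr.categorize(prof, 10_000.0)
        assert pd.isna(out["category"].iloc[0])
        assert not out["eligible"].iloc[0]


class TestShiftTable:
    def test_identical_categorizations_are_diagonal(self):
        cats = pd.Series(["lower", "higher", "no_different"] * 4,
                         index=range(12))
        tab = pr.shift_table(cats, cats)
        assert tab.pct_reclassified == 0.0
        assert np.trace(tab.counts.to_numpy()) == 12

    def test_mismatched_hospital_sets_rejected(self):
        a = pd.Series(["lower"], index=[1])
        b = pd.Series(["lower"], index=[2])
        with pytest.raises(ValueError, match="differ"):
            pr.shift_table(a, b)

    def test_accounting_identity_on_random_tables(self):
        """Column sums of the shift table are model-B category counts:
        model-A counts plus net shifts, exactly."""
        rng = np.random.default_rng(0)
        cats_a = pd.Series(rng.choice(CATEGORIES, 200), index=range(200))
        cats_b = pd.Series(rng.choice(CATEGORIES, 200), index=range(200))
        tab = pr.shift_table(cats_a, cats_b)
        for c in CATEGORIES:
            assert tab.model_b_counts[c] == (cats_b == c).sum()
            assert tab.model_a_counts[c] == (cats_a == c).sum()

    def test_infer_extreme_shifts_consistency(self):
        lh, hl = pr.infer_extreme_shifts(
            lower_a=100, lower_b=110, lower_to_no=20, no_to_lower=24,
            extreme_total=6)
        assert (lh, hl) == (0, 6)
        with pytest.raises(ValueError):
            pr.infer_extreme_shifts(100, 200, 0, 0, extreme_total=4)
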