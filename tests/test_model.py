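import numpy as np
import pytest

import bayesnma as bn
from bayesnma.model import (ModelSpec, arm_loglik, build_design, build_model,
                            direct_pairs, inverse_link,
                            sample_delta_conditional)


@pytest.fixture(scope="module")
def six_treatment_network():
    """22 studies over 6 treatments, cloglog-compatible (has follow-up)."""
    cfg = bn.FixtureConfig(T=6, M=22, family="dichotomous", link="cloglog",
                           d=(0, -0.1, -0.2, -0.3, -0.4, -0.5), sigma=0.1,
                           follow_up=4.0, baseline_mean=-3.0,
                           arms_per_study=(0.8, 0.2), seed=21)
    nd, _ = bn.generate_synthetic_network(cfg)
    return nd


class TestReferenceScale:
    def test_single_trial_log_or(self, single_trial_network):
        u = bn.compute_reference_scale(single_trial_network, "logit")
        assert u == pytest.approx(np.log((20 / 80) / (10 / 90)), abs=1e-12)
        assert u == pytest.approx(0.8109, abs=1e-4)

    def test_degenerate_network_falls_back_to_one(self):
        rows = [dict(study="S1", treatment=t, events=5, sample_size=50)
                for t in "AB"]
        nd = bn.prepare_network(rows, "dichotomous")
        with pytest.warns(UserWarning, match="u = 1"):
            assert bn.compute_reference_scale(nd, "logit") == 1.0

    def test_max_is_monotone_in_added_trials(self, single_trial_network):
        u1 = bn.compute_reference_scale(single_trial_network, "logit")
        rows = single_trial_network.to_frame().to_dict(orient="records")
        rows += [dict(study="S2", treatment="A", events=10, sample_size=100),
                 dict(study="S2", treatment="B", events=11, sample_size=100)]
        nd = bn.prepare_network(rows, "dichotomous")
        assert bn.compute_reference_scale(nd, "logit") == pytest.approx(u1)

    def test_zero_cell_correction(self):
        rows = [dict(study="S1", treatment="A", events=0, sample_size=10),
                dict(study="S1", treatment="B", events=5, sample_size=10)]
        nd = bn.prepare_network(rows, "dichotomous")
        u = bn.compute_reference_scale(nd, "logit")
        assert np.isfinite(u) and u > 0


class TestDefaultPriors:
    def test_fifteen_u_scaling(self, single_trial_network):
        spec = ModelSpec("binomial", "logit", effects="random")
        pr = bn.default_priors(single_trial_network, spec)
        assert pr.mu_sd == pytest.approx(15 * 0.8109, abs=1e-3)
        assert pr.d_sd == pytest.approx(15 * pr.u)
        assert pr.sigma_upper == pytest.approx(pr.u)

    def test_binomial_log_uses_uniform_baseline(self):
        rows = [dict(study="S1", treatment="A", events=5, sample_size=50),
                dict(study="S1", treatment="B", events=10, sample_size=50)]
        nd = bn.prepare_network(rows, "dichotomous")
        pr = bn.default_priors(nd, ModelSpec("binomial", "log"))
        assert pr.mu_log_baseline

    def test_nonfinite_override_rejected(self, single_trial_network):
        spec = ModelSpec("binomial", "logit",
                         priors={"d_sd": float("inf")})
        with pytest.raises(ValueError, match="finite"):
            bn.default_priors(single_trial_network, spec)

    def test_inconsistency_prior_per_direct_pair(self):
        rows = []
        for s, pair in [("S1", "AB"), ("S2", "AC"), ("S3", "BC"),
                        ("S4", "AD"), ("S5", "BD"), ("S6", "CD")]:
            for t in pair:
                rows.append(dict(study=s, treatment=t, events=5,
                                 sample_size=50))
        nd = bn.prepare_network(rows, "dichotomous")
        model = build_model(nd, ModelSpec("binomial", "logit",
                                          model_type="inconsistency"))
        assert model.n_d == 6


class TestLinearPredictor:
    def test_cloglog_offset_arithmetic(self):
        theta = bn.linear_predictor(-3.0, 0.5, link="cloglog",
                                    family="binomial", f=2.0)
        assert theta == pytest.approx(np.log(2.0) - 2.5)
        assert theta == pytest.approx(-1.8069, abs=1e-4)

    def test_log_link_truncation_keeps_probability_below_one(self):
        theta = bn.linear_predictor(0.3, 0.2, link="log", family="binomial")
        assert theta == -1e-16
        assert inverse_link(theta, "log") < 1.0

    def test_covariate_contribution(self):
        theta = bn.linear_predictor(0.0, 0.5, link="logit",
                                    family="binomial", beta_contrast=0.2,
                                    x=67.0, xbar=57.0)
        assert theta == pytest.approx(2.5)

    def test_nonpositive_follow_up_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            bn.linear_predictor(0.0, 0.0, link="cloglog",
                                family="binomial", f=0.0)


class TestConditionalDecomposition:
    def test_two_arm_variance_is_sigma_squared(self):
        mean, var = bn.conditional_re_moments([0.7], [], sigma=0.3, k=2)
        assert mean == pytest.approx(0.7)
        assert var == pytest.approx(0.09)

    def test_three_arm_example(self):
        mean, var = bn.conditional_re_moments([1.0, 2.0], [1.4],
                                              sigma=1.0, k=3)
        assert mean == pytest.approx(2.2)
        assert var == pytest.approx(0.75)

    def test_invalid_position_rejected(self):
        with pytest.raises(ValueError):
            bn.conditional_re_moments([0.5], [], sigma=1.0, k=1)

    def test_chain_matches_direct_mvn_sampling(self):
        """Sequential conditionals reproduce MVN(d, Sigma) moments.

        Three-arm study, compound symmetry Var sigma^2 / Cov sigma^2/2;
        empirical mean and covariance from the conditional chain must
        match the direct multivariate-normal oracle within 3 Monte
        Carlo standard errors at 10^6 draws.
        """
        rng = np.random.default_rng(99)
        d = np.array([0.3, 0.8])
        sigma = 0.5
        n = 1_000_000
        draws = sample_delta_conditional(d, sigma, rng, size=n)
        cov_true = sigma ** 2 * np.array([[1.0, 0.5], [0.5, 1.0]])
        # oracle: direct MVN sampler
        direct = rng.multivariate_normal(d, cov_true, size=n,
                                         method="cholesky")
        se_mean = sigma / np.sqrt(n)
        assert np.allclose(draws.mean(axis=0), d, atol=3 * se_mean)
        assert np.allclose(draws.mean(axis=0), direct.mean(axis=0),
                           atol=4 * se_mean)
        emp = np.cov(draws.T)
        se_var = cov_true * np.sqrt(2 / n) + 3e-4
        assert np.all(np.abs(emp - cov_true) < 3 * se_var + 3 * 3e-4)
        assert emp[0, 1] == pytest.approx(0.5 * sigma ** 2, abs=3e-3)


class TestBuildModel:
    def test_parameter_counts_random_consistency(self, six_treatment_network):
        model = build_model(six_treatment_network,
                            ModelSpec("binomial", "cloglog",
                                      effects="random"))
        names = model.parameter_names()
        assert sum(n.startswith("mu[") for n in names) == 22
        assert sum(n.startswith("d[") for n in names) == 5
        assert "sigma" in names

    def test_inconsistency_has_one_d_per_direct_pair(self,
                                                     six_treatment_network):
        model = build_model(six_treatment_network,
                            ModelSpec("binomial", "cloglog",
                                      model_type="inconsistency"))
        assert model.n_d == len(direct_pairs(six_treatment_network))

    def test_fixed_effects_has_no_sigma(self, six_treatment_network):
        model = build_model(six_treatment_network,
                            ModelSpec("binomial", "cloglog",
                                      effects="fixed"))
        assert "sigma" not in model.parameter_names()

    def test_cloglog_without_follow_up_rejected(self, single_trial_network):
        with pytest.raises(ValueError, match="follow-up"):
            build_model(single_trial_network, ModelSpec("binomial", "cloglog"))

    def test_covariate_with_inconsistency_rejected(self, toy_network):
        with pytest.raises(ValueError, match="consistency"):
            build_model(toy_network,
                        ModelSpec("binomial", "logit",
                                  model_type="inconsistency",
                                  covariate="age"))

    def test_covariate_missing_on_some_arm_rejected(self):
        rows = [dict(study="S1", treatment="A", events=1, sample_size=10,
                     age=50.0),
                dict(study="S1", treatment="B", events=1, sample_size=10)]
        nd = bn.prepare_network(rows, "dichotomous", covariate_cols=("age",))
        with pytest.raises(ValueError, match="missing"):
            build_model(nd, ModelSpec("binomial", "logit", covariate="age"))

    def test_unsupported_family_link_pair_rejected(self, toy_network):
        with pytest.raises(ValueError, match="family/link"):
            build_model(toy_network, ModelSpec("binomial", "identity"))


class TestLikelihoodNumerics:
    def test_logit_loglik_matches_naive_formula(self, single_trial_network):
        des = build_design(single_trial_network)
        theta = np.array([-0.5, 0.5])
        ll = arm_loglik(theta, des, "binomial", "logit")
        p = 1 / (1 + np.exp(-theta))
        naive = des.r * np.log(p) + (des.n - des.r) * np.log(1 - p)
        assert np.allclose(ll, naive)

    def test_log_link_truncated_theta_is_finite(self, single_trial_network):
        des = build_design(single_trial_network)
        ll = arm_loglik(np.array([-1e-16, -0.5]), des, "binomial", "log")
        assert np.all(np.isfinite(ll))
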