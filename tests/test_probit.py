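"""Liability probit model: construction, conditioning laws and analytic criteria."""

import numpy as np
import pytest
from scipy.stats import norm

import riskpanel as rp


class TestConstruction:
    def test_balanced_prevalence_gives_zero_threshold(self):
        m = rp.LiabilityProbitModel([0.5], [[1.0]], [[0.5]], [[0.5]])
        assert m.tau[0] == pytest.approx(0.0)

    def test_null_model_is_valid(self):
        m = rp.LiabilityProbitModel(
            [0.1, 0.2], np.eye(2), np.zeros((2, 2)), np.zeros((2, 2))
        )
        assert m.wilks_variance_explained() == pytest.approx(0.0)

    def test_non_psd_joint_matrix_rejected(self):
        with pytest.raises(ValueError, match="eigenvalue"):
            rp.LiabilityProbitModel([0.5], [[1.0]], [[0.5]], [[0.9]])

    def test_unit_predictor_variance_rejected(self):
        with pytest.raises(ValueError, match="sigma_X"):
            rp.LiabilityProbitModel([0.5], [[1.0]], [[1.0]], [[0.5]])


class TestRiskMapping:
    def test_risk_half_at_threshold_predictor(self, m2_model):
        assert rp.LiabilityProbitModel(
            [0.5], [[1.0]], [[0.5]], [[0.5]]
        ).risk_from_predictor([0.0])[0] == pytest.approx(0.5)
        r = m2_model.risk_from_predictor(m2_model.tau)
        assert np.allclose(r, 0.5)

    def test_low_prevalence_example(self):
        m = rp.LiabilityProbitModel([0.1], [[1.0]], [[0.25]], [[0.25]])
        expect = 1 - norm.cdf(norm.ppf(0.9) / np.sqrt(0.75))
        assert m.risk_from_predictor([0.0])[0] == pytest.approx(expect)
        assert expect == pytest.approx(0.0694, abs=5e-4)

    def test_risk_is_increasing(self, m2_model):
        xs = np.linspace(-3, 3, 21)
        risks = np.array([m2_model.risk_from_predictor([x, 0.0])[0] for x in xs])
        assert np.all(np.diff(risks) > 0)

    def test_threshold_round_trip(self, m3_model):
        rng = np.random.default_rng(0)
        t = rng.uniform(0.01, 0.99, size=3)
        tt = m3_model.predictor_threshold(t)
        assert np.allclose(m3_model.risk_from_predictor(tt), t, atol=1e-12)

    def test_threshold_limits(self, m2_model):
        assert m2_model.predictor_threshold([0.5, 0.5]) == pytest.approx(m2_model.tau)
        tt = m2_model.predictor_threshold([0.0, 1.0])
        assert tt[0] == -np.inf and tt[1] == np.inf


class TestConditioningLaws:
    def test_no_selection_without_covariance(self):
        m = rp.LiabilityProbitModel(
            [0.2, 0.4], np.eye(2), np.diag([0.3, 0.3]), np.zeros((2, 2))
        )
        mean, cov = m.predictor_moments_given_outcomes([1, 0])
        assert np.allclose(mean, 0)
        assert np.allclose(cov, m.sigma_X)

    def test_scalar_selection_example(self):
        m = rp.LiabilityProbitModel([0.5], [[1.0]], [[0.5]], [[0.5]])
        mean, _ = m.predictor_moments_given_outcomes([1])
        assert mean[0] == pytest.approx(0.5 * np.sqrt(2 / np.pi), abs=1e-9)

    def test_law_of_total_expectation(self, m3_model):
        d = [1, 0, 1]
        p = m3_model.pattern_probability(d)
        mu1, _ = m3_model.predictor_moments_given_outcomes(d)
        mu0, _ = m3_model.predictor_moments_given_outcomes(d, complement=True)
        # p enters through two independently integrated rectangle probabilities
        assert np.allclose(p * mu1 + (1 - p) * mu0, 0.0, atol=5e-6)

    def test_conditional_predictor_moments_against_simulation(self, m2_model):
        rng = np.random.default_rng(3)
        L, X = m2_model._simulate_joint(400_000, rng)
        D = (L >= m2_model.tau).astype(int)
        sel = (D == [1, 0]).all(axis=1)
        mean, cov = m2_model.predictor_moments_given_outcomes([1, 0])
        n = sel.sum()
        assert np.allclose(mean, X[sel].mean(axis=0), atol=4 * np.sqrt(0.3 / n))
        assert np.allclose(cov, np.cov(X[sel].T), atol=0.01)
        selc = ~sel
        meanc, covc = m2_model.predictor_moments_given_outcomes([1, 0], complement=True)
        assert np.allclose(meanc, X[selc].mean(axis=0), atol=0.005)
        assert np.allclose(covc, np.cov(X[selc].T), atol=0.01)

    def test_liability_given_predictor_matches_gaussian_conditioning(self, m3_model):
        """Agrees with the generic MVN conditional computed from the joint matrix."""
        x = np.array([0.3, -0.2, 0.5])
        mu, cov = m3_model.liability_given_predictor(x)
        S = m3_model.sigma
        m = m3_model.m
        A = S[:m, m:] @ np.linalg.inv(S[m:, m:])
        assert np.allclose(mu, A @ x, atol=1e-10)
        assert np.allclose(cov, S[:m, :m] - A @ S[m:, :m], atol=1e-10)
        mu0, _ = m3_model.liability_given_predictor(np.zeros(3))
        assert np.allclose(mu0, 0)

    def test_pattern_probabilities_sum_to_one(self, m3_model):
        total = sum(
            m3_model.pattern_probability([a, b, c])
            for a in (0, 1)
            for b in (0, 1)
            for c in (0, 1)
        )
        assert total == pytest.approx(1.0, abs=1e-5)


class TestWilks:
    def test_scalar_equals_r2(self):
        m = rp.LiabilityProbitModel([0.3], [[1.0]], [[0.37]], [[0.37]])
        assert m.wilks_variance_explained() == pytest.approx(0.37)


class TestAnalyticCriteria:
    def test_joint_sensitivity_closed_form(self):
        """m=1, K=0.5, R2=0.5, t=0.5: orthant probability 3/8 over 1/2."""
        m = rp.LiabilityProbitModel([0.5], [[1.0]], [[0.5]], [[0.5]])
        rec = m.analytic_criteria([0.5], "joint", compute_c_index=False)
        expect = (0.25 + np.arcsin(np.sqrt(0.5)) / (2 * np.pi)) / 0.5
        assert rec.sensitivity == pytest.approx(expect, abs=1e-5)
        assert rec.sensitivity == pytest.approx(0.75, abs=1e-5)

    def test_vacuous_thresholds(self, m2_model):
        for sense in ("joint", "screening"):
            rec = m2_model.analytic_criteria([0.0, 0.0], sense, compute_c_index=False)
            assert rec.sensitivity == pytest.approx(1.0, abs=1e-6)
            assert rec.specificity == pytest.approx(0.0, abs=1e-6)

    def test_screening_joint_complement_relation(self, m2_model):
        """Screening spec of the model == joint sens of the sign-flipped model."""
        t = np.array([0.15, 0.35])
        mirrored = rp.LiabilityProbitModel(
            1 - m2_model.prevalences,
            m2_model.sigma_L,
            m2_model.sigma_X,
            m2_model.sigma_LX,
        )
        spec_s = m2_model.analytic_criteria(t, "screening", compute_c_index=False).specificity
        sens_j = mirrored.analytic_criteria(1 - t, "joint", compute_c_index=False).sensitivity
        assert spec_s == pytest.approx(sens_j, abs=1e-5)

    def test_panel_enumeration_matches_monte_carlo(self, m3_model):
        t = m3_model.prevalences
        rec = m3_model.analytic_criteria(t, "panel_wise", compute_c_index=False)
        rng = np.random.default_rng(12)
        L, X = m3_model._simulate_joint(1_000_000, rng)
        D = L >= m3_model.tau
        I = X >= m3_model.predictor_threshold(t)
        any_out = D.any(axis=1)
        not_all = ~D.all(axis=1)
        sens_mc = (D & I).any(axis=1)[any_out].mean()
        spec_mc = (~((~D) & I).any(axis=1))[not_all].mean()
        assert rec.sensitivity == pytest.approx(sens_mc, abs=3 * np.sqrt(0.25 / any_out.sum()))
        assert rec.specificity == pytest.approx(spec_mc, abs=3 * np.sqrt(0.25 / not_all.sum()))


class TestSimulatedConcordance:
    def test_uninformative_predictor_gives_half(self):
        m = rp.LiabilityProbitModel(
            [0.2, 0.3],
            np.array([[1.0, 0.4], [0.4, 1.0]]),
            np.diag([0.3, 0.3]),
            np.zeros((2, 2)),
        )
        for sense in ("joint", "screening"):
            c, se = m.simulated_concordance(sense, n_pairs=100_000, seed=5)
            assert abs(c - 0.5) < 3 * se

    def test_reproducible_under_fixed_seed(self, m2_model):
        a = m2_model.simulated_concordance("screening", n_pairs=20_000, seed=42)
        b = m2_model.simulated_concordance("screening", n_pairs=20_000, seed=42)
        assert a == b

    def test_minimum_pair_budget_enforced(self, m2_model):
        with pytest.raises(ValueError, match="10"):
            m2_model.simulated_concordance("joint", n_pairs=100, seed=1)

    def test_single_outcome_concordance_equals_analytic_auc(self):
        """Simulated m=1 concordance matches the quadrature AUC."""
        m = rp.LiabilityProbitModel([0.1], [[1.0]], [[0.3]], [[0.3]])
        target = rp.analytic_single_outcome_auc(0.3, 0.3, 0.1)
        c, se = m.simulated_concordance("joint", n_pairs=400_000, seed=9)
        assert abs(c - target) < 3 * se


class TestAucR2Conversion:
    def test_chance_auc_maps_to_zero(self):
        assert rp.auc_r2_convert(0.5, 0.1) == 0.0

    def test_round_trip(self):
        for r2 in (0.05, 0.2, 0.5):
            auc = rp.auc_r2_convert(r2, 0.1, direction="r2_to_auc")
            back = rp.auc_r2_convert(auc, 0.1)
            assert back == pytest.approx(r2, abs=1e-6)

    def test_negatively_oriented_predictor_rejected(self):
        with pytest.raises(ValueError, match="0.5"):
            rp.auc_r2_convert(0.4, 0.1)

    def test_against_large_cohort_empirical_auc(self):
        """AUC 0.8 at 1% prevalence: fitted R2 reproduces the AUC empirically."""
        r2 = rp.auc_r2_convert(0.8, 0.01)
        m = rp.LiabilityProbitModel([0.01], [[1.0]], [[r2]], [[r2]])
        cohort = rp.simulate_cohort(m, 1_000_000, seed=13)
        d = cohort.outcomes[:, 0].astype(bool)
        auc = rp.two_sample_concordance(cohort.risks[d, 0], cohort.risks[~d, 0])
        # concordance SE with ~10^4 cases
        assert auc == pytest.approx(0.8, abs=0.012)


class TestConfig:
    def test_from_config_covariance_block(self, tmp_path):
        import json

        cfg = {
            "names": ["a", "b"],
            "prevalence": [0.1, 0.3],
            "sigma_L": [[1.0, 0.5], [0.5, 1.0]],
            "sigma_X": [[0.3, 0.1], [0.1, 0.2]],
            "sigma_LX": [[0.3, 0.1], [0.1, 0.2]],
        }
        p = tmp_path / "model.json"
        p.write_text(json.dumps(cfg))
        m = rp.LiabilityProbitModel.from_config(str(p))
        assert m.names == ("a", "b")
        assert np.allclose(m.sigma_X, cfg["sigma_X"])

    def test_from_auc_block_builds_special_case(self):
        m = rp.LiabilityProbitModel.from_config(
            {"auc": [0.7, 0.65], "prevalence": [0.1, 0.2], "corr": [[1, 0.3], [0.3, 1]]}
        )
        assert np.allclose(m.sigma_X, m.sigma_LX)
        implied = rp.analytic_single_outcome_auc(m.sigma_X[0, 0], m.sigma_X[0, 0], 0.1)
        assert implied == pytest.approx(0.7, abs=1e-6)
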