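import json
import math

import numpy as np
import pytest
from scipy.special import expit

from icurecal import (
    GeneratorConfig,
    HierarchicalGamModel,
    LogisticRecalModel,
    OffsetInterceptModel,
    fit_hierarchical_gam,
    fit_logistic_recal,
    fit_offset_intercept,
    generate_cohort,
    load_model,
    make_cohort,
    original_model,
)
from icurecal.cohort import logit
from icurecal.recalibrate import (
    ConvergenceError,
    DegenerateOutcomeError,
    IdentifiabilityError,
)


# ---------------------------------------------------------------------------
# independent Newton oracles on the raw likelihood (kept free of the
# package's fitting code paths)
# ---------------------------------------------------------------------------

def newton_offset_mle(lp, y, tol=1e-12):
    b = 0.0
    for _ in range(100):
        mu = expit(b + lp)
        score = y.sum() - mu.sum()
        info = (mu * (1 - mu)).sum()
        step = score / info
        b += step
        if abs(step) < tol:
            break
    return b


def newton_logistic_mle(lp, y, tol=1e-12):
    X = np.column_stack([np.ones_like(lp), lp])
    b = np.zeros(2)
    for _ in range(100):
        mu = expit(X @ b)
        score = X.T @ (y - mu)
        info = (X.T * (mu * (1 - mu))) @ X
        step = np.linalg.solve(info, score)
        b += step
        if np.abs(step).max() < tol:
            break
    return b


class TestOffsetIntercept:
    def test_constant_lp_closed_form(self):
        # every admission carries the registry's mean predicted risk and
        # the empirical mortality is exactly 8.1%: the update intercept
        # is the difference of the two logits
        n = 1000
        y = np.zeros(n, dtype=int)
        y[:81] = 1
        cohort = make_cohort(np.full(n, 0.17), y)
        model = fit_offset_intercept(cohort)
        expected = logit(0.081) - logit(0.17)  # -0.8432
        assert model.beta0 == pytest.approx(expected, abs=1e-8)
        assert model.beta0 == pytest.approx(
            newton_offset_mle(cohort.lp, cohort.died.astype(float)), abs=1e-10
        )

    def test_already_calibrated_gives_zero(self):
        rng = np.random.default_rng(5)
        risk = rng.uniform(0.05, 0.6, size=5000)
        y = rng.binomial(1, risk)
        # re-level risks so mean prediction equals observed mortality
        # exactly, then the score equation is satisfied at beta0 = 0
        cohort = make_cohort(risk, y)
        b = newton_offset_mle(cohort.lp, cohort.died.astype(float))
        shifted = make_cohort(expit(cohort.lp + b), y)
        model = fit_offset_intercept(shifted)
        assert model.beta0 == pytest.approx(0.0, abs=1e-6)

    def test_in_sample_smr_is_one(self, small_cohort):
        model = fit_offset_intercept(small_cohort)
        pred = model.predict_cohort(small_cohort)
        assert small_cohort.died.sum() / pred.sum() == pytest.approx(1.0, abs=1e-6)

    def test_matches_newton_oracle(self, small_cohort):
        model = fit_offset_intercept(small_cohort)
        oracle = newton_offset_mle(
            small_cohort.lp, small_cohort.died.astype(float)
        )
        assert model.beta0 == pytest.approx(oracle, abs=1e-6)

    def test_degenerate_outcomes_rejected(self):
        cohort = make_cohort([0.1, 0.2, 0.3], [1, 1, 1])
        with pytest.raises(DegenerateOutcomeError):
            fit_offset_intercept(cohort)


class TestLogisticRecal:
    def test_matches_newton_oracle(self, small_cohort):
        model = fit_logistic_recal(small_cohort)
        b0, b1 = newton_logistic_mle(
            small_cohort.lp, small_cohort.died.astype(float)
        )
        assert model.beta0 == pytest.approx(b0, abs=1e-6)
        assert model.beta1 == pytest.approx(b1, abs=1e-6)

    def test_well_specified_limit(self):
        rng = np.random.default_rng(6)
        risk = expit(rng.normal(-2.0, 1.5, size=40000))
        y = rng.binomial(1, risk)
        model = fit_logistic_recal(make_cohort(risk, y))
        assert model.beta0 == pytest.approx(0.0, abs=0.05)
        assert model.beta1 == pytest.approx(1.0, abs=0.03)

    def test_score_equation_sum_pred_equals_sum_obs(self, small_cohort):
        model = fit_logistic_recal(small_cohort)
        pred = model.predict_cohort(small_cohort)
        assert pred.sum() == pytest.approx(small_cohort.died.sum(), abs=1e-5)

    def test_constant_lp_unidentifiable(self):
        cohort = make_cohort(np.full(50, 0.2), [0, 1] * 25)
        with pytest.raises(IdentifiabilityError):
            fit_logistic_recal(cohort)

    def test_complete_separation_fails_loudly(self):
        risk = np.concatenate([np.full(25, 0.01), np.full(25, 0.99)])
        y = np.concatenate([np.zeros(25, int), np.ones(25, int)])
        with pytest.raises(ConvergenceError):
            fit_logistic_recal(make_cohort(risk, y))


class TestHierarchicalGam:
    def test_nested_model_agreement(self, linear_cohort):
        """With no unit effects and linear miscalibration, the smooth
        hierarchical update collapses onto the two-parameter logistic."""
        m3 = fit_hierarchical_gam(linear_cohort)
        m2 = fit_logistic_recal(linear_cohort)
        diff = np.abs(
            m3.predict_cohort(linear_cohort) - m2.predict_cohort(linear_cohort)
        )
        assert diff.max() < 0.01
        assert m3.sigma2_u < 0.01

    def test_in_sample_smr_is_one(self, small_cohort):
        m3 = fit_hierarchical_gam(small_cohort)
        pred = m3.predict_cohort(small_cohort)
        assert small_cohort.died.sum() / pred.sum() == pytest.approx(1.0, abs=1e-6)

    def test_nonlinearity_improves_decile_calibration(self):
        from icurecal import calibration_table

        cohort = generate_cohort(
            GeneratorConfig(n_patients=12000, sigma_u=0.0, nonlinearity=-0.08,
                            seed=4)
        )
        m2 = fit_logistic_recal(cohort)
        m3 = fit_hierarchical_gam(cohort)
        gaps = {}
        for name, m in (("m2", m2), ("m3", m3)):
            tab = calibration_table(m.predict_cohort(cohort), cohort.died)
            gaps[name] = (tab["observed"] - tab["mean_pred"]).abs().max()
        assert gaps["m3"] < gaps["m2"]

    def test_unit_variance_recovered(self, small_cohort):
        m3 = fit_hierarchical_gam(small_cohort)
        # truth sigma_u^2 = 0.09; with 44 units expect the right order
        assert 0.005 < m3.sigma2_u < 0.5

    def test_requires_two_units(self):
        cohort = make_cohort(
            np.random.default_rng(0).uniform(0.05, 0.5, 200),
            np.random.default_rng(1).binomial(1, 0.2, 200),
        )
        with pytest.raises(IdentifiabilityError):
            fit_hierarchical_gam(cohort)

    def test_edf_between_parametric_and_full(self, small_cohort):
        m3 = fit_hierarchical_gam(small_cohort)
        assert 2.0 <= m3.edf < small_cohort.n_units + 10


class TestPredictRisk:
    def test_identity_update(self):
        assert original_model().predict_risk(logit(0.3)) == pytest.approx(0.3)

    def test_logistic_closed_form(self):
        model = LogisticRecalModel(beta0=-1.32, beta1=1.02)
        assert model.predict_risk(0.0) == pytest.approx(expit(-1.32), abs=1e-12)
        assert model.predict_risk(0.0) == pytest.approx(0.2108, abs=5e-5)

    def test_unknown_unit_is_population_prediction(self, small_cohort):
        m3 = fit_hierarchical_gam(small_cohort)
        lp = np.array([-2.0, -1.0, 0.0])
        assert np.allclose(
            m3.predict_risk(lp, unit_id="never-seen"), m3.predict_risk(lp)
        )

    @pytest.mark.parametrize(
        "model",
        [OffsetInterceptModel(-0.8), LogisticRecalModel(-1.32, 1.02)],
    )
    def test_monotone_in_lp(self, model):
        lp = np.linspace(-6, 4, 300)
        assert np.all(np.diff(model.predict_risk(lp)) > 0)


class TestSerialization:
    def test_parametric_models_roundtrip(self, tmp_path):
        for model in (OffsetInterceptModel(-0.84), LogisticRecalModel(-1.32, 1.02)):
            path = tmp_path / "m.json"
            model.save(path)
            back = load_model(path)
            lp = np.linspace(-5, 3, 50)
            assert np.array_equal(back.predict_risk(lp), model.predict_risk(lp))

    def test_hierarchical_roundtrip_bit_identical(self, tmp_path, small_cohort):
        m3 = fit_hierarchical_gam(small_cohort)
        path = tmp_path / "m3.json"
        m3.save(path)
        back = load_model(path)
        assert isinstance(back, HierarchicalGamModel)
        assert np.array_equal(
            back.predict_cohort(small_cohort), m3.predict_cohort(small_cohort)
        )
        assert back.sigma2_u == m3.sigma2_u
        # JSON document is self-describing
        doc = json.loads(path.read_text())
        assert doc["kind"] == "hierarchical-gam"
        assert "spline_basis" in doc


def test_parameter_recovery_replicates():
    """Mean slope estimate over seeded replicates is unbiased within
    Monte-Carlo error (3 SE)."""
    est = []
    for seed in range(200):
        cohort = generate_cohort(
            GeneratorConfig(n_patients=5000, sigma_u=0.0, seed=1000 + seed)
        )
        est.append(fit_logistic_recal(cohort).beta1)
    est = np.asarray(est)
    se = est.std(ddof=1) / math.sqrt(len(est))
    assert abs(est.mean() - 1.02) < 3 * se
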