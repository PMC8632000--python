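"""FOCE-I estimation: reductions, oracles, identifiability, determinism."""

import numpy as np
import pytest
import scipy.optimize

from oracle_utils import quadrature_ofv_subject
from vancopk.covariates import OmegaMatrix, ThetaVector
from vancopk.estimation import (
    _FoceEngine,
    fit_model,
    foce_i_contribution,
    make_predict_fn,
    population_diagnostics,
    subject_ofv_foce_i,
)
from vancopk.model import (
    ErrorModel,
    PopulationModel,
    base_model_spec,
    final_model,
    final_model_spec,
)
from vancopk.synthetic import CohortSpec, sample_cohort, simulate_observations


def _small_dataset(n_subjects, seed, model=None, samples_max=4):
    if model is None:
        model = PopulationModel(
            spec=base_model_spec(),
            theta=ThetaVector(2.45, 22.6),
            omega=OmegaMatrix(0.02, 0.04),
            sigma=ErrorModel("additive", sigma_add=2.0),
        )
    spec = CohortSpec(
        n_subjects=n_subjects,
        total_samples=None,
        samples_max=samples_max,
        samples_probs=(0.2, 0.3, 0.3, 0.2, 0.0, 0.0, 0.0),
    )
    cohort = sample_cohort(spec, seed=seed)
    ds, truth = simulate_observations(cohort, model, seed=seed + 1)
    return ds, model


class TestContribution:
    def test_zero_omega_reduces_to_weighted_least_squares_form(self):
        ds, model = _small_dataset(1, seed=3)
        subject = ds.subjects()[0]
        sigma = ErrorModel("additive", sigma_add=2.0)
        contrib, eta, G = subject_ofv_foce_i(
            base_model_spec(eta_on_cl=False, eta_on_v=False),
            subject,
            model.theta,
            OmegaMatrix(0.0, 0.0),
            sigma,
        )
        predict = make_predict_fn(model.spec, subject, model.theta)
        f0, _ = predict(np.zeros(2))
        g0 = sigma.variance(f0)
        direct = float(np.sum((subject.dv - f0) ** 2 / g0 + np.log(g0)))
        assert np.all(eta == 0.0)
        assert contrib == pytest.approx(direct, rel=1e-12)

    def test_linear_model_single_observation_closed_form(self):
        # f(eta) = a + b*eta1 with additive error: FOCE-I is exact and equals
        # -2 log N(y; a, b^2 omega^2 + sigma^2) (without the 2*pi term)
        a, b, y = 10.0, 3.0, 12.5
        omega2, s2 = 0.04, 2.25

        def predict(eta):
            return np.array([a + b * eta[0]]), np.array([[b, 0.0]])

        sigma = ErrorModel("additive", sigma_add=np.sqrt(s2))
        contrib, eta, info = foce_i_contribution(predict, [y], [omega2, 0.0], sigma)
        V = b**2 * omega2 + s2
        expected = np.log(V) + (y - a) ** 2 / V
        assert contrib == pytest.approx(expected, abs=1e-6)

    def test_toy_problem_agrees_with_quadrature(self):
        # 2 subjects, ~3 observations: quadrature over eta within 0.5 points
        ds, model = _small_dataset(2, seed=9)
        omega = OmegaMatrix(0.02, 0.04)
        sigma = model.sigma
        total_foce = 0.0
        total_quad = 0.0
        for s in ds.subjects():
            c, _, _ = subject_ofv_foce_i(model.spec, s, model.theta, omega, sigma)
            total_foce += c
            total_quad += quadrature_ofv_subject(
                make_predict_fn(model.spec, s, model.theta), s.dv, omega.as_array(), sigma
            )
        assert total_foce == pytest.approx(total_quad, abs=0.5)

    def test_vectorized_engine_matches_scalar_path(self, study_ds, final_popmodel):
        model = final_popmodel
        engine = _FoceEngine(model.spec, study_ds)
        values = {
            "tvcl": 2.45,
            "tvv": 22.6,
            "beta_CL_CRCL": 0.0046,
            "beta_CL_WT": -0.011,
            "omega2_cl": model.omega.omega2_cl,
            "omega2_v": model.omega.omega2_v,
            "sigma_add": 3.07,
        }
        omega2 = model.omega.as_array()
        total_vec = engine.ofv(values, omega2, model.sigma, warm=False)
        total_scalar = sum(
            subject_ofv_foce_i(model.spec, s, model.theta, model.omega, model.sigma)[0]
            for s in study_ds.subjects()
        )
        assert total_vec == pytest.approx(total_scalar, rel=1e-8)


class TestFit:
    def test_noiseless_data_identified_exactly(self):
        truth = PopulationModel(
            spec=base_model_spec(eta_on_cl=False, eta_on_v=False),
            theta=ThetaVector(2.45, 22.6),
            omega=OmegaMatrix(0.0, 0.0),
            sigma=ErrorModel("additive", sigma_add=0.0),
        )
        ds, _ = _small_dataset(12, seed=21, model=truth)
        fit = fit_model(truth.spec, ds, estimate_rse=False, diagnostics=False)
        # with zero noise sigma collapses toward its bound (OFV is unbounded
        # below at a perfect fit), so the convergence flag is not asserted
        assert fit.estimates["tvcl"] == pytest.approx(2.45, rel=5e-3)
        assert fit.estimates["tvv"] == pytest.approx(22.6, rel=5e-3)
        assert fit.estimates["sigma_add"] < 1e-3

    def test_refit_is_deterministic(self):
        ds, model = _small_dataset(8, seed=33)
        f1 = fit_model(model.spec, ds, estimate_rse=False, diagnostics=False)
        f2 = fit_model(model.spec, ds, estimate_rse=False, diagnostics=False)
        assert f1.ofv == f2.ofv
        assert f1.estimates == f2.estimates

    def test_zero_omega_fit_matches_nonlinear_least_squares(self):
        # with additive error and no BSV the theta estimate is the (unweighted)
        # least-squares solution over the pooled observations
        truth = PopulationModel(
            spec=base_model_spec(eta_on_cl=False, eta_on_v=False),
            theta=ThetaVector(2.45, 22.6),
            omega=OmegaMatrix(0.0, 0.0),
            sigma=ErrorModel("additive", sigma_add=2.0),
        )
        ds, _ = _small_dataset(10, seed=55, model=truth)
        fit = fit_model(truth.spec, ds, estimate_rse=False, diagnostics=False)

        subjects = ds.subjects()

        def residuals(p):
            theta = ThetaVector(p[0], p[1])
            out = []
            for s in subjects:
                f, _ = make_predict_fn(truth.spec, s, theta)(np.zeros(2))
                out.append(s.dv - f)
            return np.concatenate(out)

        ls = scipy.optimize.least_squares(residuals, x0=[3.0, 30.0], method="lm")
        assert fit.estimates["tvcl"] == pytest.approx(ls.x[0], rel=1e-3)
        assert fit.estimates["tvv"] == pytest.approx(ls.x[1], rel=1e-3)

    def test_study_fit_converges_and_reports_rse(self, study_ds):
        fit = fit_model(final_model_spec(), study_ds, estimate_rse=True)
        assert fit.converged
        assert fit.rse is not None
        assert fit.rse["tvcl"] < 15.0  # typical CL is precisely estimated
        assert len(fit.cwres) == study_ds.observation_count
        assert len(fit.ebes) == study_ds.subject_count


class TestDiagnostics:
    def test_perfect_fit_has_zero_cwres(self):
        truth = PopulationModel(
            spec=base_model_spec(eta_on_cl=False, eta_on_v=False),
            theta=ThetaVector(2.45, 22.6),
            omega=OmegaMatrix(0.0, 0.0),
            sigma=ErrorModel("additive", sigma_add=0.0),
        )
        ds, _ = _small_dataset(6, seed=77, model=truth)
        # diagnose at the generating parameters with a tiny residual variance
        diag_model = PopulationModel(
            spec=truth.spec,
            theta=truth.theta,
            omega=truth.omega,
            sigma=ErrorModel("additive", sigma_add=1e-6),
        )
        table = population_diagnostics(diag_model, ds)
        np.testing.assert_allclose(table["CWRES"], 0.0, atol=1e-5)
        np.testing.assert_allclose(table["DV"], table["PRED"], rtol=1e-9)
        np.testing.assert_allclose(table["DV"], table["IPRED"], rtol=1e-9)

    def test_cwres_centered_on_simulated_data(self, study_ds, final_popmodel):
        # data simulated from the model it is diagnosed under
        table = population_diagnostics(final_popmodel, study_ds)
        assert abs(table["CWRES"].mean()) < 0.2
        assert table["CWRES"].std() == pytest.approx(1.0, abs=0.25)
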