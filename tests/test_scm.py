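"""Stepwise covariate modeling: ground-truth recovery, thresholds, tie-breaks."""

from types import SimpleNamespace

import pytest

from vancopk.covariates import CovariateRelation, OmegaMatrix, ThetaVector
from vancopk.model import ErrorModel, PopulationModel, base_model_spec
from vancopk.scm import default_candidates, run_scm
from vancopk.synthetic import CohortSpec, sample_cohort, simulate_observations


def _stub_fitter(ofv_map, estimates=None):
    """Fitter returning preset OFVs keyed by the model's relation labels."""

    def fitter(spec, ds, init=None):
        key = tuple(sorted(r.label for r in spec.relations))
        return SimpleNamespace(
            ofv=ofv_map[key],
            converged=True,
            estimates=estimates or {"tvcl": 2.45, "tvv": 22.6},
            model=SimpleNamespace(spec=spec),
        )

    return fitter


class TestThresholdConventions:
    def test_forward_drop_exactly_at_threshold_is_included(self):
        cand = CovariateRelation("CL", "CRCL", "linear_centered", center=100.0)
        ofv_map = {(): 100.0, ("CL-CRCL",): 100.0 - 3.84}
        res = run_scm(base_model_spec(), ds=None, candidates=[cand],
                      fitter=_stub_fitter(ofv_map))
        forward = [s for s in res.steps if s.phase == "forward"]
        assert forward[0].decision == "included"
        assert forward[0].delta_ofv == pytest.approx(3.84)
        # backward: removal raises OFV by only 3.84 < 6.63, so it is removed
        backward = [s for s in res.steps if s.phase == "backward"]
        assert backward[0].decision == "removed"
        assert res.final_relations == ()

    def test_rise_at_backward_threshold_is_retained(self):
        cand = CovariateRelation("CL", "CRCL", "linear_centered", center=100.0)
        ofv_map = {(): 100.0, ("CL-CRCL",): 100.0 - 6.63}
        res = run_scm(base_model_spec(), ds=None, candidates=[cand],
                      fitter=_stub_fitter(ofv_map))
        assert res.final_relations == (cand,)
        backward = [s for s in res.steps if s.phase == "backward"]
        assert backward[0].decision == "retained"

    def test_drop_below_threshold_rejected(self):
        cand = CovariateRelation("CL", "CRCL", "linear_centered", center=100.0)
        ofv_map = {(): 100.0, ("CL-CRCL",): 100.0 - 3.83}
        res = run_scm(base_model_spec(), ds=None, candidates=[cand],
                      fitter=_stub_fitter(ofv_map))
        assert res.final_relations == ()
        assert res.steps[0].decision == "rejected"


class TestDeterministicOrder:
    def test_equal_drops_break_toward_canonical_order(self):
        c_crcl = CovariateRelation("CL", "CRCL", "linear_centered", center=100.0)
        c_wt = CovariateRelation("CL", "WT", "linear_centered", center=75.0)
        ofv_map = {
            (): 100.0,
            ("CL-CRCL",): 90.0,
            ("CL-WT",): 90.0,
            ("CL-CRCL", "CL-WT"): 89.9,
        }
        res = run_scm(base_model_spec(), ds=None, candidates=[c_wt, c_crcl],
                      fitter=_stub_fitter(ofv_map))
        included = [s for s in res.steps if s.decision == "included"]
        assert included[0].candidate == c_crcl  # CRCL precedes WT

    def test_failed_candidate_is_skipped_not_fatal(self):
        c_crcl = CovariateRelation("CL", "CRCL", "linear_centered", center=100.0)
        c_age = CovariateRelation("CL", "AGE", "linear_centered", center=54.0)

        def fitter(spec, ds, init=None):
            labels = tuple(sorted(r.label for r in spec.relations))
            if "CL-AGE" in labels:
                raise RuntimeError("synthetic failure")
            ofv = {(): 100.0, ("CL-CRCL",): 90.0}[labels]
            return SimpleNamespace(ofv=ofv, converged=True,
                                   estimates={}, model=SimpleNamespace(spec=spec))

        res = run_scm(base_model_spec(), ds=None, candidates=[c_crcl, c_age], fitter=fitter)
        assert res.final_relations == (c_crcl,)
        assert any(s.decision == "skipped" for s in res.steps)


class TestGroundTruthRecovery:
    def test_strong_crcl_effect_found_and_others_rejected(self):
        # cohort simulated with a CRCL effect on CL only; SCM should include
        # and retain CRCL-CL and reject AGE/SEX
        truth = PopulationModel(
            spec=base_model_spec(eta_on_cl=True, eta_on_v=False).with_relation(
                CovariateRelation("CL", "CRCL", "linear_centered", center=101.15)
            ),
            theta=ThetaVector(2.45, 22.6, beta={("CL", "CRCL"): 0.0046}),
            omega=OmegaMatrix(0.0128, 0.0),
            sigma=ErrorModel("additive", sigma_add=3.07),
        )
        cohort = sample_cohort(CohortSpec(), seed=101)
        ds, _ = simulate_observations(cohort, truth, seed=102)
        candidates = [
            CovariateRelation("CL", "CRCL", "linear_centered"),
            CovariateRelation("CL", "AGE", "linear_centered"),
            CovariateRelation("CL", "SEX", "fractional_categorical"),
        ]
        res = run_scm(base_model_spec(eta_on_cl=True, eta_on_v=False), ds, candidates)
        labels = [r.label for r in res.final_relations]
        assert labels == ["CL-CRCL"]

    def test_default_candidates_cover_both_parameters(self):
        cands = default_candidates()
        labels = [c.label for c in cands]
        assert labels[0] == "CL-CRCL"
        assert len(cands) == 10
        assert {c.parameter for c in cands} == {"CL", "V"}
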