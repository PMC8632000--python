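"""Closed-form infusion kinetics: values, linearity, mass balance, oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from oracle_utils import ode_conc_two_cmt
from vancopk.structural import (
    InfusionDose,
    PKParameters,
    conc_one_cmt,
    conc_two_cmt,
    ss_trough_one_cmt,
)


class TestOneCompartment:
    def test_end_of_infusion_concentration_matches_arithmetic(self):
        # 1,000 mg over 0.5 h at CL 2.45 L/h, V 22.6 L, read at infusion end
        p = PKParameters(cl=2.45, v=22.6)
        expected = (2000.0 / 2.45) * (1.0 - math.exp(-(2.45 / 22.6) * 0.5))
        got = conc_one_cmt(p, [InfusionDose(0.0, 1000.0, 0.5)], 0.5)
        assert got == pytest.approx(expected, rel=1e-12)
        assert round(got, 2) == 43.07

    def test_no_doses_gives_zero(self):
        p = PKParameters(cl=2.0, v=20.0)
        assert conc_one_cmt(p, [], 5.0) == 0.0

    def test_continuity_across_infusion_end(self):
        p = PKParameters(cl=3.1, v=24.0)
        doses = [InfusionDose(0.0, 750.0, 0.5)]
        eps = 1e-9
        before = conc_one_cmt(p, doses, 0.5 - eps)
        after = conc_one_cmt(p, doses, 0.5 + eps)
        assert after == pytest.approx(before, rel=1e-6)

    @given(
        cl=st.floats(0.5, 10.0),
        v=st.floats(5.0, 80.0),
        amount=st.floats(100.0, 2000.0),
        t=st.floats(0.0, 48.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_linearity_and_nonnegativity(self, cl, v, amount, t):
        p = PKParameters(cl=cl, v=v)
        doses = [InfusionDose(0.0, amount, 0.5), InfusionDose(12.0, amount, 0.5)]
        doubled = [InfusionDose(0.0, 2 * amount, 0.5), InfusionDose(12.0, 2 * amount, 0.5)]
        c1 = conc_one_cmt(p, doses, t)
        c2 = conc_one_cmt(p, doubled, t)
        assert c1 >= 0.0
        assert c2 == pytest.approx(2.0 * c1, rel=1e-9, abs=1e-12)

    def test_superposition_over_vector_times(self):
        p = PKParameters(cl=2.45, v=22.6)
        doses = [InfusionDose(i * 12.0, 1000.0, 0.5) for i in range(3)]
        ts = np.array([0.25, 6.0, 12.25, 30.0])
        vec = conc_one_cmt(p, doses, ts)
        scal = [conc_one_cmt(p, doses, t) for t in ts]
        np.testing.assert_allclose(vec, scal, rtol=1e-12)


class TestSteadyStateTrough:
    def test_matches_thirty_dose_superposition(self):
        # closed form vs explicit superposition of 30 q12h doses (>=10 t1/2)
        p = PKParameters(cl=1.5354, v=22.6)
        trough = ss_trough_one_cmt(p, 1000.0, 12.0, 0.5)
        doses = [InfusionDose(i * 12.0, 1000.0, 0.5) for i in range(30)]
        superposed = conc_one_cmt(p, doses, 30 * 12.0)
        assert trough == pytest.approx(superposed, rel=1e-3)
        assert round(trough, 1) == 35.7

    def test_zero_dose_gives_zero(self):
        p = PKParameters(cl=2.0, v=25.0)
        assert ss_trough_one_cmt(p, 0.0, 12.0, 0.5) == 0.0

    @given(cl=st.floats(0.5, 8.0), v=st.floats(10.0, 60.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_dose_linearity_exact(self, cl, v):
        p = PKParameters(cl=cl, v=v)
        t400 = ss_trough_one_cmt(p, 400.0, 12.0, 0.5)
        t1000 = ss_trough_one_cmt(p, 1000.0, 12.0, 0.5)
        assert t400 / t1000 == pytest.approx(0.4, rel=1e-12)

    def test_monotone_in_dose_and_clearance(self):
        v = 22.6
        troughs_dose = [
            ss_trough_one_cmt(PKParameters(2.45, v), d, 12.0, 0.5) for d in (400, 700, 1000)
        ]
        assert troughs_dose == sorted(troughs_dose)
        troughs_cl = [
            ss_trough_one_cmt(PKParameters(cl, v), 1000.0, 12.0, 0.5) for cl in (1.5, 2.5, 3.5)
        ]
        assert troughs_cl == sorted(troughs_cl, reverse=True)

    def test_invalid_interval_rejected(self):
        p = PKParameters(cl=2.0, v=25.0)
        with pytest.raises(ValueError):
            ss_trough_one_cmt(p, 1000.0, 0.5, 0.5)

    def test_auc_over_interval_equals_dose_over_cl(self):
        # mass balance at steady state via numerical quadrature
        p = PKParameters(cl=2.45, v=22.6)
        doses = [InfusionDose(i * 12.0, 1000.0, 0.5) for i in range(60)]
        lo, hi = 50 * 12.0, 51 * 12.0
        auc, _ = quad(lambda t: conc_one_cmt(p, doses, t), lo, hi, limit=400)
        assert auc == pytest.approx(1000.0 / 2.45, rel=1e-3)


class TestTwoCompartment:
    def test_requires_peripheral_parameters(self):
        p = PKParameters(cl=2.45, v=22.6)
        with pytest.raises(ValueError):
            conc_two_cmt(p, [InfusionDose(0.0, 1000.0, 0.5)], 1.0)

    def test_small_q_limit_matches_one_compartment(self):
        p1 = PKParameters(cl=2.45, v=22.6)
        p2 = PKParameters(cl=2.45, v=22.6, q=1e-8, v2=10.0)
        doses = [InfusionDose(0.0, 1000.0, 0.5)]
        for t in (0.25, 0.5, 2.0, 12.0):
            assert conc_two_cmt(p2, doses, t) == pytest.approx(
                conc_one_cmt(p1, doses, t), rel=1e-6
            )

    def test_empty_dose_list_gives_zero(self):
        p = PKParameters(cl=2.45, v=22.6, q=5.0, v2=40.0)
        assert conc_two_cmt(p, [], 3.0) == 0.0

    def test_agrees_with_ode_integration(self):
        rng = np.random.default_rng(42)
        cl, v = rng.uniform(1, 5), rng.uniform(10, 40)
        q, v2 = rng.uniform(1, 10), rng.uniform(20, 80)
        p = PKParameters(cl=cl, v=v, q=q, v2=v2)
        doses = [InfusionDose(0.0, 1000.0, 0.5), InfusionDose(12.0, 500.0, 1.0)]
        ts = [0.5, 1.0, 4.0, 12.5, 13.0, 24.0]
        analytic = conc_two_cmt(p, doses, np.array(ts))
        numeric = ode_conc_two_cmt(cl, v, q, v2, doses, ts)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-6)


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"cl": -1.0, "v": 20.0},
            {"cl": 2.0, "v": 0.0},
            {"cl": 2.0, "v": 20.0, "q": 5.0},  # q without v2
            {"cl": 2.0, "v": 20.0, "q": -1.0, "v2": 10.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PKParameters(**kwargs)

    def test_invalid_doses_rejected(self):
        with pytest.raises(ValueError):
            InfusionDose(0.0, 0.0, 0.5)
        with pytest.raises(ValueError):
            InfusionDose(0.0, 500.0, 0.0)
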