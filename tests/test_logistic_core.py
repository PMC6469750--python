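"""Unit and property tests for the 4PL/5PL curve primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

from elisashift import (
    CurveParams,
    DataError,
    DegenerateDataError,
    ExpFormParams,
    RangeError,
    fit_curve,
    from_exp_form,
    initial_params,
    inverse_logistic,
    logistic,
    to_exp_form,
)

# Frozen oracle: bisection of the forward curve (reference params a=-0.01,
# d=3.20, xmid=ln 1300, scal=1/1.30, g=1) at OD 0.686, computed with
# scipy.brentq over (1, 1e6) pg/mL before the implementation was written.
ORACLE_LOG_CONC_AT_0686 = 6.182211290514418
ORACLE_CONC_AT_0686 = 484.0611736237248


def curve_strategy():
    """Random valid increasing curves with well-separated asymptotes."""
    return st.builds(
        CurveParams,
        a=st.floats(-0.5, 0.5),
        d=st.floats(1.0, 4.0),
        xmid=st.floats(2.0, 10.0),
        scal=st.floats(0.2, 2.0),
        g=st.floats(0.3, 3.0),
    )


class TestLogistic:
    def test_midpoint_of_symmetric_curve(self, ref_params):
        assert logistic(ref_params.xmid, ref_params) == pytest.approx(
            (ref_params.a + ref_params.d) / 2
        )
        assert logistic(ref_params.xmid, ref_params) == pytest.approx(1.595)

    def test_upper_asymptote_reached(self, ref_params):
        far = ref_params.xmid + 50 * ref_params.scal
        assert abs(logistic(far, ref_params) - ref_params.d) < 1e-12

    def test_stable_far_into_lower_asymptote(self, ref_params):
        y = logistic(ref_params.xmid - 2000.0, ref_params)
        assert math.isfinite(y) and abs(y - ref_params.a) < 1e-12

    @given(p=curve_strategy())
    def test_strict_monotonicity_increasing(self, p):
        x = np.linspace(p.xmid - 5 * abs(p.scal), p.xmid + 5 * abs(p.scal), 200)
        y = logistic(x, p)
        assert np.all(np.diff(y) > 0)

    def test_5pl_with_g1_equals_4pl(self, ref_params):
        x = np.linspace(ref_params.xmid - 10, ref_params.xmid + 10, 1001)
        p5 = CurveParams(ref_params.a, ref_params.d, ref_params.xmid, ref_params.scal, g=1.0)
        assert np.max(np.abs(logistic(x, p5) - logistic(x, ref_params))) < 1e-12


class TestInverse:
    def test_midpoint_inverts_to_xmid(self, ref_params):
        y = (ref_params.a + ref_params.d) / 2
        assert inverse_logistic(y, ref_params) == pytest.approx(ref_params.xmid)

    def test_against_frozen_bisection_oracle(self, ref_params):
        x = inverse_logistic(0.686, ref_params)
        assert x == pytest.approx(ORACLE_LOG_CONC_AT_0686, rel=1e-9)
        assert math.exp(x) == pytest.approx(ORACLE_CONC_AT_0686, rel=1e-6)

    def test_against_runtime_bisection(self, ref_params):
        # independent root-finder on the forward curve, (1, 1e6) pg/mL
        for y in (0.1, 0.686, 1.595, 3.0):
            x_bi = brentq(lambda lx: logistic(lx, ref_params) - y, math.log(1.0), math.log(1e6))
            assert inverse_logistic(y, ref_params) == pytest.approx(x_bi, rel=1e-9)

    @pytest.mark.parametrize("y,tag", [(3.20, "above_range"), (5.0, "above_range"),
                                       (-0.01, "below_range"), (-1.0, "below_range")])
    def test_out_of_range_tagged(self, ref_params, y, tag):
        with pytest.raises(RangeError) as err:
            inverse_logistic(y, ref_params)
        assert err.value.tag == tag

    @given(p=curve_strategy())
    def test_roundtrip_grid(self, p):
        x = np.linspace(p.xmid - 6 * abs(p.scal), p.xmid + 6 * abs(p.scal), 1000)
        back = np.array([inverse_logistic(float(y), p) for y in logistic(x, p)])
        assert np.max(np.abs(back - x)) < 1e-9


class TestExpForm:
    def test_reference_curve_printed_values(self, ref_params):
        e = to_exp_form(ref_params)
        assert e.C == pytest.approx(1300.00)
        assert e.B == pytest.approx(-1.30)
        assert (e.A, e.D) == (ref_params.a, ref_params.d)

    @given(p=curve_strategy())
    def test_roundtrip_identity(self, p):
        q = from_exp_form(to_exp_form(p))
        for attr in ("a", "d", "xmid", "scal", "g"):
            assert getattr(q, attr) == pytest.approx(getattr(p, attr), abs=1e-12, rel=1e-12)

    def test_nonpositive_c_rejected(self):
        with pytest.raises(DataError):
            ExpFormParams(A=0.0, D=3.0, C=-5.0, B=-1.3)


def _simulated_standards(p, n_rep=3, top=8000.0, n_levels=8, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.repeat([math.log(top / 2 ** i) for i in range(n_levels)], n_rep)
    od = logistic(x, p) + rng.normal(0, noise, x.size)
    return x, od


class TestInitialParams:
    def test_orientation_of_slope(self, ref_params):
        x, od = _simulated_standards(ref_params)
        assert initial_params((x, od)).scal > 0
        # decreasing curve: competitive-assay orientation
        dec = CurveParams(a=ref_params.a, d=ref_params.d, xmid=ref_params.xmid,
                          scal=-ref_params.scal)
        x2, od2 = _simulated_standards(dec)
        assert initial_params((x2, od2)).scal < 0

    def test_too_few_levels_rejected(self):
        with pytest.raises(DataError):
            initial_params(([0.0, 1.0, 2.0], [0.1, 0.5, 0.9]))

    def test_flat_data_rejected(self):
        with pytest.raises(DegenerateDataError):
            initial_params(([0.0, 1.0, 2.0, 3.0], [0.5, 0.5, 0.5, 0.5]))


class TestFitCurve:
    def test_noiseless_recovery_exact(self):
        truth = CurveParams(a=0.0, d=3.2, xmid=7.17, scal=0.77, g=1.0)
        x, od = _simulated_standards(truth)
        fit = fit_curve((x, od), "4pl")
        assert fit.converged and fit.rss < 1e-16
        for attr in ("d", "xmid", "scal"):
            assert getattr(fit.params, attr) == pytest.approx(getattr(truth, attr), rel=1e-6)
        assert fit.params.a == pytest.approx(truth.a, abs=1e-6)

    def test_5pl_on_symmetric_data_finds_g_near_1(self):
        truth = CurveParams(a=0.0, d=3.2, xmid=7.17, scal=0.77, g=1.0)
        x, od = _simulated_standards(truth)
        fit = fit_curve((x, od), "5pl")
        assert fit.params.g == pytest.approx(1.0, abs=1e-3)

    def test_noiseless_recovery_over_random_draws(self):
        """Parameter recovery within 1e-6 relative for 100 random curves."""
        rng = np.random.default_rng(12345)
        for _ in range(100):
            truth = CurveParams(
                a=float(rng.uniform(-0.3, 0.3)),
                d=float(rng.uniform(1.0, 4.0)),  # a, d separated by >= 0.5 OD
                xmid=float(rng.uniform(4.0, 9.0)),
                scal=float(rng.uniform(0.3, 1.5)),
                g=1.0,
            )
            x, od = _simulated_standards(truth)
            fit = fit_curve((x, od), "4pl")
            assert fit.converged
            for attr in ("a", "d", "xmid", "scal"):
                got, want = getattr(fit.params, attr), getattr(truth, attr)
                assert got == pytest.approx(want, rel=1e-6, abs=1e-6), attr

    def test_nan_reading_named(self, ref_params):
        x, od = _simulated_standards(ref_params)
        od = od.copy()
        od[5] = np.nan
        with pytest.raises(DataError, match="W6"):
            fit_curve((x, od), "4pl", labels=[f"W{i + 1}" for i in range(x.size)])

    def test_5pl_needs_five_levels(self, ref_params):
        x, od = _simulated_standards(ref_params, n_levels=4)
        with pytest.raises(DataError):
            fit_curve((x, od), "5pl")

    def test_noisy_fit_converges(self, ref_params):
        x, od = _simulated_standards(ref_params, noise=0.02, seed=3)
        fit = fit_curve((x, od), "4pl")
        assert fit.converged and fit.rss > 0
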