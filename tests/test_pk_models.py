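"""Closed-form concentration curves against independent ODE oracles."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

import mixpower as mp
from mixpower.pk_models import InvalidParameterError


def ode_onecomp(t, dose, p):
    """Depot + central linear system integrated adaptively."""

    def rhs(_, y):
        return [-p.ka * y[0], p.ka * y[0] - p.ke * y[1]]

    sol = solve_ivp(rhs, [dose.time, max(t, dose.time + 1e-9)],
                    [p.F * dose.amount, 0.0], rtol=1e-11, atol=1e-13)
    return sol.y[1, -1] / p.V


def ode_transit(t, dose, p):
    """Chain of n+1 transit compartments feeding the central compartment."""
    n = p.n_transit
    ktr = p.ktr

    def rhs(_, y):
        dy = np.empty(n + 2)
        dy[0] = -ktr * y[0]
        for i in range(1, n + 1):
            dy[i] = ktr * (y[i - 1] - y[i])
        dy[n + 1] = ktr * y[n] - p.ke * y[n + 1]
        return dy

    y0 = np.zeros(n + 2)
    y0[0] = p.F * dose.amount
    sol = solve_ivp(rhs, [dose.time, max(t, dose.time + 1e-9)], y0,
                    rtol=1e-11, atol=1e-13)
    return sol.y[n + 1, -1] / p.V


class TestOneCompartment:
    def test_zero_at_dose_time(self):
        p = mp.OneCompFOAParams(ka=0.8, CL=20, V=70)
        assert mp.conc_onecomp(0.0, mp.DoseEvent(100), p) == 0.0

    def test_matches_ode_at_reference_point(self):
        p = mp.OneCompFOAParams(ka=0.8, CL=20, V=70)
        d = mp.DoseEvent(100)
        closed = float(mp.conc_onecomp(2.0, d, p))
        oracle = ode_onecomp(2.0, d, p)
        assert closed == pytest.approx(oracle, rel=1e-8)

    def test_degenerate_ka_equals_ke(self):
        # repeated eigenvalue: ka == CL/V exactly
        p = mp.OneCompFOAParams(ka=0.5, CL=35, V=70)
        d = mp.DoseEvent(100)
        val = float(mp.conc_onecomp(3.0, d, p))
        assert np.isfinite(val) and val > 0
        assert val == pytest.approx(ode_onecomp(3.0, d, p), rel=1e-8)
        # analytic limit F·D·ke·t·exp(-ke·t)/V
        limit = 100 * 0.5 * 3.0 * np.exp(-0.5 * 3.0) / 70
        assert val == pytest.approx(limit, rel=1e-10)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            mp.OneCompFOAParams(ka=-1, CL=20, V=70)
        with pytest.raises(InvalidParameterError):
            mp.OneCompFOAParams(ka=0.8, CL=20, V=70, F=1.5)
        with pytest.raises(InvalidParameterError):
            mp.DoseEvent(0.0)


class TestTransit:
    def test_zero_at_dose_time(self):
        p = mp.TransitAbsParams(n_transit=7, MTT=0.982, CL=78, V=129)
        assert mp.conc_transit(0.0, mp.DoseEvent(100), p) == 0.0

    def test_reduces_to_onecomp_for_zero_transits(self):
        # n=0 with ktr = 0.8 is first-order absorption with ka = 0.8
        pt = mp.TransitAbsParams(n_transit=0, MTT=1 / 0.8, CL=20, V=70)
        po = mp.OneCompFOAParams(ka=0.8, CL=20, V=70)
        d = mp.DoseEvent(100)
        for t in (0.5, 2.0, 8.0, 24.0):
            assert float(mp.conc_transit(t, d, pt)) == pytest.approx(
                float(mp.conc_onecomp(t, d, po)), rel=1e-10)

    def test_matches_ode_chain_and_mass_balance(self):
        p = mp.TransitAbsParams(n_transit=7, MTT=0.982, CL=78, V=129)
        d = mp.DoseEvent(100)
        closed = float(mp.conc_transit(1.0, d, p))
        assert closed == pytest.approx(ode_transit(1.0, d, p), rel=1e-6)
        auc, _ = quad(lambda t: float(mp.conc_transit(t, d, p)), 0, 60, limit=300)
        assert p.CL * auc == pytest.approx(p.F * d.amount, rel=1e-6)

    def test_slow_elimination_branch(self):
        # ktr < ke exercises the quadrature fallback
        p = mp.TransitAbsParams(n_transit=3, MTT=20.0, CL=70, V=70)
        d = mp.DoseEvent(100)
        assert p.ktr < p.ke
        for t in (0.5, 5.0, 30.0):
            assert float(mp.conc_transit(t, d, p)) == pytest.approx(
                ode_transit(t, d, p), rel=1e-6)


class TestOracleGrid:
    """Both closed forms against the ODE oracle over random parameters."""

    @pytest.mark.parametrize("model", ["onecomp", "transit"])
    def test_random_parameter_grid(self, model, rng):
        d = mp.DoseEvent(100)
        times = np.linspace(0.1, 30, 20)
        for _ in range(25):
            if model == "onecomp":
                p = mp.OneCompFOAParams(
                    ka=rng.uniform(0.1, 3), CL=rng.uniform(2, 100),
                    V=rng.uniform(10, 300), F=rng.uniform(0.3, 1.0))
                oracle, closed = ode_onecomp, mp.conc_onecomp
            else:
                p = mp.TransitAbsParams(
                    n_transit=int(rng.integers(0, 10)), MTT=rng.uniform(0.2, 5),
                    CL=rng.uniform(2, 100), V=rng.uniform(10, 300),
                    F=rng.uniform(0.3, 1.0))
                oracle, closed = ode_transit, mp.conc_transit
            vals = np.array([float(closed(t, d, p)) for t in times])
            refs = np.array([oracle(t, d, p) for t in times])
            scale = refs.max()
            assert np.all(vals >= 0)
            np.testing.assert_allclose(vals, refs, rtol=1e-6, atol=1e-6 * scale)

    def test_concentration_vanishes_at_late_times(self):
        d = mp.DoseEvent(100)
        p1 = mp.OneCompFOAParams(ka=0.8, CL=20, V=70)
        p2 = mp.TransitAbsParams(n_transit=7, MTT=0.982, CL=78, V=129)
        assert float(mp.conc_onecomp(500.0, d, p1)) < 1e-12
        assert float(mp.conc_transit(500.0, d, p2)) < 1e-12

    def test_mass_balance_onecomp(self):
        p = mp.OneCompFOAParams(ka=0.8, CL=20, V=70, F=0.7)
        d = mp.DoseEvent(100)
        auc, _ = quad(lambda t: float(mp.conc_onecomp(t, d, p)), 0, 400, limit=300)
        assert p.CL * auc == pytest.approx(p.F * d.amount, rel=1e-6)
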