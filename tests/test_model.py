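"""Kinetic core: right-hand sides, steady states, closed forms, timescales."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from sokinetics import (
    ExperimentConfig,
    NoSteadyStateError,
    PhysicalConstants,
    RateConstants,
    SOState,
    closed_form_coefficients,
    derived_timescales,
    integrate_photobleaching,
    inverse_rate_curve,
    oxidation_rate,
    rate_ratio,
    so_rhs,
    steady_state_so,
    transfer_rates_from_permeability,
)
from conftest import ALPHA, mv_to_density, random_rate_constants


def ode_steady_state(rc, cfg, t_fixed, s_fixed, horizon_factor=60.0):
    """Independent oracle: integrate the frozen SO balance from zero SO."""
    def rhs(t, y):
        state = SOState(
            o_c=max(y[0], 0.0), o_m=max(y[1], 0.0), o_t=max(y[2], 0.0),
            t_vis=t_fixed, s_tot=s_fixed,
        )
        _, doc, dom, dot = so_rhs(state, rc, cfg)
        return [doc, dom, dot]

    rates = [rc.k_ctm, rc.k_mct, rc.k_w, rc.k_w0, rc.k_so * s_fixed,
             rc.k_to * t_fixed, rc.k_pso * cfg.ps_density]
    slowest = min(r for r in rates if r > 0)
    t_end = horizon_factor / slowest
    sol = solve_ivp(rhs, (0.0, t_end), [0.0, 0.0, 0.0], method="Radau",
                    rtol=1e-10, atol=1e-30)
    assert sol.success
    return sol.y[:, -1]


class TestRightHandSide:
    def test_null_dynamics(self, cfg_cis):
        rc = RateConstants(0, 0, 0, 0, 0, 0, 0)
        state = SOState(1e12, 2e12, 3e12, cfg_cis.t0, cfg_cis.t0 + cfg_cis.s0)
        assert so_rhs(state, rc, cfg_cis) == (0.0, 0.0, 0.0, 0.0)

    def test_zero_so_equilibrium_target(self, alpcs2):
        # at adsorption equilibrium with no SO, only generation is active
        t0 = mv_to_density(20.0)
        rc = alpcs2.replace(k_ads=1e-2, k_des=5e-3)
        cfg = ExperimentConfig("cis", ps_density=228e12, t0=t0, s0=0.0,
                               target_aqueous=rc.k_des * t0 / rc.k_ads)
        state = SOState(0.0, 0.0, 0.0, t0, t0)
        dt, doc, dom, dot = so_rhs(state, rc, cfg)
        assert dt == pytest.approx(0.0, abs=1e-12 * t0)
        assert doc == pytest.approx(rc.k_gen * cfg.ps_density, rel=1e-15)
        assert dom == 0.0 and dot == 0.0

    @pytest.mark.parametrize("side", ["cis", "trans"])
    def test_hand_expanded_terms(self, alpcs2, side):
        """Each derivative equals the term-by-term arithmetic expansion."""
        rc = alpcs2.replace(k_pso=1e-12, k_ads=2e-2, k_des=5e-3)
        cfg = ExperimentConfig(side, ps_density=228e12,
                               t0=mv_to_density(20.0), s0=mv_to_density(30.0),
                               target_aqueous=4.0)
        t, oc, om, ot = 3.7e16, 1.1e6, 4.0e6, 0.9e6
        s = t + cfg.s0
        state = SOState(oc, om, ot, t, s)
        dt, doc, dom, dot = so_rhs(state, rc, cfg)
        exp_dt = rc.k_ads * 4.0 - rc.k_des * t - rc.k_to * t * om
        exp_dom = (rc.k_ctm * (oc + ot)
                   - (2 * rc.k_mct + rc.k_w0) * om - rc.k_to * t * om)
        if side == "cis":
            exp_doc = (rc.k_gen * cfg.ps_density - rc.k_so * s * oc
                       - (rc.k_pso * cfg.ps_density + rc.k_ctm + rc.k_w) * oc
                       + rc.k_mct * om)
            exp_dot = rc.k_mct * om - (rc.k_ctm + rc.k_w) * ot
        else:
            exp_doc = (rc.k_gen * cfg.ps_density
                       - (rc.k_pso * cfg.ps_density + rc.k_ctm + rc.k_w) * oc
                       + rc.k_mct * om)
            exp_dot = (-rc.k_so * s * ot + rc.k_mct * om
                       - (rc.k_ctm + rc.k_w) * ot)
        assert dt == pytest.approx(exp_dt, rel=1e-14)
        assert doc == pytest.approx(exp_doc, rel=1e-14)
        assert dom == pytest.approx(exp_dom, rel=1e-14)
        assert dot == pytest.approx(exp_dot, rel=1e-14)

    def test_rejects_bad_inputs(self, alpcs2, cfg_cis):
        with pytest.raises(ValueError):
            SOState(-1.0, 0, 0, 1, 1)
        with pytest.raises(ValueError):
            ExperimentConfig("middle", ps_density=1e12, t0=0.0)


class TestSteadyState:
    def test_no_source_gives_zero(self, alpcs2, cfg_cis):
        state = steady_state_so(alpcs2.replace(k_gen=0.0), cfg_cis)
        assert (state.o_c, state.o_m, state.o_t) == (0.0, 0.0, 0.0)

    def test_decoupled_cascade_trans(self, alpcs2, cfg_trans):
        # with no middle->outer return, the three layers solve by forward
        # substitution
        rc = alpcs2.replace(k_mct=0.0)
        t, s = cfg_trans.t0, cfg_trans.t0 + cfg_trans.s0
        state = steady_state_so(rc, cfg_trans, t_fixed=t, s_fixed=s)
        oc = rc.k_gen * cfg_trans.ps_density / (rc.k_ctm + rc.k_w)
        om = rc.k_ctm * oc / (rc.k_w0 + rc.k_to * t)
        assert state.o_c == pytest.approx(oc, rel=1e-12)
        assert state.o_m == pytest.approx(om, rel=1e-12)
        assert state.o_t == pytest.approx(0.0, abs=1e-12 * om)
        # the oxidation rate then follows the hand-derived cascade formula
        r = oxidation_rate(rc, cfg_trans)
        assert r == pytest.approx(rc.k_to * om, rel=1e-12)

    def test_matches_ode_integration_table1(self, alpcs2):
        cfg = ExperimentConfig("cis", ps_density=228e12,
                               t0=mv_to_density(30.0), s0=mv_to_density(30.0))
        t, s = cfg.t0, cfg.t0 + cfg.s0
        state = steady_state_so(alpcs2, cfg, t_fixed=t, s_fixed=s)
        o_ode = ode_steady_state(alpcs2, cfg, t, s)
        np.testing.assert_allclose(
            [state.o_c, state.o_m, state.o_t], o_ode, rtol=1e-6
        )

    def test_residual_mass_balance_and_ode_oracle_random(self):
        """Random parameter sets: exact residuals, SO mass balance, and
        agreement with the ODE-integration oracle."""
        rng = np.random.default_rng(42)
        n_ode_checks = 0
        for i in range(100):
            rc = random_rate_constants(rng)
            side = "cis" if rng.random() < 0.5 else "trans"
            cfg = ExperimentConfig(side, ps_density=10 ** rng.uniform(13, 16),
                                   t0=mv_to_density(rng.uniform(5, 60)),
                                   s0=mv_to_density(rng.uniform(0, 60)))
            t, s = cfg.t0, cfg.t0 + cfg.s0
            state = steady_state_so(rc, cfg, t_fixed=t, s_fixed=s)
            gen = rc.k_gen * cfg.ps_density
            _, doc, dom, dot = so_rhs(state, rc, cfg)
            assert max(abs(doc), abs(dom), abs(dot)) <= 1e-10 * gen
            losses = (
                rc.k_so * s * (state.o_c if side == "cis" else state.o_t)
                + rc.k_to * t * state.o_m
                + rc.k_w * (state.o_c + state.o_t)
                + rc.k_w0 * state.o_m
            )
            assert losses == pytest.approx(gen, rel=1e-9)
            if i % 4 == 0:  # ODE oracle on a quarter of the draws
                o_ode = ode_steady_state(rc, cfg, t, s)
                np.testing.assert_allclose(
                    [state.o_c, state.o_m, state.o_t], o_ode, rtol=1e-6,
                    atol=1e-9 * max(o_ode),
                )
                n_ode_checks += 1
        assert n_ode_checks == 25

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        log_kso=st.floats(-12, -8),
        log_kw=st.floats(5, 9),
        log_kw0=st.floats(5, 9),
        log_kmct=st.floats(6, 9),
        phi_mv=st.floats(1.0, 80.0),
        s0_mv=st.floats(0.0, 80.0),
    )
    def test_mass_balance_and_suppression_property(
            self, log_kso, log_kw, log_kw0, log_kmct, phi_mv, s0_mv):
        """For any admissible constants, generation balances total loss at
        steady state and the cis rate never exceeds the trans rate."""
        rc = RateConstants(
            k_gen=1.7, k_so=10 ** log_kso, k_to=6e-10, k_ctm=2.4e8,
            k_mct=10 ** log_kmct, k_w=10 ** log_kw, k_w0=10 ** log_kw0)
        t0, s0 = mv_to_density(phi_mv), mv_to_density(s0_mv)
        ps = 228e12
        rates = {}
        for side in ("cis", "trans"):
            cfg = ExperimentConfig(side, ps, t0, s0)
            st_ = steady_state_so(rc, cfg)
            gen = rc.k_gen * ps
            loss = (rc.k_so * st_.s_tot
                    * (st_.o_c if side == "cis" else st_.o_t)
                    + rc.k_to * st_.t_vis * st_.o_m
                    + rc.k_w * (st_.o_c + st_.o_t) + rc.k_w0 * st_.o_m)
            assert loss == pytest.approx(gen, rel=1e-9)
            rates[side] = rc.k_to * st_.o_m
        assert rates["cis"] <= rates["trans"]

    def test_no_steady_state_signalled(self, cfg_cis):
        rc = RateConstants(k_gen=1.0, k_so=0, k_to=0, k_ctm=0, k_mct=0,
                           k_w=0, k_w0=0)
        with pytest.raises(NoSteadyStateError):
            steady_state_so(rc, cfg_cis)


class TestRatesAndRatio:
    def test_zero_generation_zero_rate(self, alpcs2, cfg_cis):
        assert oxidation_rate(alpcs2.replace(k_gen=0.0), cfg_cis) == 0.0

    def test_cis_always_below_trans(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            rc = random_rate_constants(rng)
            t0 = mv_to_density(rng.uniform(1, 60))
            s0 = mv_to_density(rng.uniform(0, 60))
            ps = 10 ** rng.uniform(13, 16)
            r_c = oxidation_rate(
                RateConstants(**{**rc.__dict__}),
                ExperimentConfig("cis", ps_density=ps, t0=t0, s0=s0))
            r_t = oxidation_rate(
                rc, ExperimentConfig("trans", ps_density=ps, t0=t0, s0=s0))
            assert r_c < r_t

    def test_ratio_trivial_and_bounds(self, alpcs2):
        assert rate_ratio(alpcs2, 0.0, 0.0) == 1.0
        assert rate_ratio(alpcs2, mv_to_density(20), mv_to_density(30)) < 1.0

    def test_ratio_closed_form_vs_steady_states(self, alpcs2):
        t0, s0 = mv_to_density(20.0), mv_to_density(30.0)
        ratio_cf = rate_ratio(alpcs2, t0, s0)
        ps = 228e12
        r_c = oxidation_rate(alpcs2, ExperimentConfig("cis", ps, t0, s0))
        r_t = oxidation_rate(alpcs2, ExperimentConfig("trans", ps, t0, s0))
        assert ratio_cf == pytest.approx(r_c / r_t, rel=1e-9)
        # direct substitution of the fitted constants
        c = alpcs2.k_ctm + alpcs2.k_w
        assert ratio_cf == pytest.approx(
            c / (c + alpcs2.k_so * (t0 + s0)), rel=1e-12
        )

    def test_ratio_linear_in_t0(self, alpcs2):
        """R_t/R_c - 1 is linear in T0 with slope k_so/(k_ctm + k_w)."""
        s0 = mv_to_density(30.0)
        ps = 228e12
        t0s = np.array([mv_to_density(v) for v in np.linspace(2, 60, 10)])
        y = []
        for t0 in t0s:
            r_c = oxidation_rate(alpcs2, ExperimentConfig("cis", ps, t0, s0))
            r_t = oxidation_rate(alpcs2, ExperimentConfig("trans", ps, t0, s0))
            y.append(r_t / r_c - 1.0)
        y = np.array(y)
        coef = np.polyfit(t0s, y, 1)
        pred = np.polyval(coef, t0s)
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1.0 - ss_res / ss_tot > 1.0 - 1e-10
        assert coef[0] == pytest.approx(
            alpcs2.k_so / (alpcs2.k_ctm + alpcs2.k_w), rel=1e-9
        )
        assert coef[1] == pytest.approx(
            alpcs2.k_so * s0 / (alpcs2.k_ctm + alpcs2.k_w), rel=1e-9
        )


class TestClosedForm:
    def test_inverse_rate_exactly_quadratic(self, alpcs2, phys):
        """3 points determine the whole 1/R_cis(phi) curve; the quadratic
        coefficient is the analytic a1."""
        s0 = mv_to_density(30.0)
        ps = 228e12
        phi = np.linspace(2e-3, 80e-3, 12)
        inv_r = inverse_rate_curve(alpcs2, "cis", ps, phi, s0, ALPHA)
        coef = np.polyfit(phi[[0, 5, 11]], inv_r[[0, 5, 11]], 2)
        np.testing.assert_allclose(np.polyval(coef, phi), inv_r, rtol=1e-9)
        a1_expected = alpcs2.k_so / (
            alpcs2.k_ctm * alpcs2.k_gen * ps * ALPHA**2
        )
        assert coef[0] == pytest.approx(a1_expected, rel=1e-9)

    def test_coefficients_match_numeric_solve(self, alpcs2, phys, cfg_cis):
        cf = closed_form_coefficients(alpcs2, cfg_cis, phys)
        phi = np.array([5e-3, 15e-3, 30e-3, 45e-3, 60e-3])
        inv_cis = inverse_rate_curve(
            alpcs2, "cis", cfg_cis.ps_density, phi, cfg_cis.s0, ALPHA)
        np.testing.assert_allclose(cf.inverse_rate_cis(phi), inv_cis,
                                   rtol=1e-12)
        inv_trans = inverse_rate_curve(
            alpcs2, "trans", cfg_cis.ps_density, phi, cfg_cis.s0, ALPHA)
        np.testing.assert_allclose(
            cf.inverse_rate_trans(phi, ALPHA * cfg_cis.s0), inv_trans,
            rtol=1e-12)

    def test_coefficients_match_symbolic_elimination(self, alpcs2, phys,
                                                     cfg_cis):
        """Independent oracle: eliminate the frozen steady-state system with
        sympy and compare every coefficient."""
        sp = pytest.importorskip("sympy")
        k_so, k_to, k_ctm, k_mct, k_w, k_w0, g, al, t0v, s0v = sp.symbols(
            "k_so k_to k_ctm k_mct k_w k_w0 G alpha T0 S0", positive=True)
        oc, om, ot = sp.symbols("oc om ot")
        c = k_ctm + k_w
        sol = sp.solve(
            [sp.Eq(g - k_so * (t0v + s0v) * oc - c * oc + k_mct * om, 0),
             sp.Eq(k_ctm * (oc + ot) - (2 * k_mct + k_w0) * om
                   - k_to * t0v * om, 0),
             sp.Eq(k_mct * om - c * ot, 0)],
            [oc, om, ot])
        phi = sp.symbols("phi", positive=True)
        inv_r = sp.cancel(sp.expand((1 / (k_to * sol[om])).subs(t0v, phi / al)))
        poly = sp.Poly(inv_r, phi)
        subs = {
            k_so: alpcs2.k_so, k_to: alpcs2.k_to, k_ctm: alpcs2.k_ctm,
            k_mct: alpcs2.k_mct, k_w: alpcs2.k_w, k_w0: alpcs2.k_w0,
            g: alpcs2.k_gen * cfg_cis.ps_density, al: ALPHA,
            s0v: cfg_cis.s0,
        }
        a1s, a2s, a3s = [float(cc.evalf(subs=subs)) for cc in poly.all_coeffs()]
        cf = closed_form_coefficients(alpcs2, cfg_cis, phys)
        assert cf.a1 == pytest.approx(a1s, rel=1e-10)
        assert cf.a2 == pytest.approx(a2s, rel=1e-10)
        assert cf.a3 == pytest.approx(a3s, rel=1e-10)

    def test_degenerate_cases(self, alpcs2, phys, cfg_cis):
        cf0 = closed_form_coefficients(alpcs2.replace(k_so=0.0), cfg_cis, phys)
        assert cf0.a1 == 0.0  # curve degenerates to affine in phi
        with pytest.raises(ValueError):
            closed_form_coefficients(
                alpcs2, ExperimentConfig("cis", 0.0, cfg_cis.t0), phys)
        with pytest.raises(ValueError):
            closed_form_coefficients(
                alpcs2.replace(k_pso=1e-12), cfg_cis, phys)


class TestPhotobleaching:
    def test_dark_equilibrium_flat(self, alpcs2, cfg_cis):
        t, phi_rel, light = integrate_photobleaching(
            alpcs2, cfg_cis, [("off", 100.0)])
        np.testing.assert_allclose(phi_rel, 1.0, rtol=1e-9)
        assert not light.any()

    def test_dark_relaxation_closed_form(self, alpcs2, cfg_cis):
        t, phi_rel, _ = integrate_photobleaching(
            alpcs2, cfg_cis, [("off", 600.0)], t_start=cfg_cis.t0 / 2)
        expected = 1.0 - 0.5 * np.exp(-alpcs2.k_des * t)
        np.testing.assert_allclose(phi_rel, expected, rtol=1e-7)

    def test_initial_slope_equals_oxidation_rate(self, alpcs2, cfg_cis):
        r = oxidation_rate(alpcs2, cfg_cis)
        t, phi_rel, _ = integrate_photobleaching(
            alpcs2, cfg_cis, [("on", 0.01 / r)], n_per_segment=4000)
        slope = (phi_rel[1] - phi_rel[0]) / (t[1] - t[0])
        assert -slope == pytest.approx(r, rel=1e-3)

    def test_rejects_bad_schedule(self, alpcs2, cfg_cis):
        with pytest.raises(ValueError):
            integrate_photobleaching(alpcs2, cfg_cis, [])
        with pytest.raises(ValueError):
            integrate_photobleaching(alpcs2, cfg_cis, [("on", -1.0)])
        with pytest.raises(ValueError):
            integrate_photobleaching(alpcs2, cfg_cis, [("dim", 1.0)])


class TestTimescalesAndTransfer:
    def test_travel_time_printed_value(self, alpcs2, phys):
        ts = derived_timescales(alpcs2, phys, ps_dt_distance=2e-9,
                                target_density=0.1e18)
        assert ts.tau_t == pytest.approx(0.8e-9, rel=1e-12)

    def test_dwell_time_sum(self, phys):
        rc = RateConstants(k_gen=1, k_so=6e-10, k_to=6e-10, k_ctm=2.4e8,
                           k_mct=5.5e7, k_w=5.0e7, k_w0=2.9e7)
        ts = derived_timescales(rc, phys, 2e-9, 0.1e18)
        assert ts.tau_dw_sum == pytest.approx(38.2e-9, rel=1e-3)

    def test_zero_lifetime_zero_span(self, alpcs2):
        phys0 = PhysicalConstants(tau_l_ref=0.0)
        ts = derived_timescales(alpcs2, phys0, 2e-9, 0.1e18)
        assert ts.delta_travel == 0.0

    def test_zero_rate_infinite_timescale(self, phys):
        rc = RateConstants(k_gen=1, k_so=0, k_to=0, k_ctm=0, k_mct=0,
                           k_w=0, k_w0=0)
        ts = derived_timescales(rc, phys, 2e-9, 0.1e18)
        assert math.isinf(ts.tau_dw_sum) and math.isinf(ts.tau_to)

    def test_transfer_rates_printed_mode(self, phys):
        assert transfer_rates_from_permeability(phys, use_printed=True) == (
            2.4e8, 5.5e7)

    def test_transfer_rate_ratio_matches_partition(self, phys):
        # the fixed pair satisfies k_mct = k_ctm / K_p to 2 significant figures
        k_ctm, k_mct = transfer_rates_from_permeability(phys, use_printed=True)
        assert k_ctm / phys.K_p == pytest.approx(5.5e7, rel=0.01)
        # the direct permeability formula
        k_ctm_f, k_mct_f = transfer_rates_from_permeability(phys)
        assert k_ctm_f == pytest.approx(
            6.0 * phys.P_M / (phys.K_p * phys.thickness), rel=1e-12)
        assert k_mct_f == pytest.approx(k_ctm_f / phys.K_p, rel=1e-12)

    def test_symmetric_partition(self):
        phys1 = PhysicalConstants(K_p=1.0)
        k_ctm, k_mct = transfer_rates_from_permeability(phys1)
        assert k_ctm == k_mct
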