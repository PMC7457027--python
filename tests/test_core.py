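"""Core circuit dynamics: shifted-Hill kinetics, the ODE right-hand
side, quasi-steady-state metabolic rates, and steady-state finding."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from metabostate.core import (
    _Compiled,
    find_steady_states,
    integrate,
    metabolic_rates,
    numerical_jacobian,
    rhs,
    shifted_hill,
)
from metabostate.params import (
    HillEdge,
    ModelParameters,
    ParameterError,
    SolverSettings,
)


def make_params(edges=(), **overrides):
    """A minimal valid parameter set with configurable topology."""
    p = ModelParameters(
        g={"A": 50.0, "H": 20.0, "Rmt": 600.0, "Rnox": 120.0},
        k={"A": 0.5, "H": 0.25, "Rmt": 300.0, "Rnox": 60.0},
        rate_basal={"G1": 0.2, "G2": 0.4, "F": 0.1},
        atp_yield={"G1": 29.0, "G2": 2.0, "F": 106.0},
        edges=tuple(edges),
    )
    return p.with_values(overrides) if overrides else p


class TestShiftedHill:
    @pytest.mark.parametrize(
        "x,x0,n,lam,expected",
        [
            (0.0, 1.0, 2, 0.1, 1.0),          # zero-input limit
            (1.0, 1.0, 7, 0.1, 0.55),         # midpoint gives (1+lam)/2
            (2.0, 1.0, 2, 0.2, 0.36),         # 0.2 + 0.8/5
        ],
    )
    def test_closed_form_values(self, x, x0, n, lam, expected):
        assert shifted_hill(x, x0, n, lam) == pytest.approx(expected, abs=1e-12)

    @given(
        x0=st.floats(1e-3, 1e3),
        n=st.integers(1, 8),
        lam=st.floats(1e-3, 20.0),
        xs=st.lists(st.floats(0.0, 1e4), min_size=2, max_size=10),
    )
    @hsettings(max_examples=250, derandomize=True)
    def test_monotone_and_bounded(self, x0, n, lam, xs):
        vals = [shifted_hill(x, x0, n, lam) for x in sorted(xs)]
        lo, hi = min(1.0, lam), max(1.0, lam)
        assert all(lo - 1e-12 <= v <= hi + 1e-12 for v in vals)
        diffs = np.diff(vals)
        if lam > 1:
            assert np.all(diffs >= -1e-9)      # activation: non-decreasing
        elif lam < 1:
            assert np.all(diffs <= 1e-9)

    @pytest.mark.parametrize("kwargs", [
        dict(x0=0.0, n=2, lam=0.5),
        dict(x0=-1.0, n=2, lam=0.5),
        dict(x0=1.0, n=2, lam=0.0),
        dict(x0=1.0, n=0, lam=0.5),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            shifted_hill(1.0, **kwargs)

    def test_negative_regulator_rejected(self):
        with pytest.raises(ValueError):
            shifted_hill(-0.1, 1.0, 2, 0.5)


class TestRhs:
    def test_decoupled_steady_point_and_pure_production(self):
        p = make_params()
        d_at_ss = rhs([100.0, 80.0, 2.0, 2.0], p)
        assert d_at_ss[0] == pytest.approx(0.0, abs=1e-12)   # A at g/k = 100
        d_at_zero = rhs([0.0, 0.0, 0.0, 0.0], p)
        assert d_at_zero[0] == pytest.approx(50.0)           # pure production
        assert d_at_zero[1] == pytest.approx(20.0)

    def test_activating_edge_at_midpoint_composes_with_hill(self):
        lam = 3.0
        p = make_params([HillEdge("H", "A", "production", x0=80.0, n=2, lam=lam)])
        A = 10.0
        d = rhs([A, 80.0, 2.0, 2.0], p)   # H at its threshold
        assert d[0] == pytest.approx(50.0 * (1 + lam) / 2 - 0.5 * A)

    def test_degradation_edge_scales_removal_term(self):
        p = make_params([HillEdge("Rnox", "H", "degradation", x0=2.0, n=4, lam=0.2)])
        H = 40.0
        d = rhs([100.0, H, 2.0, 2.0], p)  # Rnox at threshold: F_k = 0.6
        assert d[1] == pytest.approx(20.0 - 0.25 * 0.6 * H)

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError):
            rhs([-1.0, 1.0, 1.0, 1.0], make_params())

    def test_compiled_evaluator_matches_reference(self, baseline, rng):
        X = rng.uniform(0.05, 800.0, size=(40, 4))
        cm = _Compiled(baseline)
        np.testing.assert_allclose(cm.rhs(X), rhs(X, baseline), rtol=1e-13)


class TestMetabolicRates:
    def test_zero_regulators_give_basal_rates(self, baseline):
        r = metabolic_rates(0.0, 0.0, baseline)
        assert r.G1 == pytest.approx(baseline.rate_basal["G1"])
        assert r.G2 == pytest.approx(baseline.rate_basal["G2"])
        assert r.F == pytest.approx(baseline.rate_basal["F"])

    def test_g2_monotone_in_h(self, baseline):
        vals = [metabolic_rates(150.0, h, baseline).G2 for h in np.linspace(0, 600, 25)]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_atp_rates_are_yield_times_rates(self, baseline, rng):
        for _ in range(10):
            a, h = rng.uniform(0, 800, 2)
            r = metabolic_rates(a, h, baseline)
            assert r.G1_atp / r.G1 == pytest.approx(baseline.atp_yield["G1"])
            assert r.G2_atp / r.G2 == pytest.approx(baseline.atp_yield["G2"])
            assert r.F_atp / r.F == pytest.approx(baseline.atp_yield["F"])

    def test_rate_surface_matches_composed_closed_form(self, baseline):
        """Brute-force oracle: rebuild the rate surface directly from the
        flattened scalar parameters and the shifted-Hill closed form."""
        v = baseline.flatten()

        def hill(x, key):
            return v[f"lam_{key}"] + (1 - v[f"lam_{key}"]) / (
                1 + (x / v[f"x0_{key}"]) ** v[f"n_{key}"]
            )

        A, H = np.meshgrid(np.linspace(0, 900, 20), np.linspace(0, 600, 20))
        got = metabolic_rates(A, H, baseline)
        np.testing.assert_allclose(
            got.G1, v["basal_G1"] * hill(A, "A_G1") * hill(H, "H_G1"), rtol=1e-14)
        np.testing.assert_allclose(
            got.G2, v["basal_G2"] * hill(H, "H_G2") * hill(A, "A_G2"), rtol=1e-14)
        np.testing.assert_allclose(
            got.F, v["basal_F"] * hill(A, "A_F"), rtol=1e-14)


class TestFindSteadyStates:
    def test_decoupled_linear_system_has_single_state_at_g_over_k(self, rng):
        p = make_params()
        recs = find_steady_states(p, rng=rng)
        assert len(recs) == 1 and recs[0].stable
        expected = [p.g[x] / p.k[x] for x in ("A", "H", "Rmt", "Rnox")]
        np.testing.assert_allclose(list(recs[0].state), expected, rtol=1e-8)

    def test_all_lambda_one_reduces_to_linear_system(self, baseline, rng):
        p = baseline.with_values(
            {name: 1.0 for name in baseline.flatten() if name.startswith("lam_")})
        recs = find_steady_states(p, rng=rng)
        assert len(recs) == 1 and recs[0].stable
        expected = [p.g[x] / p.k[x] for x in ("A", "H", "Rmt", "Rnox")]
        np.testing.assert_allclose(list(recs[0].state), expected, rtol=1e-8)

    def test_self_activation_toy_is_bistable_with_integration_basins(self, rng):
        # strong self-activation of A: two stable branches + a saddle
        p = make_params([HillEdge("A", "A", "production", x0=250.0, n=4, lam=4.0)])
        recs = find_steady_states(p, n_starts=200, rng=rng)
        stable = [r for r in recs if r.stable]
        unstable = [r for r in recs if not r.stable]
        assert len(stable) == 2 and len(unstable) == 1
        # brute-force basins: forward integration from a grid of A values
        attractors = sorted(r.state.A for r in stable)
        for a0 in np.linspace(1.0, 900.0, 20):
            sol = integrate(p, [a0, 80.0, 2.0, 2.0], t_span=(0, 2000))
            final = sol.y[0, -1]
            nearest = min(attractors, key=lambda s: abs(s - final))
            assert abs(final - nearest) / nearest < 1e-3

    def test_residuals_below_tolerance(self, baseline, solver, rng):
        recs = find_steady_states(baseline, rng=rng, settings=solver)
        assert recs and all(r.residual < solver.tol for r in recs)

    def test_stable_state_set_invariant_when_starts_double(self, baseline, solver):
        """The stable states that feed downstream statistics must not
        depend on the number of Newton starts (saddle capture from
        random starts is best-effort and may vary)."""
        a = find_steady_states(baseline, n_starts=100, rng=np.random.default_rng(7),
                               settings=solver)
        b = find_steady_states(baseline, n_starts=200, rng=np.random.default_rng(8),
                               settings=solver)
        xa = np.array([list(r.state) for r in a if r.stable])
        xb = np.array([list(r.state) for r in b if r.stable])
        assert len(xa) == len(xb)
        for row in xa:
            rel = np.min(np.max(np.abs(xb - row) / np.abs(row), axis=1))
            assert rel < solver.dedup_rtol

    def test_stability_labels_agree_with_forward_integration(self, baseline, solver):
        """Perturb each root by 1% and integrate: stable roots return,
        unstable roots leave."""
        rng = np.random.default_rng(99)
        n_checked = 0
        from metabostate.ensemble import sample_parameters

        for _ in range(10):
            p = sample_parameters(baseline, rng=rng)
            for r in find_steady_states(p, rng=rng, settings=solver):
                if abs(r.max_eig_real) < 1e-3:
                    continue          # marginal mode: timescale too slow to probe
                x = np.array(list(r.state))
                x_pert = x * (1 + 0.01 * rng.choice([-1, 1], size=4))
                horizon = min(5000.0, max(1000.0, 8.0 / abs(r.max_eig_real)))
                sol = integrate(p, x_pert, t_span=(0, horizon))
                rel = np.max(np.abs(sol.y[:, -1] - x) / np.maximum(np.abs(x), 1e-9))
                if r.stable:
                    assert rel < 0.02, f"stable root drifted: {rel}"
                else:
                    assert rel > 0.05, f"unstable root did not leave: {rel}"
                n_checked += 1
        assert n_checked >= 20

    def test_jacobian_matches_analytic_on_linear_system(self):
        p = make_params()
        J = numerical_jacobian(np.array([100.0, 80.0, 2.0, 2.0]), p)
        np.testing.assert_allclose(
            J, np.diag([-0.5, -0.25, -300.0, -60.0]), rtol=1e-6, atol=1e-8)
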