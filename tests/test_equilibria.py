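import numpy as np
import pytest
import scipy.optimize

from chemorad import (
    coexistence_equilibrium,
    jacobian,
    make_params,
    rhs,
    simulate,
    tumor_free_equilibrium,
)
from chemorad.dynamics import DoseSchedule, kill_fraction
from chemorad.equilibria import NoEquilibriumError, find_coexistence_equilibria


def scalar_coexistence_oracle(p):
    """Independent route to the coexistence root: reduce to one equation in T.

    With drugs at V/d, the immune equation is linear in I given T and the
    resistant-cell equation is a quadratic in TR given T, so the per-capita
    growth balance of T becomes a scalar root problem solved by bisection.
    """
    sM = kill_fraction(p.VM / p.d1, p.delta1)
    sR = kill_fraction(p.VR / p.d2, p.delta2)

    def I_of_T(T):
        denom = p.d + p.alpha2 * T + p.aI * sM + p.bI * sR - p.eps1 * T / (p.eps2 + T)
        return p.s / denom

    def h(T):
        return (
            p.r1 * (1 - T / p.Tmax)
            - p.alpha1 * I_of_T(T)
            - p.mu
            - p.aT * sM
            - p.bT * sR
        )

    T = scipy.optimize.brentq(h, 1.0, p.Tmax, xtol=1e-6, rtol=1e-14)
    # TR quadratic: -(r2/Tmax) TR^2 + (r2 - kill) TR + mu T = 0
    a = -p.r2 / p.Tmax
    b = p.r2 - p.aTR * sM - p.bTR * sR
    c = p.mu * T
    TR = max(r.real for r in np.roots([a, b, c]) if abs(r.imag) < 1e-9)
    return T, TR, I_of_T(T)


class TestTumorFree:
    def test_immune_level_matches_reported_value(self, tumor_free_params):
        eq = tumor_free_equilibrium(tumor_free_params)
        # closed form s/(d + aI + bI) at saturated kill
        assert eq.state[3] == pytest.approx(1e5 / 0.0725, rel=1e-12)
        assert eq.state[3] == pytest.approx(1.3793e6, rel=1e-4)

    def test_normal_level_is_the_closed_form(self, tumor_free_params):
        # Nmax (1 - (aN + bN)/r3) at saturated kill with r3 = 0.65
        eq = tumor_free_equilibrium(tumor_free_params)
        assert eq.state[2] == pytest.approx(3e7 * (1 - 0.06 / 0.65), rel=1e-9)

    def test_drug_free_limit(self):
        p = make_params({"VM": 0.0, "VR": 0.0})
        eq = tumor_free_equilibrium(p)
        assert eq.state[2] == pytest.approx(p.Nmax)
        assert eq.state[3] == pytest.approx(p.s / p.d)
        assert eq.state[4] == 0.0 and eq.state[5] == 0.0

    def test_residual_is_tiny(self, tumor_free_params):
        eq = tumor_free_equilibrium(tumor_free_params)
        assert eq.residual < 1e-6 * max(1.0, eq.state.max())

    def test_agrees_with_generic_root_finder(self, tumor_free_params):
        # independent oracle: the model equations written out literally,
        # root-found in scaled variables from (0, 0, Nmax/2, s/d, 0, 0)
        p = tumor_free_params
        scale = np.array([p.Tmax, p.Tmax, p.Nmax, p.s / p.d, 50.0, 50.0])

        def field(u):
            T, TR, N, I, M, R = u * scale
            fM = 1 - np.exp(-p.delta1 * M)
            fR = 1 - np.exp(-p.delta2 * R)
            return np.array(
                [
                    T * (p.r1 * (1 - T / p.Tmax) - p.alpha1 * I - p.mu - p.aT * fM - p.bT * fR)
                    / (p.r1 * p.Tmax),
                    (p.r2 * TR * (1 - TR / p.Tmax) + p.mu * T - (p.aTR * fM + p.bTR * fR) * TR)
                    / (p.r2 * p.Tmax),
                    (p.r3 * N * (1 - N / p.Nmax) + p.k * T * (1 - T / p.Tstar)
                     - (p.aN * fM + p.bN * fR) * N) / p.Nmax,
                    (p.s + p.eps1 * I * T / (p.eps2 + T) - p.d * I - p.alpha2 * I * T
                     - (p.aI * fM + p.bI * fR) * I) / p.s,
                    p.VM - p.d1 * M,
                    p.VR - p.d2 * R,
                ]
            )

        # unit diag: the start has N at the logistic inflection, where the
        # zero Jacobian column defeats MINPACK's automatic scaling
        u0 = np.array([0, 0, 0.5, 1.0, 0.0, 0.0])
        sol = scipy.optimize.root(
            field, u0, method="hybr", options={"xtol": 1e-14, "diag": [1.0] * 6}
        )
        assert sol.success
        eq = tumor_free_equilibrium(p)
        np.testing.assert_allclose((sol.x * scale)[2:], eq.state[2:], rtol=1e-8)
        assert abs(sol.x[0]) < 1e-9 and abs(sol.x[1]) < 1e-9

    def test_toxic_regime_flagged_other(self):
        # normal-cell kill exceeds growth: no positive normal branch
        p = make_params({"r3": 0.05})
        eq = tumor_free_equilibrium(p)
        assert eq.kind == "other"
        assert eq.state[2] == 0.0


class TestCoexistence:
    def test_tumor_components_match_reported_values(self, endemic_params):
        eq = coexistence_equilibrium(endemic_params)
        assert eq.state[0] == pytest.approx(4.0558e7, rel=1e-3)
        assert eq.state[1] == pytest.approx(3.1085e7, rel=2e-3)

    def test_drug_components_are_analytic_steady_states(self, endemic_params):
        eq = coexistence_equilibrium(endemic_params)
        assert eq.state[4] == pytest.approx(0.5 / 0.011, rel=1e-12)
        assert eq.state[5] == pytest.approx(0.5 / 0.011, rel=1e-12)

    def test_matches_scalar_reduction_oracle(self, endemic_params):
        eq = coexistence_equilibrium(endemic_params)
        T, TR, I = scalar_coexistence_oracle(endemic_params)
        assert eq.state[0] == pytest.approx(T, rel=1e-8)
        assert eq.state[1] == pytest.approx(TR, rel=1e-8)
        assert eq.state[3] == pytest.approx(I, rel=1e-8)

    def test_projected_residual_small_with_boundary_flag(self, endemic_params):
        # the normal-cell equation has no nonnegative root at this tumor
        # burden; N rests on the zero boundary and is flagged
        eq = coexistence_equilibrium(endemic_params)
        assert eq.boundary_defect == ("N",)
        assert eq.residual < 1e-6 * eq.state.max()
        assert eq.raw_residual > eq.residual  # the defect is reported, not hidden

    def test_reduced_root_decoupled_from_normal_cell_parameters(self, endemic_params):
        base = coexistence_equilibrium(endemic_params)
        for overrides in [{"r3": 0.3}, {"Nmax": 2e7}, {"k": 0.0}, {"Tstar": 8e5}]:
            eq = coexistence_equilibrium(endemic_params.replace(**overrides))
            np.testing.assert_allclose(
                eq.state[[0, 1, 3, 4, 5]], base.state[[0, 1, 3, 4, 5]], rtol=1e-7
            )

    def test_no_root_in_slow_growth_scenario(self, tumor_free_params):
        with pytest.raises(NoEquilibriumError):
            coexistence_equilibrium(tumor_free_params)

    def test_all_roots_sorted_by_tumor_burden(self, endemic_params):
        eqs = find_coexistence_equilibria(endemic_params)
        assert len(eqs) >= 1
        burdens = [e.state[0] for e in eqs]
        assert burdens == sorted(burdens, reverse=True)


class TestJacobian:
    def test_linear_entries(self, default_params):
        J = jacobian(np.array([1e6, 1e6, 1e6, 1e6, 10, 10]), default_params)
        assert J[4, 4] == -default_params.d1
        assert J[5, 5] == -default_params.d2
        assert J[0, 3] == pytest.approx(-default_params.alpha1 * 1e6)

    @pytest.mark.parametrize("scenario", ["tumor-free", "interior"])
    def test_matches_finite_differences(self, default_params, scenario):
        p = default_params
        if scenario == "tumor-free":
            x = tumor_free_equilibrium(make_params({"r1": 0.00431, "r2": 0.0025})).state
            p = make_params({"r1": 0.00431, "r2": 0.0025})
        else:
            x = np.array([2e7, 1e7, 5e6, 3e5, 20.0, 30.0])
        J = jacobian(x, p)
        sched = DoseSchedule.from_params(p)
        # step floor 1e-3 avoids cancellation noise from O(1e6) rates in
        # the drug columns, where the state is O(10)
        eps = np.maximum(np.abs(x) * 1e-6, 1e-3)
        J_fd = np.empty((6, 6))
        for j in range(6):
            hi = x.copy(); hi[j] += eps[j]
            lo = x.copy(); lo[j] = max(lo[j] - eps[j], 0.0)
            J_fd[:, j] = (rhs(0, hi, p, sched) - rhs(0, lo, p, sched)) / (hi[j] - lo[j])
        scale = np.max(np.abs(J_fd))
        np.testing.assert_allclose(J, J_fd, atol=1e-5 * scale, rtol=1e-4)


class TestStability:
    def test_tumor_free_scenario_is_stable(self, tumor_free_params):
        eq = tumor_free_equilibrium(tumor_free_params)
        assert eq.verdict == "stable"
        # the decoupled drug equations contribute eigenvalues -d1, -d2
        assert np.any(np.isclose(eq.eigenvalues.real, -tumor_free_params.d1))

    def test_coexistence_scenario_is_stable(self, endemic_params):
        assert coexistence_equilibrium(endemic_params).verdict == "stable"

    def test_threshold_inequality_tumor_free(self, tumor_free_params):
        eq = tumor_free_equilibrium(tumor_free_params)
        thr = eq.threshold
        assert thr["rhs"] == pytest.approx(0.00431 / 1e-8)  # 4.31e5
        assert thr["lhs"] == pytest.approx(1.3793e6, rel=1e-4)
        assert thr["satisfied"]

    def test_threshold_inequality_coexistence(self, endemic_params):
        eq = coexistence_equilibrium(endemic_params)
        thr = eq.threshold
        # (r1 - aT - bT)/alpha1 = 3.21e7 at saturated kill
        assert thr["rhs"] == pytest.approx(3.21e7, rel=1e-3)
        assert thr["lhs"] < thr["rhs"] and thr["satisfied"]

    @pytest.mark.parametrize("scenario", ["tumor-free", "endemic"])
    def test_perturbation_returns_to_stable_equilibrium(self, scenario):
        overrides = (
            {"r1": 0.00431, "r2": 0.0025} if scenario == "tumor-free" else {"r3": 0.007}
        )
        p = make_params(overrides)
        eq = (
            tumor_free_equilibrium(p)
            if scenario == "tumor-free"
            else coexistence_equilibrium(p)
        )
        x0 = eq.state * 1.01
        scale = np.maximum(eq.state, 1.0)
        traj = simulate(p, x0=x0, horizon=100)
        d0 = np.max(np.abs(x0 - eq.state) / scale)
        d1 = np.max(np.abs(traj.states[-1] - eq.state) / scale)
        assert d1 < d0
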