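import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kelpres.model_core import (
    drift_equilibrium,
    jacobian_reduced,
    rhs_full,
    rhs_reduced,
    simulate,
)

from conftest import random_states


class TestRhsFull:
    def test_extinction_is_fixed_point(self, baseline):
        assert np.allclose(rhs_full(np.zeros(4), baseline), 0.0)

    def test_kelp_at_capacity_hand_values(self, baseline):
        # at A = K with nothing else present: logistic term vanishes, kelp
        # only sloughs into drift at rate delta_A, of which eps_D is retained
        rates = rhs_full(np.array([10000.0, 0.0, 0.0, 0.0]), baseline)
        assert rates[0] == pytest.approx(-18000.0)
        assert rates[1] == pytest.approx(12600.0)
        assert rates[2] == rates[3] == 0.0

    def test_negative_state_rejected_without_clip(self, baseline):
        with pytest.raises(ValueError):
            rhs_full(np.array([-1.0, 0.0, 0.0, 0.0]), baseline, clip=False)

    def test_clip_treats_small_negative_as_zero(self, baseline):
        a = rhs_full(np.array([100.0, -1e-12, 5.0, 1.0]), baseline)
        b = rhs_full(np.array([100.0, 0.0, 5.0, 1.0]), baseline)
        assert np.allclose(a, b)


class TestDriftEquilibrium:
    def test_no_live_kelp_no_drift(self, baseline):
        assert drift_equilibrium(0.0, 17.0, baseline) == 0.0

    def test_no_urchins_closed_form(self, baseline):
        # with U=0 the quadratic factors, leaving D* = eps_D*delta_A*A/delta_D
        assert drift_equilibrium(10000.0, 0.0, baseline) == pytest.approx(
            42000.0, rel=1e-12
        )

    def test_root_residual(self, baseline, rng):
        A = rng.uniform(0.0, 15000.0, size=200)
        U = rng.uniform(0.0, 100.0, size=200)
        D = drift_equilibrium(A, U, baseline)
        full = np.stack([A, D, U, np.zeros_like(A)], axis=-1)
        dD = rhs_full(full, baseline)[:, 1]
        bound = 1e-9 * np.maximum(1.0, baseline.eps_D * baseline.delta_A * A)
        assert np.all(np.abs(dD) < bound)

    def test_kappa_d_zero_limit_is_continuous(self, baseline):
        # the degenerate linear case must agree with the quadratic root as
        # kappa_D -> 0 (drift consumption vanishes with the preference factor)
        lo = baseline.replace(kappa_D=0.0)
        eps = baseline.replace(kappa_D=1e-11)
        for A, U in [(10.0, 3.0), (5000.0, 40.0), (12000.0, 0.0)]:
            d0 = drift_equilibrium(A, U, lo)
            d1 = drift_equilibrium(A, U, eps)
            assert d0 == pytest.approx(baseline.eps_D * baseline.delta_A * A / baseline.delta_D)
            # the quadratic root approaches the linear form as O(kappa_D * D^2)
            assert d1 == pytest.approx(d0, rel=1e-5)

    def test_negative_inputs_rejected(self, baseline):
        with pytest.raises(ValueError):
            drift_equilibrium(-1.0, 0.0, baseline)


class TestReduction:
    def test_zero_state_zero_rates(self, baseline):
        assert np.allclose(rhs_reduced(np.zeros(3), baseline), 0.0)

    def test_urchin_free_kelp_equilibrium_is_fixed(self, baseline):
        A_star = baseline.K * (1.0 - baseline.delta_A / baseline.r)
        rates = rhs_reduced(np.array([A_star, 0.0, 0.0]), baseline)
        assert abs(rates[0]) < 1e-9 * baseline.K

    def test_reduced_matches_full_at_drift_equilibrium(self, baseline, rng):
        """Core consistency: eliminating D at its quasi-equilibrium leaves
        the (A, U, S) rates of the full model unchanged."""
        states = random_states(rng, 500)
        D = drift_equilibrium(states[:, 0], states[:, 1], baseline)
        full = np.stack([states[:, 0], D, states[:, 1], states[:, 2]], axis=-1)
        got = rhs_reduced(states, baseline)
        want = rhs_full(full, baseline)[:, [0, 2, 3]]
        assert np.allclose(got, want, rtol=1e-10, atol=1e-12)

    def test_plain_chain_limit(self, baseline, rng):
        """With all four NCE feedbacks off, the reduced model is a standard
        Rosenzweig-MacArthur chain (Type I grazing, Type II predation) whose
        drift pool decouples from consumption."""
        p = baseline.replace(kappa_D=0.0, kappa_S=0.0, kappa_A=0.0, beta=0.0)

        def plain_chain(y):
            A, U, S = y
            pred = p.alpha_U * U * S / (1.0 + p.gamma_U * U)
            return np.array(
                [
                    p.r * A * (1.0 - A / p.K) - p.alpha_A * A * U - p.delta_A * A,
                    p.eps_U * p.alpha_A * A * U - pred - p.delta_U * U,
                    p.eps_S * pred - p.delta_S * S,
                ]
            )

        for y in random_states(rng, 50):
            assert np.allclose(rhs_reduced(y, p), plain_chain(y), rtol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        A=st.floats(0.0, 15000.0),
        U=st.floats(0.0, 200.0),
        S=st.floats(0.0, 50.0),
    )
    def test_reduction_consistency_property(self, baseline, A, U, S):
        D = drift_equilibrium(A, U, baseline)
        got = rhs_reduced(np.array([A, U, S]), baseline)
        want = rhs_full(np.array([A, D, U, S]), baseline)[[0, 2, 3]]
        assert np.allclose(got, want, rtol=1e-10, atol=1e-12)


class TestJacobian:
    def test_analytic_matches_finite_difference(self, baseline, rng):
        for y in random_states(rng, 100):
            Ja = jacobian_reduced(y, baseline)
            Jf = jacobian_reduced(y, baseline, method="fd")
            scale = np.max(np.abs(Ja)) + 1e-12
            assert np.max(np.abs(Ja - Jf)) < 1e-5 * scale, y

    def test_kelp_only_eigenvalues(self, baseline):
        # decoupled configuration: urchins gain nothing and both consumers
        # die at unit rate; eigenvalues are -(r - delta_A), -delta_U, -delta_S
        p = baseline.replace(eps_U=0.0, delta_U=1.0, delta_S=1.0)
        A_star = p.K * (1.0 - p.delta_A / p.r)
        eig = np.linalg.eigvals(jacobian_reduced(np.array([A_star, 0.0, 0.0]), p))
        assert np.allclose(sorted(eig.real), [-1.0, -1.0, -0.7], atol=1e-9)
        assert np.allclose(eig.imag, 0.0)

    def test_extinction_linearization(self, baseline):
        J = jacobian_reduced(np.zeros(3), baseline)
        diag = np.diag(J)
        assert diag == pytest.approx(
            [baseline.r - baseline.delta_A, -baseline.delta_U, -baseline.delta_S]
        )

    def test_unknown_method_rejected(self, baseline):
        with pytest.raises(ValueError):
            jacobian_reduced(np.zeros(3), baseline, method="bogus")


class TestSimulate:
    def test_equilibrium_stays_put(self, baseline):
        A_star = baseline.K * (1.0 - baseline.delta_A / baseline.r)
        tr = simulate(np.array([A_star, 0.0, 0.0]), baseline, 200.0)
        assert tr.success
        assert np.allclose(tr.states[:, 0], A_star, rtol=1e-6)
        assert np.allclose(tr.states[:, 1:], 0.0, atol=1e-8)

    def test_logistic_growth_to_urchin_free_equilibrium(self, baseline):
        # without consumers the kelp equation is logistic with effective
        # rate r - delta_A and plateau K(1 - delta_A/r) = 2800 g
        tr = simulate(np.array([1.0, 0.0, 0.0]), baseline, 60.0)
        A = tr.states[:, 0]
        assert tr.success
        assert np.all(np.diff(A) > -1e-6)
        assert A[-1] == pytest.approx(2800.0, rel=1e-4)
        rho, plateau = 0.7, 2800.0
        expected = plateau / (1.0 + (plateau / 1.0 - 1.0) * np.exp(-rho * tr.times))
        assert np.allclose(A, expected, rtol=1e-4, atol=1e-6)

    def test_tolerance_refinement(self, baseline):
        y0 = np.array([500.0, 10.0, 0.5])
        a = simulate(y0, baseline, 300.0, rtol=1e-8, atol=1e-10)
        b = simulate(y0, baseline, 300.0, rtol=5e-9, atol=5e-11)
        denom = np.maximum(np.abs(a.final_state), 1.0)
        assert np.max(np.abs(a.final_state - b.final_state) / denom) < 1e-4

    def test_states_nonnegative(self, baseline, rng):
        for y0 in random_states(rng, 5):
            tr = simulate(y0, baseline, 200.0)
            assert tr.success
            assert np.all(tr.states >= 0.0)

    def test_invalid_horizon(self, baseline):
        with pytest.raises(ValueError):
            simulate(np.zeros(3), baseline, 0.0)

    def test_trajectory_csv_round_trip(self, baseline, tmp_path):
        import pandas as pd

        tr = simulate(np.array([100.0, 1.0, 0.1]), baseline, 10.0)
        path = tmp_path / "traj.csv"
        tr.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["time", "A", "U", "S"]
        assert len(df) == len(tr.times)

    def test_full_model_trajectory_includes_drift_column(self, baseline, tmp_path):
        from kelpres.model_core import rhs_full

        tr = simulate(np.array([100.0, 10.0, 1.0, 0.1]), baseline, 5.0, rhs=rhs_full)
        assert tr.success
        assert tr.state_names == ("A", "D", "U", "S")
        import pandas as pd

        path = tmp_path / "full.csv"
        tr.to_csv(path)
        assert list(pd.read_csv(path).columns) == ["time", "A", "D", "U", "S"]


class TestFastEngine:
    def test_matches_reference_integrator(self, baseline):
        """The compiled Rosenbrock engine and the LSODA reference must agree
        on tail means and final states across both basins."""
        from kelpres._fastsim import integrate_tail_mean

        pa = baseline.to_array()
        for ic in [(500.0, 10.0, 0.01), (100.0, 40.0, 0.0), (5000.0, 1.0, 0.01)]:
            tm, yf, status = integrate_tail_mean(np.array(ic), pa)
            tr = simulate(np.array(ic), baseline, 1000.0)
            assert status == 0
            ref = tr.tail_mean("A")
            assert tm == pytest.approx(ref, rel=1e-3, abs=1e-3)
            assert np.allclose(yf, tr.final_state, rtol=5e-3, atol=1e-3)
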