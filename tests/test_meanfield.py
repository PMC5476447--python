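"""E-I mean-field model: transfer, fixed points, OU statistics, sweeps."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import integrate, optimize
from scipy.special import erfcx

from attncov.meanfield import (
    REFERENCE,
    MeanFieldParams,
    StabilityError,
    attention_sweep,
    calibrate_eta,
    closed_form_GE_sym,
    closed_form_second_moments,
    closed_form_VE_sym_chi1,
    coupling_asymmetry_map,
    delta_mu_region,
    equilibrium,
    integrated_autocov_quadrature,
    invert_transfer,
    jacobian_eigs,
    lif_transfer,
    rate_space_maps,
    simulate_linear,
    simulate_nonlinear,
    stationary_stats,
    stimulus_gain,
    transfer_slope,
)


def _random_stable_params(rng) -> tuple[MeanFieldParams, object]:
    """Random symmetric-coupling parameter draw with a stable fixed point."""
    while True:
        J_E, J_I = rng.uniform(0.5, 2.5), rng.uniform(1.0, 4.0)
        p = replace(
            REFERENCE,
            mu_EB=rng.uniform(0.3, 0.9), mu_IB=rng.uniform(0.3, 0.9),
            J_EE=J_E, J_IE=J_E, J_EI=J_I, J_II=J_I,
            sigma_E=rng.uniform(0.1, 0.5), sigma_I=rng.uniform(0.1, 0.5),
            eta_E=rng.uniform(0.4, 0.8), eta_I=rng.uniform(0.4, 0.8),
        )
        try:
            eq = equilibrium(p)
        except StabilityError:
            continue
        if eq.stable:
            return p, eq


class TestLifTransfer:
    def test_subthreshold_limit_vanishes(self):
        assert lif_transfer(-10.0, 0.2) < 1e-6

    def test_strict_monotonicity(self):
        Is = np.linspace(-0.5, 2.0, 11)
        fs = [lif_transfer(I, 0.6) for I in Is]
        assert np.all(np.diff(fs) > 0)

    def test_independent_quadrature_oracle(self):
        """Fixed-order Gauss-Legendre on the first-passage integrand agrees
        with the adaptive-quadrature rate to 1e-6 relative."""
        I, eta = 1.2, 0.2
        a, b = (I - 1.0) / eta, (I - 0.0) / eta
        nodes, weights = np.polynomial.legendre.leggauss(400)
        z = 0.5 * (b - a) * nodes + 0.5 * (a + b)
        val = 0.5 * (b - a) * np.sum(weights * erfcx(z))
        oracle = 1.0 / (np.sqrt(np.pi) * val)
        assert lif_transfer(I, eta) == pytest.approx(oracle, rel=1e-6)

    def test_nonpositive_noise_rejected(self):
        with pytest.raises(ValueError):
            lif_transfer(1.0, 0.0)


class TestTransferSlope:
    def test_positive_everywhere_sampled(self):
        for I in np.linspace(-1.0, 2.5, 8):
            assert transfer_slope(I, 0.6) > 0

    def test_matches_finite_difference_oracle(self):
        """Richardson-extrapolated central differences reproduce the
        analytic slope to 1e-5 relative."""
        for I in (0.4, 0.9, 1.3):
            h = 1e-5
            fd = (8 * (lif_transfer(I + h, 0.6) - lif_transfer(I - h, 0.6))
                  - (lif_transfer(I + 2 * h, 0.6)
                     - lif_transfer(I - 2 * h, 0.6))) / (12 * h)
            assert transfer_slope(I, 0.6) == pytest.approx(fd, rel=1e-5)

    def test_matches_local_quadratic_fit(self):
        I = 1.2
        grid = I + np.linspace(-1e-3, 1e-3, 7)
        f = [lif_transfer(g, 0.2) for g in grid]
        coef = np.polyfit(grid - I, f, 2)
        assert transfer_slope(I, 0.2) == pytest.approx(coef[1], rel=1e-5)


def test_invert_transfer_roundtrip():
    for r in (0.05, 0.2, 0.45):
        I = invert_transfer(r, 0.6)
        assert lif_transfer(I, 0.6) == pytest.approx(r, abs=1e-9)


class TestEquilibrium:
    def test_uncoupled_fixed_point_is_direct_transfer(self):
        p = replace(REFERENCE, J_EE=0.0, J_EI=0.0, J_IE=0.0, J_II=0.0, A=0.3)
        eq = equilibrium(p)
        mu = p.static_input()
        assert eq.r_E == pytest.approx(lif_transfer(mu[0], p.eta_E), abs=1e-10)
        assert eq.r_I == pytest.approx(lif_transfer(mu[1], p.eta_I), abs=1e-10)

    def test_matches_root_finder_oracle(self):
        p = REFERENCE

        def resid(r):
            mu = p.static_input()
            return [
                lif_transfer(mu[0] + p.J_EE * r[0] - p.J_EI * r[1],
                             p.eta_E) - r[0],
                lif_transfer(mu[1] + p.J_IE * r[0] - p.J_II * r[1],
                             p.eta_I) - r[1],
            ]

        oracle = optimize.root(resid, [0.2, 0.2], tol=1e-12)
        eq = equilibrium(p)
        assert np.allclose(eq.r, oracle.x, atol=1e-8)

    def test_rates_increase_with_attention(self):
        e0 = equilibrium(REFERENCE.with_attention(0.0))
        e1 = equilibrium(REFERENCE.with_attention(1.0))
        assert e1.r_E > e0.r_E and e1.r_I > e0.r_I

    def test_fixed_point_self_consistency(self):
        eq = equilibrium(REFERENCE)
        f_E = lif_transfer(eq.I_eff[0], REFERENCE.eta_E)
        assert abs(f_E - eq.r_E) < 1e-10


class TestJacobian:
    def test_symmetric_coupling_pins_one_eigenvalue_at_minus_one(self):
        p = REFERENCE
        eq = equilibrium(p)
        M, ev = jacobian_eigs(eq, p)
        assert min(abs(ev + 1.0)) < 1e-12
        lam1 = -1.0 - p.J_EI * eq.L_I + p.J_EE * eq.L_E
        assert min(abs(ev - lam1)) < 1e-12

    def test_uncoupled_eigenvalues_are_minus_one(self):
        p = replace(REFERENCE, J_EE=0.0, J_EI=0.0, J_IE=0.0, J_II=0.0)
        eq = equilibrium(p)
        _, ev = jacobian_eigs(eq, p)
        assert np.allclose(ev, -1.0, atol=1e-12)

    def test_determinant_identity(self):
        p = REFERENCE
        eq = equilibrium(p)
        M, ev = jacobian_eigs(eq, p)
        det = 1.0 + p.J_EI * eq.L_I - p.J_EE * eq.L_E
        assert np.linalg.det(M) == pytest.approx(det, abs=1e-10)


class TestStationaryStats:
    def test_lyapunov_consistency_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            M = rng.normal(size=(2, 2))
            M = M - (max(np.real(np.linalg.eigvals(M)).max(), 0) + 0.5) \
                * np.eye(2)
            D = rng.normal(size=(2, 3))
            from attncov.meanfield import _sigma_closed_form
            S = _sigma_closed_form(M, D @ D.T)
            resid = M @ S + S @ M.T + D @ D.T
            assert np.max(np.abs(resid)) < 1e-10 * max(np.max(np.abs(D @ D.T)), 1)

    def test_uncoupled_variance_is_gain_times_noise(self):
        p = replace(REFERENCE, J_EE=0.0, J_EI=0.0, J_IE=0.0, J_II=0.0)
        eq = equilibrium(p)
        st = stationary_stats(eq, p)
        assert st.V_E == pytest.approx(eq.L_E ** 2 * p.sigma_E ** 2,
                                       rel=1e-12)

    def test_zero_noise_gives_zero_stats(self):
        p = replace(REFERENCE, sigma_E=0.0, sigma_I=0.0)
        eq = equilibrium(p)
        st = stationary_stats(eq, p)
        assert np.allclose(st.Sigma, 0) and st.V_E == 0

    def test_symmetric_chi1_matches_closed_form(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            p, eq = _random_stable_params(rng)
            st = stationary_stats(eq, p)
            cf = closed_form_VE_sym_chi1(eq.L_E, eq.L_I, p.J_EE, p.J_EI,
                                         p.sigma_E, p.sigma_I)
            assert st.V_E == pytest.approx(cf, rel=1e-10)

    def test_general_chi_closed_forms_match_matrix_route(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            p, _ = _random_stable_params(rng)
            p = replace(p, chi=rng.uniform(0.0, 1.0))
            eq = equilibrium(p)
            st = stationary_stats(eq, p)
            V_E, V_I, C_EI = closed_form_second_moments(
                eq.L_E, eq.L_I, p.J_EE, p.J_EI, p.sigma_E, p.sigma_I, p.chi)
            assert st.V_E == pytest.approx(V_E, rel=1e-10)
            assert st.V_I == pytest.approx(V_I, rel=1e-10)
            assert st.C_EI == pytest.approx(C_EI, rel=1e-10, abs=1e-14)

    def test_integrated_autocovariance_identity(self):
        p = REFERENCE
        eq = equilibrium(p)
        st = stationary_stats(eq, p)
        quad = integrated_autocov_quadrature(st)
        assert np.allclose(quad, st.long_window_matrix(), atol=1e-8)
        assert quad[0, 0] == pytest.approx(st.V_E, rel=1e-8)

    def test_autocovariance_decays_and_starts_at_sigma(self):
        p = REFERENCE
        eq = equilibrium(p)
        st = stationary_stats(eq, p)
        assert np.allclose(st.autocov(0.0), st.Sigma)
        assert np.max(np.abs(st.autocov(30.0))) < 1e-8

    def test_unstable_point_rejected(self):
        p = REFERENCE
        eq = equilibrium(p)
        eq.stable = False
        with pytest.raises(StabilityError):
            stationary_stats(eq, p)


class TestStimulusGain:
    def test_zero_feedforward_gains_give_zero(self):
        p = replace(REFERENCE, k_E=0.0, k_I=0.0)
        eq = equilibrium(p)
        assert stimulus_gain(eq, p) == (0.0, 0.0)

    def test_symmetric_closed_form(self):
        p = REFERENCE
        eq = equilibrium(p)
        G_E, _ = stimulus_gain(eq, p)
        cf = closed_form_GE_sym(eq.L_E, eq.L_I, p.J_EE, p.J_EI, p.k_E, p.k_I)
        assert G_E == pytest.approx(cf, rel=1e-12)

    def test_gain_variance_consistency_when_symmetric_inputs(self):
        """With k_E = k_I and sigma_E = sigma_I the gain and the long-window
        variance obey G_E sigma_E = k_E sqrt(V_E)."""
        p = replace(REFERENCE, k_E=0.7, k_I=0.7, sigma_E=0.3, sigma_I=0.3)
        eq = equilibrium(p)
        st = stationary_stats(eq, p)
        assert st.G_E * p.sigma_E == pytest.approx(p.k_E * np.sqrt(st.V_E),
                                                   abs=1e-10)

    def test_gain_increases_with_attention(self):
        s0 = stationary_stats(equilibrium(REFERENCE.with_attention(0.0)),
                              REFERENCE.with_attention(0.0))
        s1 = stationary_stats(equilibrium(REFERENCE.with_attention(1.0)),
                              REFERENCE.with_attention(1.0))
        assert s1.G_E > s0.G_E


class TestSweepsAndMaps:
    def test_attention_path_monotonicities(self):
        df = attention_sweep(REFERENCE, np.linspace(0, 1, 11))
        assert len(df) == 11
        assert np.all(np.diff(df.r_E) > 0)
        assert np.all(np.diff(df.r_I) > 0)
        assert np.all(np.diff(df.lambda1) < 0)
        assert np.all(np.diff(df.V_E) < 0)
        assert np.all(np.diff(df.G_E) > 0)

    def test_no_modulation_gives_flat_sweep(self):
        p = replace(REFERENCE, dmu_E=0.0, dmu_I=0.0)
        df = attention_sweep(p, np.linspace(0, 1, 5))
        assert df.r_E.std() < 1e-10 and df.V_E.std() < 1e-12

    def test_rate_space_corner_ordering(self):
        df = rate_space_maps(REFERENCE, [0.12, 0.35], [0.12, 0.35])
        hi_E_lo_I = df[(df.r_E == 0.35) & (df.r_I == 0.12)].V_E.iloc[0]
        lo_E_hi_I = df[(df.r_E == 0.12) & (df.r_I == 0.35)].V_E.iloc[0]
        assert hi_E_lo_I > lo_E_hi_I

    def test_rate_space_surface_smooth(self):
        grid = np.linspace(0.12, 0.4, 10)
        df = rate_space_maps(REFERENCE, grid, grid)
        V = df.pivot(index="r_E", columns="r_I", values="V_E").to_numpy()
        rel = np.abs(np.diff(V, axis=0)) / V[:-1, :]
        assert np.nanmax(rel) < 0.5

    def test_delta_mu_origin_is_neutral(self):
        df, _ = delta_mu_region(REFERENCE, [0.0], [0.0])
        assert abs(df.dV_E.iloc[0]) < 1e-12

    def test_pure_excitatory_drive_raises_variance(self):
        df, _ = delta_mu_region(REFERENCE, [0.15, 0.3], [0.0])
        assert np.all(df.dV_E > 0)

    def test_coupling_symmetry_cell_matches_sweep(self):
        df = coupling_asymmetry_map(REFERENCE, [1.0], [1.0])
        assert df.stable.iloc[0]
        assert df.dV_E.iloc[0] < 0  # attention reduces variance

    def test_asymmetric_region_keeps_variance_decrease(self):
        df = coupling_asymmetry_map(REFERENCE, [0.9, 1.1], [0.9, 1.1])
        ok = df[df.stable]
        assert len(ok) >= 3 and np.all(ok.dV_E < 0)


class TestSimulateLinear:
    def test_zero_noise_paths_identically_zero(self):
        p = replace(REFERENCE, sigma_E=0.0, sigma_I=0.0)
        eq = equilibrium(p)
        sim = simulate_linear(eq, p, duration=50.0, dt=0.1, seed=0)
        assert np.allclose(sim["dr"], 0.0)

    def test_seed_determinism(self):
        eq = equilibrium(REFERENCE)
        a = simulate_linear(eq, REFERENCE, 50.0, 0.1, seed=5)
        b = simulate_linear(eq, REFERENCE, 50.0, 0.1, seed=5)
        assert np.array_equal(a["dr"], b["dr"])

    def test_lagged_autocovariance_matches_theory(self):
        p = REFERENCE
        eq = equilibrium(p)
        st = stationary_stats(eq, p)
        sim = simulate_linear(eq, p, duration=8000.0, dt=0.1, seed=1,
                              lags=(0.5, 1.0, 2.0))
        n_eff = 8000.0 / 1.0  # rough effective samples at unit corr time
        for lag, emp in sim["autocov_emp"].items():
            th = st.autocov(lag)[0, 0]
            se = st.Sigma[0, 0] / np.sqrt(n_eff)
            assert abs(emp[0, 0] - th) < 3 * se


class TestSimulateNonlinear:
    def test_zero_noise_converges_to_equilibrium(self):
        p = replace(REFERENCE, sigma_E=0.0, sigma_I=0.0)
        eq = equilibrium(p)
        sim = simulate_nonlinear(p, duration=30.0, dt=0.02, tau_x=0.5, seed=0)
        assert np.allclose(sim["r"][-1], eq.r, atol=1e-6)

    def test_small_noise_variance_matches_linearization(self):
        p = replace(REFERENCE, sigma_E=0.06, sigma_I=0.07)
        eq = equilibrium(p)
        st = stationary_stats(eq, p)
        sim = simulate_nonlinear(p, duration=1200.0, dt=0.005, tau_x=0.05,
                                 seed=2)
        v = np.var(sim["r"][:, 0])
        assert v == pytest.approx(st.Sigma[0, 0], rel=0.2)

    def test_attention_reduces_slow_fluctuation_variance(self):
        """With slow global fluctuations the attended state shows smaller
        excitatory rate variance and a faster autocovariance decay."""
        out = {}
        for A in (0.0, 1.0):
            p = REFERENCE.with_attention(A)
            sim = simulate_nonlinear(p, duration=600.0, dt=0.02, tau_x=0.5,
                                     seed=3)
            r = sim["r"][:, 0] - sim["r"][:, 0].mean()
            out[A] = {
                "var": np.var(r),
                "ac1": np.mean(r[:-50] * r[50:]) / np.var(r),  # lag 1.0
            }
        assert out[1.0]["var"] < out[0.0]["var"]
        assert out[1.0]["ac1"] < out[0.0]["ac1"]

    def test_timestep_guard(self):
        with pytest.raises(ValueError):
            simulate_nonlinear(REFERENCE, 10.0, dt=0.2, tau_x=0.5, seed=0)


def test_eta_calibration_hits_target_rate():
    eta = calibrate_eta(REFERENCE, target_sps=20.6, bounds=(0.3, 1.0))
    p = replace(REFERENCE, eta_E=eta, eta_I=eta, A=0.0)
    eq = equilibrium(p)
    assert eq.r_E / p.tau_m == pytest.approx(20.6, abs=0.01)
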