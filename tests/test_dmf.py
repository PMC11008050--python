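"""Core neural-mass model tests: transfer function, currents, integration,
FIC calibration and atrophy modulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmfit import (
    AtrophyMap,
    DMFParameters,
    FICVector,
    StructuralConnectome,
    calibrate_fic,
    currents,
    integrate,
    modulate_fic,
    transfer_rate,
)

P = DMFParameters()


class TestTransferRate:
    def test_threshold_limit_is_one_over_d(self):
        assert transfer_rate(P.I_thr_E, "E") == pytest.approx(1.0 / P.d_E)  # 6.25 Hz
        assert transfer_rate(P.I_thr_I, "I") == pytest.approx(1.0 / P.d_I)  # ~11.494 Hz

    def test_direct_scalar_evaluation_above_threshold(self):
        # at I = 0.5 nA: x = 310*0.097, r = x/(1-exp(-0.16*x))
        x = 310.0 * (0.5 - 0.403)
        expected = x / (1.0 - np.exp(-0.16 * x))
        assert transfer_rate(0.5, "E") == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(30.32, abs=0.01)

    def test_strongly_hyperpolarised_rate_vanishes(self):
        assert transfer_rate(-10.0, "E") == pytest.approx(0.0, abs=1e-12)
        assert transfer_rate(-10.0, "E") >= 0.0

    def test_strictly_increasing_and_continuous_across_threshold(self):
        I = np.linspace(P.I_thr_E - 0.05, P.I_thr_E + 0.05, 2001)
        r = transfer_rate(I, "E")
        assert (np.diff(r) > 0).all()
        # no jump at the removable singularity
        assert np.abs(np.diff(r)).max() < 0.05

    def test_unknown_population_rejected(self):
        with pytest.raises(ValueError):
            transfer_rate(0.4, "X")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-5.0, 5.0), st.floats(-5.0, 5.0))
    def test_positive_and_monotone_pairwise(self, a, b):
        ra, rb = transfer_rate(a, "E"), transfer_rate(b, "E")
        assert ra >= 0.0 and rb >= 0.0
        if a < b:
            assert ra <= rb


class TestCurrents:
    def test_zero_state_leaves_external_drive_only(self):
        C = np.zeros((4, 4))
        z = np.zeros(4)
        I_E, I_I = currents(z, z, P, C, np.ones(4))
        assert np.allclose(I_E, P.W_E * P.I0)
        assert np.allclose(I_E, 0.382)
        assert np.allclose(I_I, P.W_I * P.I0)
        assert np.allclose(I_I, 0.2674)

    def test_no_coupling_isolates_regions(self, rng):
        C = rng.uniform(0, 0.2, (5, 5))
        np.fill_diagonal(C, 0.0)
        C = (C + C.T) / 2
        S_E = rng.uniform(0, 1, 5)
        S_I = rng.uniform(0, 1, 5)
        p0 = DMFParameters(G=0.0)
        I_E, _ = currents(S_E, S_I, p0, C, np.ones(5))
        S_E2 = S_E.copy()
        S_E2[1:] = rng.uniform(0, 1, 4)  # perturb the *other* regions only
        I_E2, _ = currents(S_E2, S_I, p0, C, np.ones(5))
        assert I_E[0] == pytest.approx(I_E2[0])

    def test_matches_naive_afferent_loop_oracle(self, rng):
        n = 5
        C = rng.uniform(0, 0.2, (n, n))
        np.fill_diagonal(C, 0.0)
        C = (C + C.T) / 2
        S_E = rng.uniform(0, 1, n)
        S_I = rng.uniform(0, 1, n)
        J = rng.uniform(0.5, 2.0, n)
        I_E, I_I = currents(S_E, S_I, P, C, J)
        for i in range(n):
            acc = sum(C[i, p] * S_E[p] for p in range(n))
            ie = P.W_E * P.I0 + P.W_plus * P.J_NMDA * S_E[i] + P.G * P.J_NMDA * acc - J[i] * S_I[i]
            ii = P.W_I * P.I0 + P.J_NMDA * S_E[i] - S_I[i]
            assert I_E[i] == pytest.approx(ie, rel=1e-14)
            assert I_I[i] == pytest.approx(ii, rel=1e-14)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            currents(np.zeros(3), np.zeros(3), P, np.zeros((4, 4)), np.ones(4))


class TestIntegrate:
    def test_gatings_stay_clipped(self, small_connectome, short_params, small_J0):
        out = integrate(short_params, small_connectome, small_J0, seed=5)
        assert float(out.S_E_series.min()) >= 0.0
        assert float(out.S_E_series.max()) <= 1.0

    def test_seeded_determinism(self, small_connectome, short_params, small_J0):
        a = integrate(short_params, small_connectome, small_J0, seed=9)
        b = integrate(short_params, small_connectome, small_J0, seed=9)
        assert np.array_equal(a.r_E_series, b.r_E_series)

    def test_noiseless_run_settles_to_fixed_point(self, small_connectome, small_J0):
        p = DMFParameters(sigma_g=0.0, t_total=60.0, t_burn=0.0)
        out = integrate(p, small_connectome, small_J0, seed=0)
        S_E, S_I = out.final_state
        # residual of the drift field at the terminal state
        I_E, I_I = currents(S_E, S_I, p, small_connectome, small_J0)
        r_E = transfer_rate(I_E, "E", p)
        r_I = transfer_rate(I_I, "I", p)
        dS_E = -S_E / p.tau_NMDA + (1 - S_E) * p.gamma * r_E
        dS_I = -S_I / p.tau_GABA + r_I
        assert np.linalg.norm(np.concatenate([dS_E, dS_I])) < 1e-8

    def test_fixed_point_is_invariant_under_further_integration(self, small_connectome, small_J0):
        p = DMFParameters(sigma_g=0.0, t_total=60.0, t_burn=0.0)
        out = integrate(p, small_connectome, small_J0, seed=0)
        p2 = DMFParameters(sigma_g=0.0, t_total=1.0, t_burn=0.0)
        out2 = integrate(p2, small_connectome, small_J0, seed=0, initial_state=out.final_state)
        drift = np.abs(out2.S_E_series[-1] - out2.S_E_series[0]).max()
        assert drift < 1e-10

    def test_series_length_contract(self, small_connectome, small_J0):
        p = DMFParameters(t_total=5.0, t_burn=1.0)
        out = integrate(p, small_connectome, small_J0, seed=1)
        assert out.r_E_series.shape[0] == int(round((p.t_total - p.t_burn) / p.dt))

    def test_halving_dt_changes_mean_rates_little(self, small_connectome, small_J0):
        p1 = DMFParameters(sigma_g=0.0, t_total=30.0, t_burn=5.0, dt=1e-3)
        p2 = DMFParameters(sigma_g=0.0, t_total=30.0, t_burn=5.0, dt=5e-4)
        r1 = integrate(p1, small_connectome, small_J0, seed=0).mean_rate
        r2 = integrate(p2, small_connectome, small_J0, seed=0).mean_rate
        assert np.abs(r1 - r2).max() / r1.mean() < 0.02


class TestModulateFIC:
    def test_zero_sigma_keeps_baseline(self, rng):
        J0 = rng.uniform(0.5, 2.0, 8)
        alpha = rng.uniform(0, 2, 8)
        out = modulate_fic(FICVector(J0=J0), 0.0, AtrophyMap(alpha=alpha))
        assert np.allclose(out.J, J0)

    def test_zero_atrophy_keeps_baseline(self, rng):
        J0 = rng.uniform(0.5, 2.0, 8)
        out = modulate_fic(FICVector(J0=J0), -0.7, AtrophyMap(alpha=np.zeros(8)))
        assert np.allclose(out.J, J0)

    def test_printed_arithmetic_example(self):
        out = modulate_fic(FICVector(J0=np.array([1.5])), -0.4, AtrophyMap(alpha=np.array([0.5])))
        assert out.J[0] == pytest.approx(1.2)

    def test_floor_prevents_nonpositive_inhibition(self, caplog):
        out = modulate_fic(FICVector(J0=np.array([1.0])), -1.5, AtrophyMap(alpha=np.array([1.0])))
        assert out.J[0] == pytest.approx(0.01)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            modulate_fic(FICVector(J0=np.ones(3)), 0.1, AtrophyMap(alpha=np.ones(4)))


def _bisection_single_node_fic(params: DMFParameters, target_rate: float) -> float:
    """Oracle: solve the decoupled steady state of one region for J by bisection.

    For a single region with G = 0 and no noise, the steady state satisfies
    S_I = tau_GABA * r_I(I_I), I_I = W_I*I0 + J_NMDA*S_E - S_I, and
    S_E = gamma*tau*r_E / (1 + gamma*tau*r_E) with I_E depending on J. For a
    given J the fixed point is found by damped iteration; bisection then
    finds the J whose fixed-point rate equals the target.
    """
    p = params

    def fixed_point_rate(J):
        S_E, S_I = 0.1, 0.1
        for _ in range(50000):
            I_I = p.W_I * p.I0 + p.J_NMDA * S_E - S_I
            r_I = transfer_rate(I_I, "I", p)
            S_I_new = p.tau_GABA * r_I
            I_E = p.W_E * p.I0 + p.W_plus * p.J_NMDA * S_E - J * S_I
            r_E = transfer_rate(I_E, "E", p)
            g = p.gamma * p.tau_NMDA * r_E
            S_E_new = g / (1.0 + g)
            if abs(S_E_new - S_E) < 1e-14 and abs(S_I_new - S_I) < 1e-14:
                break
            S_E += 0.2 * (S_E_new - S_E)
            S_I += 0.2 * (S_I_new - S_I)
        return transfer_rate(p.W_E * p.I0 + p.W_plus * p.J_NMDA * S_E - J * S_I, "E", p)

    lo, hi = 0.01, 5.0
    for _ in range(60):
        mid = (lo + hi) / 2
        if fixed_point_rate(mid) > target_rate:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


class TestCalibrateFIC:
    def test_single_node_matches_bisection_oracle(self):
        p = DMFParameters(G=0.0, sigma_g=0.0)
        C = np.zeros((1, 1))
        target = 3.44
        J = calibrate_fic(p, C, target_rate=target, rate_tol=0.005, sweep_duration=20.0, seed=0)
        J_oracle = _bisection_single_node_fic(p, target)
        assert J.J0[0] == pytest.approx(J_oracle, abs=1e-3)

    def test_calibrated_rates_hit_band(self, small_connectome, short_params, small_J0):
        ver = short_params.with_(t_total=60.0, t_burn=5.0)
        out = integrate(ver, small_connectome, small_J0, seed=31)
        assert out.mean_rate.min() >= 3.0
        assert out.mean_rate.max() <= 4.0

    def test_all_weights_positive(self, small_J0):
        assert (small_J0.J0 > 0).all()

    def test_stronger_connectome_needs_no_less_inhibition(self, small_cfg):
        # compare two weight scales that both keep the balanced state stable;
        # doubling excitatory in-strength must not reduce any calibrated J
        from dmfit import gen_connectome

        p = DMFParameters(sigma_g=0.0)
        C = gen_connectome(small_cfg).C
        J1 = calibrate_fic(p, 0.4 * C, rate_tol=0.05, seed=0)
        J2 = calibrate_fic(p, 0.8 * C, rate_tol=0.05, seed=0)
        assert (J2.J0 >= J1.J0 - 1e-6).all()


class TestContainers:
    def test_connectome_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            StructuralConnectome(C=np.array([[0.0, 1.0], [0.5, 0.0]])).validate()
        with pytest.raises(ValueError, match="diagonal"):
            StructuralConnectome(C=np.array([[1.0, 0.5], [0.5, 0.0]])).validate()
        with pytest.raises(ValueError, match="nonnegative"):
            StructuralConnectome(C=np.array([[0.0, -0.5], [-0.5, 0.0]])).validate()

    def test_fic_requires_positive_baseline(self):
        with pytest.raises(ValueError):
            FICVector(J0=np.array([1.0, 0.0]))

    def test_params_validation(self):
        with pytest.raises(ValueError):
            DMFParameters(dt=0.01).validate()  # not << tau_GABA
        with pytest.raises(ValueError):
            DMFParameters(t_burn=200.0).validate()
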