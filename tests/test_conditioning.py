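"""Tests of the Doob h-transform machinery against independent oracles."""

import numpy as np
import pytest

from selbridge import (
    InfeasibleBridgeError,
    ModelSpec,
    absorption_probs,
    asymptotic_conditional_matrix,
    asymptotic_conditional_row,
    build_transition_matrix,
    conditional_transition_row,
    hitting_profile,
    simulate_unconditioned_ensemble,
    spectral_data,
    spectral_phi,
)

from conftest import bridge_law_by_enumeration


def test_hitting_profile_zero_and_one_step(moran6_s2):
    prof0 = hitting_profile(moran6_s2, 4, 0)
    expected = np.zeros(7)
    expected[4] = 1.0
    np.testing.assert_array_equal(prof0.h, expected)
    assert prof0.log_scale == 0.0

    prof1 = hitting_profile(moran6_s2, 4, 1)
    col = moran6_s2.P[:, 4]
    np.testing.assert_allclose(prof1.h * np.exp(prof1.log_scale), col, atol=1e-14)


def test_hitting_profile_matches_monte_carlo():
    """h_m(i) equals the simulated frequency of being at k after m steps."""
    spec = ModelSpec("moran", 4, 2.0)
    tm = build_transition_matrix(spec)
    prof = hitting_profile(tm, 4, 6)
    exact = prof.h * np.exp(prof.log_scale)
    n = 100_000
    for i in range(5):
        states = simulate_unconditioned_ensemble(spec, i, 6, n, seed=100 + i)
        freq = np.mean(states[:, -1] == 4)
        se = np.sqrt(max(exact[i] * (1 - exact[i]), 1e-12) / n)
        assert abs(freq - exact[i]) <= 3 * se + 1e-9


@pytest.mark.parametrize("family", ["moran", "wright_fisher"])
@pytest.mark.parametrize("s", [0.5, 1.0, 2.0, 5.0])
def test_conditioned_rows_sum_to_one(family, s):
    """Doob normalization: every feasible conditioned row is a distribution."""
    tm = build_transition_matrix(ModelSpec(family, 10, s))
    for k in (0, 3, 10):
        for m in (1, 2, 5, 40):
            for i in range(11):
                try:
                    row = conditional_transition_row(tm, i, k, m)
                except InfeasibleBridgeError:
                    continue
                assert row.min() >= 0.0
                assert row.sum() == pytest.approx(1.0, abs=1e-10)
        if k in (0, 10):
            u = absorption_probs(tm, k).u
            for i in np.flatnonzero(u > 0):
                row = asymptotic_conditional_row(tm, int(i), k)
                assert row.sum() == pytest.approx(1.0, abs=1e-10)
        else:
            for i in range(1, 10):
                row = asymptotic_conditional_row(tm, i, k)
                assert row.sum() == pytest.approx(1.0, abs=1e-10)


def test_forced_last_step_is_indicator(moran6_s2):
    row = conditional_transition_row(moran6_s2, 3, 4, 1)
    expected = np.zeros(7)
    expected[4] = 1.0
    np.testing.assert_allclose(row, expected, atol=1e-14)


def test_neutral_symmetric_conditioning(moran4_neutral):
    """Neutral chain conditioned on a symmetric endpoint keeps up/down symmetry."""
    for m in (2, 5, 10):
        row = conditional_transition_row(moran4_neutral, 2, 2, m)
        assert row[1] == pytest.approx(row[3], abs=1e-12)


def test_infeasible_bridge_raises(moran6_s2):
    with pytest.raises(InfeasibleBridgeError):
        conditional_transition_row(moran6_s2, 1, 6, 2)  # too far for 2 steps
    with pytest.raises(InfeasibleBridgeError):
        conditional_transition_row(moran6_s2, 0, 3, 50)  # absorbed start
    with pytest.raises(InfeasibleBridgeError):
        asymptotic_conditional_row(moran6_s2, 0, 6)  # u_{0,N} = 0


def test_conditional_row_matches_rejection_sampling(moran6_s2):
    """First-step law of rejection-sampled bridges matches the transformed row."""
    spec = ModelSpec("moran", 6, 2.0)
    i, k, m = 3, 6, 10
    row = conditional_transition_row(moran6_s2, i, k, m)
    n = 400_000
    states = simulate_unconditioned_ensemble(spec, i, m, n, seed=7)
    accepted = states[states[:, -1] == k]
    assert accepted.shape[0] > 1000
    for j in np.flatnonzero(moran6_s2.P[i]):
        freq = np.mean(accepted[:, 1] == j)
        se = np.sqrt(max(row[j] * (1 - row[j]), 1e-12) / accepted.shape[0])
        assert abs(freq - row[j]) <= 3 * se + 1e-9


def test_bridge_path_law_equals_enumeration():
    """Product of conditioned rows = enumeration-renormalized path law (TV ~ 0)."""
    for s in (0.5, 1.0, 2.0):
        tm = build_transition_matrix(ModelSpec("moran", 4, s))
        i0, k, T = 2, 3, 4
        exact = bridge_law_by_enumeration(tm.P, i0, k, T)
        tv = 0.0
        for path, prob in exact.items():
            q = 1.0
            for t in range(T):
                row = conditional_transition_row(tm, path[t], k, T - t)
                q *= row[path[t + 1]]
            tv += abs(q - prob)
        assert tv < 1e-10


def test_spectral_eigen_equation(moran4_neutral):
    """(P restricted to transient states) w0 = lambda0 w0, components positive."""
    sd = spectral_data(moran4_neutral)
    Q = moran4_neutral.P[1:-1, 1:-1]
    np.testing.assert_allclose(Q @ sd.w[1:-1], sd.lam0 * sd.w[1:-1], atol=1e-12)
    assert 0 < sd.lam0 < 1
    assert sd.w[1:-1].min() > 0


def test_spectral_phi_diagonal_identity(moran6_s2):
    sd = spectral_data(moran6_s2)
    for i in (1, 3, 5):
        assert spectral_phi(moran6_s2, i, i, sd) == pytest.approx(1 / sd.lam0)


def test_finite_horizon_phi_converges_to_spectral(moran6_s2):
    """phi_{ij|k}(m) for transient k approaches w0(j)/(lambda0 w0(i)) as m grows."""
    sd = spectral_data(moran6_s2)
    k, m = 3, 500
    for i in (1, 3, 5):
        row = conditional_transition_row(moran6_s2, i, k, m)
        for j in np.flatnonzero(moran6_s2.P[i][1:-1]) + 1:
            phi_m = row[j] / moran6_s2.P[i, j]
            phi_inf = spectral_phi(moran6_s2, i, int(j), sd)
            assert abs(phi_m - phi_inf) / phi_inf < 1e-6


@pytest.mark.parametrize("s", [0.5, 2.0, 5.0])
@pytest.mark.parametrize("N", [4, 10, 20])
def test_moran_absorption_closed_form(N, s):
    """Birth–death ladder: u_iN = (1 - s^i)/(1 - s^N) since Q_i/P_i = s."""
    tm = build_transition_matrix(ModelSpec("moran", N, s))
    u = absorption_probs(tm, N).u
    i = np.arange(N + 1)
    expected = (1.0 - s**i) / (1.0 - float(s) ** N)
    np.testing.assert_allclose(u, expected, atol=1e-10)


@pytest.mark.parametrize("family", ["moran", "wright_fisher"])
def test_neutral_absorption_is_linear(family):
    """Martingale + optional stopping: u_iN = i/N at s = 1, both families."""
    tm = build_transition_matrix(ModelSpec(family, 12, 1.0))
    u = absorption_probs(tm, 12).u
    np.testing.assert_allclose(u, np.arange(13) / 12, atol=1e-10)


def test_absorption_profile_invariants(moran6_s2):
    u_n = absorption_probs(moran6_s2, 6).u
    u_0 = absorption_probs(moran6_s2, 0).u
    assert u_n[6] == 1.0 and u_n[0] == 0.0
    assert u_0[0] == 1.0 and u_0[6] == 0.0
    np.testing.assert_allclose(u_0 + u_n, 1.0, atol=1e-10)


def test_fixation_conditioning_biases_upward():
    """Conditioning on fixation of B shifts mass to up-moves."""
    tm = build_transition_matrix(ModelSpec("moran", 54, 2.0))
    row = asymptotic_conditional_row(tm, 53, 54)
    assert row[54] > tm.P[53, 54]


def test_asymptotic_row_is_long_horizon_limit(moran6_s2):
    """Absorbing conditioning equals the m = 500 finite-horizon transform."""
    for i in (1, 3, 5):
        finite = conditional_transition_row(moran6_s2, i, 0, 500)
        asym = asymptotic_conditional_row(moran6_s2, i, 0)
        np.testing.assert_allclose(finite, asym, atol=1e-8)


def test_asymptotic_matrix_matches_rejection_sampling_neutral():
    """Neutral chain conditioned on fixation vs rejection-sampled paths."""
    spec = ModelSpec("moran", 6, 1.0)
    tm = build_transition_matrix(spec)
    M = asymptotic_conditional_matrix(tm, 6)
    n, horizon = 200_000, 300
    states = simulate_unconditioned_ensemble(spec, 3, horizon, n, seed=11)
    fixed = states[states[:, -1] == 6]
    assert fixed.shape[0] > 10_000
    for j in (2, 3, 4):
        freq = np.mean(fixed[:, 1] == j)
        p = M[3, j]
        se = np.sqrt(p * (1 - p) / fixed.shape[0])
        assert abs(freq - p) <= 3 * se + 1e-9
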