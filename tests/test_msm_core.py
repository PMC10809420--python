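"""Count matrices, MSM estimators and spectral analysis."""

import numpy as np
import pytest
import scipy.optimize

from msmselect.msm_core import (CountMatrices, count_transitions,
                                estimate_nonreversible, estimate_reversible_mle,
                                eigenvector_overlap, implied_timescales,
                                largest_connected_set, mfpt,
                                reversible_mle_likelihood_trace,
                                spectral_decomposition, two_state_split)
from msmselect.synthetic_data import GroundTruthMSM, sample_discrete_trajectories


def brute_force_reversible_mle(C: np.ndarray) -> np.ndarray:
    """Independent oracle: maximize the constrained likelihood directly over
    the log upper triangle of the symmetric flux matrix (analytic gradient)."""
    n = C.shape[0]
    rows = C.sum(axis=1)
    iu = np.triu_indices(n)

    def unpack(u):
        X = np.zeros((n, n))
        X[iu] = np.exp(u)
        X = X + np.triu(X, 1).T
        return X

    def negll_grad(u):
        X = unpack(u)
        x = X.sum(axis=1)
        T = X / x[:, None]
        mask = C > 0
        ll = np.sum(C[mask] * np.log(T[mask]))
        # dL/dX_ab for a<b: c_ab/x_ab + c_ba/x_ba - c_a/x_a - c_b/x_b
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(X > 0, C / X, 0.0)
        rowterm = rows / x
        G = np.zeros((n, n))
        a, b = iu
        offdiag = a != b
        G[a[offdiag], b[offdiag]] = (
            ratio[a[offdiag], b[offdiag]] + ratio[b[offdiag], a[offdiag]]
            - rowterm[a[offdiag]] - rowterm[b[offdiag]]
        )
        diag = ~offdiag
        G[a[diag], b[diag]] = ratio[a[diag], b[diag]] - rowterm[a[diag]]
        grad_u = G[iu] * np.exp(u)  # chain rule through the log parametrization
        return -ll, -grad_u

    X0 = (C + C.T) / 2.0
    u0 = np.log(np.maximum(X0[iu], 1e-8))
    res = scipy.optimize.minimize(negll_grad, u0, jac=True, method="L-BFGS-B",
                                  options={"gtol": 1e-14, "ftol": 1e-17, "maxiter": 20_000})
    X = unpack(res.x)
    return X / X.sum(axis=1)[:, None]


class TestCounting:
    def test_hand_enumerated_alternating_trajectory(self):
        C = count_transitions([np.array([0, 1, 0, 1])], lag=1)
        assert np.array_equal(C.C0t, [[0, 2], [1, 0]])
        assert np.array_equal(np.diag(C.C00), [2, 1])
        assert np.array_equal(np.diag(C.Ctt), [1, 2])

    def test_maximum_lag_yields_single_count(self):
        d = np.array([0, 1, 2, 1, 0])
        C = count_transitions([d], lag=4)
        assert C.total == 1
        assert C.C0t[0, 0] == 1

    def test_counts_additive_over_trajectories(self):
        rng = np.random.default_rng(0)
        a, b = rng.integers(0, 3, 50), rng.integers(0, 3, 70)
        C_joint = count_transitions([a, b], lag=2, n_states=3)
        C_a = count_transitions([a], lag=2, n_states=3)
        C_b = count_transitions([b], lag=2, n_states=3)
        assert np.array_equal(C_joint.C0t, C_a.C0t + C_b.C0t)

    def test_short_trajectories_contribute_nothing(self):
        C = count_transitions([np.array([0, 1]), np.array([1, 0, 1, 0])], lag=2)
        assert C.total == 2  # only the length-4 trajectory counts

    def test_all_short_rejected(self):
        with pytest.raises(ValueError):
            count_transitions([np.array([0, 1])], lag=5)


class TestConnectedSet:
    def test_fully_connected_keeps_all(self):
        C = CountMatrices(np.ones((3, 3)), lag=1)
        keep, sub = largest_connected_set(C)
        assert np.array_equal(keep, [0, 1, 2])
        assert sub.n_states == 3

    def test_block_diagonal_larger_block_wins(self):
        # states {0,1} strongly connected, {2,3,4} strongly connected
        C = np.zeros((5, 5))
        C[0, 1] = C[1, 0] = 1
        C[2, 3] = C[3, 4] = C[4, 2] = 1
        keep, sub = largest_connected_set(CountMatrices(C, lag=1))
        assert np.array_equal(keep, [2, 3, 4])
        assert np.array_equal(sub.active_set, [2, 3, 4])

    def test_equal_size_tie_goes_to_lowest_index(self):
        C = np.zeros((4, 4))
        C[0, 1] = C[1, 0] = 1
        C[2, 3] = C[3, 2] = 1
        keep, _ = largest_connected_set(CountMatrices(C, lag=1))
        assert np.array_equal(keep, [0, 1])

    def test_isolated_state_dropped(self):
        C = np.zeros((3, 3))
        C[0, 1] = C[1, 0] = 5
        keep, _ = largest_connected_set(CountMatrices(C, lag=1))
        assert np.array_equal(keep, [0, 1])


class TestNonreversible:
    def test_row_normalization_by_hand(self):
        C = CountMatrices(np.array([[0.0, 2.0], [1.0, 0.0]]), lag=1)
        m = estimate_nonreversible(C)
        assert np.allclose(m.T, [[0, 1], [1, 0]])

    def test_symmetric_counts_already_reversible(self):
        C = CountMatrices(np.array([[4.0, 2.0], [2.0, 4.0]]), lag=1)
        m = estimate_nonreversible(C)
        flux = m.pi[:, None] * m.T
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_scale_invariance(self, random_counts):
        for C in random_counts:
            t1 = estimate_nonreversible(CountMatrices(C, lag=1)).T
            t2 = estimate_nonreversible(CountMatrices(7.5 * C, lag=1)).T
            assert np.allclose(t1, t2, atol=1e-14)


class TestReversibleMLE:
    def test_symmetric_counts_closed_form(self):
        C = CountMatrices(np.array([[4.0, 2.0], [2.0, 4.0]]), lag=1)
        m = estimate_reversible_mle(C)
        assert np.allclose(m.T, [[2 / 3, 1 / 3], [1 / 3, 2 / 3]], atol=1e-12)
        assert np.allclose(m.pi, [0.5, 0.5], atol=1e-12)

    def test_matches_brute_force_constrained_likelihood(self, random_counts):
        for C in random_counts:
            m = estimate_reversible_mle(CountMatrices(C, lag=1), tol=1e-14)
            T_oracle = brute_force_reversible_mle(C)
            assert np.max(np.abs(m.T - T_oracle)) < 1e-8

    def test_detailed_balance_satisfied(self, random_counts):
        for C in random_counts:
            m = estimate_reversible_mle(CountMatrices(C, lag=1))
            flux = m.pi[:, None] * m.T
            assert np.max(np.abs(flux - flux.T)) < 1e-10

    def test_likelihood_nondecreasing_over_iterations(self, random_counts):
        for C in random_counts:
            trace = reversible_mle_likelihood_trace(CountMatrices(C, lag=1), 200)
            assert np.all(np.diff(trace) > -1e-10)

    def test_rows_stochastic(self, random_counts):
        for C in random_counts:
            m = estimate_reversible_mle(CountMatrices(C, lag=1))
            assert np.allclose(m.T.sum(axis=1), 1.0, atol=1e-12)


class TestSpectral:
    def test_leading_pair_is_trivial(self, random_counts):
        for C in random_counts:
            m = estimate_reversible_mle(CountMatrices(C, lag=1))
            spectral_decomposition(m, m.n_states)
            assert m.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)
            psi1 = m.right_eigenvectors[:, 0]
            assert np.allclose(psi1, psi1[0], atol=1e-8)

    def test_two_state_trace_closed_form(self):
        m = estimate_nonreversible(CountMatrices(np.array([[9.0, 1.0], [2.0, 8.0]]), lag=1))
        spectral_decomposition(m, 2)
        assert m.eigenvalues[1] == pytest.approx(0.7, abs=1e-12)

    def test_reversible_solver_matches_generic_eigensolver(self, random_counts):
        for C in random_counts:
            m = estimate_reversible_mle(CountMatrices(C, lag=1))
            spectral_decomposition(m, m.n_states)
            generic = np.sort(np.real(np.linalg.eigvals(m.T)))[::-1]
            assert np.max(np.abs(m.eigenvalues - generic)) < 1e-10

    def test_pi_orthonormality_and_sign_convention(self, random_counts):
        C = random_counts[-1]
        m = estimate_reversible_mle(CountMatrices(C, lag=1))
        spectral_decomposition(m, m.n_states)
        psi = m.right_eigenvectors
        G = np.einsum("i,ia,ib->ab", m.pi, psi, psi)
        assert np.allclose(G, np.eye(psi.shape[1]), atol=1e-8)
        for a in range(psi.shape[1]):
            nz = psi[np.abs(psi[:, a]) > 1e-12, a]
            assert nz[0] > 0


class TestTimescalesAndMFPT:
    def test_analytic_timescale_values(self):
        m = estimate_nonreversible(CountMatrices(np.array([[9.0, 1.0], [2.0, 8.0]]), lag=10))
        ts = implied_timescales(m, 2)
        assert ts[0] == pytest.approx(-10 / np.log(0.7), abs=1e-9)

    def test_negative_eigenvalue_flagged_not_numeric(self):
        m = estimate_nonreversible(CountMatrices(np.array([[1.0, 9.0], [9.0, 1.0]]), lag=1))
        ts = implied_timescales(m, 2)
        assert np.isnan(ts[0])

    def test_timescale_monotone_in_lambda(self):
        lams = np.linspace(0.1, 0.99, 20)
        ts = [-1 / np.log(l) for l in lams]
        assert np.all(np.diff(ts) > 0)
        # e^-1 at unit lag gives exactly 1 step
        m = GroundTruthMSM.from_matrix(np.array([[0.5 + np.exp(-1) / 2, 0.5 - np.exp(-1) / 2],
                                                 [0.5 - np.exp(-1) / 2, 0.5 + np.exp(-1) / 2]]))
        mm = estimate_nonreversible(CountMatrices(m.transition_matrix * 1000, lag=1))
        assert implied_timescales(mm, 2)[0] == pytest.approx(1.0, abs=1e-9)

    def test_mfpt_two_state_closed_form(self):
        for lag in (1, 10):
            m = estimate_nonreversible(
                CountMatrices(np.array([[9.0, 1.0], [2.0, 8.0]]), lag=lag))
            times = mfpt(m, [1])
            assert times[0] == pytest.approx(10.0 * lag, abs=1e-9)  # 1/p rule
            assert times[1] == 0.0


class TestEigenvectorCharacter:
    def test_two_state_model_splits_apart(self):
        m = estimate_nonreversible(CountMatrices(np.array([[9.0, 1.0], [2.0, 8.0]]), lag=1))
        split = two_state_split(m)
        assert set(split) == {0, 1}

    def test_symmetric_chain_splits_at_middle(self):
        # 4-state nearest-neighbour chain; brute-force psi_2 changes sign at the centre
        T = np.array([
            [0.9, 0.1, 0.0, 0.0],
            [0.1, 0.8, 0.1, 0.0],
            [0.0, 0.1, 0.8, 0.1],
            [0.0, 0.0, 0.1, 0.9],
        ])
        m = estimate_reversible_mle(CountMatrices(T * 1000, lag=1))
        split = two_state_split(m)
        assert np.array_equal(split, [split[0]] * 2 + [1 - split[0]] * 2)

    def test_partition_invariant_to_sign_flip(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        m = estimate_nonreversible(CountMatrices(T * 100, lag=1))
        spectral_decomposition(m, 2)
        split_a = two_state_split(m)
        m.right_eigenvectors = m.right_eigenvectors.copy()
        m.right_eigenvectors[:, 1] *= -1
        split_b = two_state_split(m)
        assert (np.array_equal(split_a, split_b)
                or np.array_equal(split_a, 1 - split_b))

    def test_overlap_same_model_is_one(self, toy_dtrajs):
        from msmselect.msm_core import count_transitions
        C = count_transitions(toy_dtrajs, lag=1)
        _, Cr = largest_connected_set(C)
        m = estimate_reversible_mle(Cr)
        frames = np.concatenate(toy_dtrajs)
        assert eigenvector_overlap(m, frames, m, frames) == pytest.approx(1.0)

    def test_overlap_with_flipped_psi2_still_one(self, toy_dtrajs):
        C = count_transitions(toy_dtrajs, lag=1)
        _, Cr = largest_connected_set(C)
        m1 = estimate_reversible_mle(Cr)
        m2 = estimate_reversible_mle(Cr)
        spectral_decomposition(m2, m2.n_states)
        m2.right_eigenvectors[:, 1] *= -1
        frames = np.concatenate(toy_dtrajs)
        assert eigenvector_overlap(m1, frames, m2, frames) == pytest.approx(1.0)

    def test_independent_processes_have_near_zero_overlap(self, toy_model):
        a = sample_discrete_trajectories(toy_model, 1, 20_000, seed=100)
        b = sample_discrete_trajectories(toy_model, 1, 20_000, seed=200)
        ma = estimate_reversible_mle(largest_connected_set(count_transitions(a, 1))[1])
        mb = estimate_reversible_mle(largest_connected_set(count_transitions(b, 1))[1])
        r = eigenvector_overlap(ma, a[0], mb, b[0])
        assert r < 3 / np.sqrt(20_000) * 3  # generous null bound


class TestRecoveryProperties:
    def test_transition_matrix_error_decreases_with_length(self, toy_model):
        errs = []
        for length in (1_000, 10_000, 100_000, 1_000_000):
            (d,) = sample_discrete_trajectories(toy_model, 1, length, seed=13)
            m = estimate_reversible_mle(largest_connected_set(count_transitions([d], 1))[1])
            errs.append(np.max(np.abs(m.T - toy_model.transition_matrix)))
        assert all(a > b for a, b in zip(errs, errs[1:]))

    def test_variational_bound_under_state_merging(self, toy_dtrajs):
        """Lumping microstates can only lower the summed eigenvalues (within
        sampling error on matched data)."""
        C_fine = count_transitions(toy_dtrajs, lag=1)
        m_fine = estimate_reversible_mle(largest_connected_set(C_fine)[1])
        spectral_decomposition(m_fine, 2)
        merged = [np.where(d == 2, 1, d) for d in toy_dtrajs]  # lump states 1 and 2
        C_coarse = count_transitions(merged, lag=1)
        m_coarse = estimate_reversible_mle(largest_connected_set(C_coarse)[1])
        spectral_decomposition(m_coarse, 2)
        fine_sum = np.sum(m_fine.eigenvalues[:2])
        coarse_sum = np.sum(m_coarse.eigenvalues[:2])
        assert coarse_sum <= fine_sum + 0.02
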