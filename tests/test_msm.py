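"""Counting, estimation, spectra, implied timescales and propagation."""

import numpy as np
import pytest

from lidmsm.msm import (
    CountMatrix,
    MarkovStateModel,
    PopulationVector,
    count_transitions,
    estimate_nonreversible,
    estimate_reversible_mle,
    implied_timescale_curves,
    propagate,
    spectral_analysis,
)
from lidmsm.synthetic import planted_four_state_matrix, simulate_chain, SyntheticChainSpec


def random_reversible_T(n, rng):
    """Reversible chain from a random symmetric positive weight matrix."""
    W = rng.uniform(0.1, 1.0, size=(n, n))
    W = W + W.T
    return W / W.sum(axis=1, keepdims=True)


class TestCountTransitions:
    def test_sliding_window_enumeration(self):
        cm = count_transitions([[0, 0, 1, 1, 0]], lag=1)
        assert cm.counts.tolist() == [[1, 1], [1, 1]]

    def test_lag_two_on_alternating_labels(self):
        # pairs (t0,t2) and (t1,t3) are 0->0 and 1->1 (before ergodic trimming)
        cm = count_transitions([[0, 1, 0, 1]], lag=2, trim=False)
        assert cm.counts.tolist() == [[1, 0], [0, 1]]

    def test_strided_counts_skip_overlapping_pairs(self):
        cm = count_transitions([[0, 1, 0, 1, 0]], lag=2, mode="strided")
        # strided frames: 0, 0, 0 -> two 0->0 pairs
        assert cm.counts.tolist() == [[2]]
        assert cm.ergodic_subset == [0]

    def test_matches_brute_force_on_random_streams(self):
        rng = np.random.default_rng(0)
        trajs = [rng.integers(0, 4, size=rng.integers(5, 60)) for _ in range(20)]
        lag = 3
        cm = count_transitions(trajs, lag=lag, trim=False)
        expected = np.zeros((4, 4), dtype=int)
        for t in trajs:
            for i in range(len(t) - lag):
                expected[t[i], t[i + lag]] += 1
        assert np.array_equal(cm.counts, expected)

    def test_error_when_no_trajectory_longer_than_lag(self):
        with pytest.raises(ValueError, match="lag \\(10"):
            count_transitions([[0, 1, 0]], lag=10)

    def test_trimming_keeps_largest_strong_component(self):
        # state 2 is a sink reached once: not part of the ergodic core
        cm = count_transitions([[0, 1, 0, 1, 0, 2]], lag=1)
        assert cm.ergodic_subset == [0, 1]
        assert cm.dropped_states == [2]


class TestNonreversible:
    def test_row_normalization_example(self):
        cm = CountMatrix(np.array([[8, 2], [1, 9]]), 1, 2, [0, 1])
        model = estimate_nonreversible(cm)
        assert np.allclose(model.T, [[0.8, 0.2], [0.1, 0.9]])

    def test_single_state(self):
        cm = CountMatrix(np.array([[5]]), 1, 1, [0])
        model = estimate_nonreversible(cm)
        assert model.T.tolist() == [[1.0]]

    def test_matches_hand_normalization_on_random_counts(self):
        rng = np.random.default_rng(1)
        C = rng.integers(1, 50, size=(5, 5))
        model = estimate_nonreversible(CountMatrix(C, 1, 5, list(range(5))))
        assert np.allclose(model.T.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(model.T, C / C.sum(axis=1, keepdims=True))


class TestReversibleMle:
    def test_symmetric_counts_reduce_to_row_normalization(self):
        cm = CountMatrix(np.array([[4, 2], [2, 4]]), 1, 2, [0, 1])
        model = estimate_reversible_mle(cm)
        assert np.allclose(model.T, [[2 / 3, 1 / 3], [1 / 3, 2 / 3]], atol=1e-14)

    def test_detailed_balance_and_local_optimality(self):
        cm = CountMatrix(np.array([[8, 2], [1, 9]]), 1, 2, [0, 1])
        model = estimate_reversible_mle(cm)
        pi = model.stationary
        flux = pi[:, None] * model.T
        assert np.allclose(flux, flux.T, atol=1e-10)
        # local-search oracle: no nearby reversible matrix beats the MLE
        C = cm.counts

        def log_likelihood(T):
            mask = C > 0
            return float((C[mask] * np.log(T[mask])).sum())

        best = log_likelihood(model.T)
        rng = np.random.default_rng(2)
        for _ in range(200):
            # perturb the symmetric flux matrix, renormalize
            x = flux * np.exp(0.01 * rng.standard_normal())
            bump = 0.005 * rng.standard_normal((2, 2))
            x = np.abs(x + 0.5 * (bump + bump.T))
            T = x / x.sum(axis=1, keepdims=True)
            assert log_likelihood(T) <= best + 1e-12

    def test_parameter_recovery_within_three_standard_errors(self):
        T_true = planted_four_state_matrix()
        spec = SyntheticChainSpec(
            n_states=4, T_true=T_true,
            emission_means=np.eye(4), emission_sd=0.0, n_features=4,
            length_mean=2, length_max=2, n_trajectories=1, n_initial_states=1,
            seed=7,
        )
        labels, _ = simulate_chain(spec, lengths=[200000])
        cm = count_transitions(labels, lag=1)
        model = estimate_reversible_mle(cm)
        rows = cm.counts.sum(axis=1)
        for i in range(4):
            for j in range(4):
                se = np.sqrt(T_true[i, j] * (1 - T_true[i, j]) / rows[i])
                assert abs(model.T[i, j] - T_true[i, j]) < 3 * se + 1e-9

    def test_db_consistent_counts_equal_plain_normalization(self):
        rng = np.random.default_rng(3)
        T = random_reversible_T(4, rng)
        counts = np.round(1e6 * T * 0.25).astype(int)  # uniform pi, symmetric
        rev = estimate_reversible_mle(CountMatrix(counts, 1, 4, list(range(4))))
        plain = counts / counts.sum(axis=1, keepdims=True)
        assert np.allclose(rev.T, plain, atol=1e-9)


class TestSpectralAnalysis:
    def test_identity_matrix_all_timescales_infinite(self):
        model = spectral_analysis(np.eye(2), lag_time=1.0, reversible=True)
        assert np.allclose(model.eigenvalues, [1.0, 1.0])
        assert np.all(np.isinf(model.implied_timescales))

    def test_two_state_closed_form(self):
        model = spectral_analysis(
            np.array([[0.9, 0.1], [0.2, 0.8]]), lag_time=1.0, reversible=True
        )
        assert np.allclose(model.eigenvalues, [1.0, 0.7], atol=1e-12)
        assert np.allclose(model.stationary, [2 / 3, 1 / 3], atol=1e-12)
        assert model.implied_timescales[1] == pytest.approx(-1 / np.log(0.7))

    def test_matches_symmetrization_oracle(self):
        rng = np.random.default_rng(4)
        T = random_reversible_T(5, rng)
        model = spectral_analysis(T, lag_time=1.0, reversible=True)
        pi = model.stationary
        M = np.sqrt(pi)[:, None] * T / np.sqrt(pi)[None, :]
        oracle = np.sort(np.linalg.eigvalsh(M))[::-1]
        assert np.allclose(model.eigenvalues, oracle, atol=1e-8)
        # biorthonormality and stationarity
        assert np.allclose(model.left_eigenvectors @ model.right_eigenvectors,
                           np.eye(5), atol=1e-8)
        assert np.allclose(pi @ T, pi, atol=1e-10)

    def test_sign_convention_nonnegative_entry_sums(self):
        rng = np.random.default_rng(5)
        T = random_reversible_T(6, rng)
        model = spectral_analysis(T, lag_time=1.0, reversible=True)
        for n in range(1, 6):
            s = model.right_eigenvectors[:, n].sum()
            if abs(s) > 1e-8:
                assert s > 0

    def test_non_stochastic_input_rejected(self):
        with pytest.raises(ValueError, match="stochastic"):
            spectral_analysis(np.array([[0.5, 0.2], [0.1, 0.9]]), lag_time=1.0)


class TestImpliedTimescaleCurves:
    def test_flat_curve_for_exact_markov_chain(self, planted_chain_data):
        _, labels, _ = planted_chain_data
        table = implied_timescale_curves(labels, [1, 2, 5, 10], n_timescales=2)
        truth = -1 / np.log(0.95)
        rel = np.abs(table["tau_1"] - truth) / truth
        assert np.all(rel < 0.15)

    def test_gap_ratio_matches_planted_spectrum(self, planted_chain_data):
        _, labels, _ = planted_chain_data
        table = implied_timescale_curves(labels, [1], n_timescales=2)
        expected = np.log(0.5) / np.log(0.95)  # ~13.5
        assert table["gap_ratio"].iloc[0] == pytest.approx(expected, rel=0.15)

    def test_single_lag_gives_single_row(self, planted_chain_data):
        _, labels, _ = planted_chain_data
        table = implied_timescale_curves(labels[:10], [1], n_timescales=2)
        assert len(table) == 1

    def test_relabeling_leaves_timescales_unchanged(self, planted_chain_data):
        _, labels, _ = planted_chain_data
        perm = np.array([2, 0, 3, 1])
        relabeled = [perm[t] for t in labels]
        a = implied_timescale_curves(labels, [1], n_timescales=2)
        b = implied_timescale_curves(relabeled, [1], n_timescales=2)
        assert a["tau_1"].iloc[0] == pytest.approx(b["tau_1"].iloc[0], abs=1e-9)

    def test_non_ascending_lags_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            implied_timescale_curves([[0, 1, 0, 1]], [2, 1], 1)


class TestPropagate:
    def test_stationary_start_stays_stationary(self):
        T = planted_four_state_matrix()
        model = spectral_analysis(T, lag_time=1.0, reversible=True)
        out = propagate(model, model.stationary, n_steps=5)
        for pv in out:
            assert np.allclose(pv.p, model.stationary, atol=1e-10)

    def test_zero_steps_returns_initial(self):
        T = planted_four_state_matrix()
        model = spectral_analysis(T, lag_time=1.0, reversible=True)
        p0 = np.array([1.0, 0.0, 0.0, 0.0])
        out = propagate(model, p0, n_steps=0)
        assert len(out) == 1 and np.allclose(out[0].p, p0)

    def test_spectral_equals_matrix_powers(self):
        rng = np.random.default_rng(6)
        T = random_reversible_T(4, rng)
        model = spectral_analysis(T, lag_time=1.0, reversible=True)
        p0 = np.array([0.0, 1.0, 0.0, 0.0])
        out = propagate(model, p0, n_steps=20)
        p = p0.copy()
        for k in range(1, 21):
            p = p @ T
            assert np.allclose(out[k].p, p, atol=1e-10)
            assert out[k].p.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.all(out[k].p >= -1e-12)

    def test_incomplete_spectrum_rejected(self):
        from lidmsm.msm import TransitionModel

        model = TransitionModel(T=np.eye(2), lag_time=1.0)
        with pytest.raises(ValueError, match="spectra"):
            propagate(model, np.array([1.0, 0.0]), 1)


class TestEstimatorFacade:
    def test_fit_exposes_spectral_attributes(self, planted_chain_data):
        _, labels, _ = planted_chain_data
        est = MarkovStateModel(lag=1).fit(labels)
        assert est.transition_matrix_.shape == (4, 4)
        assert est.eigenvalues_[0] == pytest.approx(1.0, abs=1e-10)
        assert np.isinf(est.timescales_[0])

    def test_population_vector_validation(self):
        with pytest.raises(ValueError):
            PopulationVector(np.array([0.7, 0.7]))
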