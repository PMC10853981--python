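import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import dynstates as ds
from dynstates.hmm import EmptyStateWarning

from _oracles import enumerate_posteriors
from conftest import align_states, random_hmm_params, simulate_gaussian_hmm


class TestForwardBackward:
    def test_single_state_reduces_to_gaussian_density(self):
        rng = np.random.default_rng(0)
        cov = np.array([[[2.0, 0.5], [0.5, 1.0]]])
        params = ds.HMMParams([1.0], [[1.0]], cov)
        X = rng.normal(size=(50, 2))
        post = ds.forward_backward(params, X)
        assert np.all(post.gamma == 1.0)
        expected = stats.multivariate_normal(np.zeros(2), cov[0]).logpdf(X).sum()
        assert post.loglik == pytest.approx(expected, abs=1e-8)

    def test_absorbing_start_forces_state_one(self):
        rng = np.random.default_rng(1)
        params = ds.HMMParams(
            [1.0, 0.0], np.eye(2),
            np.stack([np.eye(2), 3 * np.eye(2)]),
        )
        X = rng.normal(size=(20, 2))
        post = ds.forward_backward(params, X)
        assert np.allclose(post.gamma[:, 0], 1.0)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            K = int(rng.integers(1, 4))
            T = int(rng.integers(2, 9))
            params = random_hmm_params(rng, K, 2)
            X = rng.normal(size=(T, 2))
            post = ds.forward_backward(params, X)
            g, xi, ll, vit = enumerate_posteriors(params, X)
            assert np.abs(post.gamma - g).max() < 1e-10
            assert np.abs(post.xi_sum - xi).max() < 1e-10
            assert post.loglik == pytest.approx(ll, abs=1e-9)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_gamma_rows_sum_to_one_property(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(1, 5))
        params = random_hmm_params(rng, K, 3)
        X = rng.normal(size=(int(rng.integers(2, 40)), 3))
        post = ds.forward_backward(params, X)
        assert np.abs(post.gamma.sum(axis=1) - 1).max() < 1e-8
        assert np.isfinite(post.loglik)

    def test_segments_block_cross_boundary_transitions(self):
        rng = np.random.default_rng(3)
        params = random_hmm_params(rng, 2, 2)
        X = rng.normal(size=(40, 2))
        joint = ds.forward_backward(params, X, boundaries=[0, 20, 40])
        a = ds.forward_backward(params, X[:20])
        b = ds.forward_backward(params, X[20:])
        assert np.allclose(joint.gamma, np.vstack([a.gamma, b.gamma]))
        assert joint.loglik == pytest.approx(a.loglik + b.loglik)

    def test_long_sequence_numerically_stable(self):
        rng = np.random.default_rng(4)
        params = random_hmm_params(rng, 3, 2)
        _, X = simulate_gaussian_hmm(rng, params.transition_matrix,
                                     params.covariances, 200_000)
        post = ds.forward_backward(params, X)
        assert np.isfinite(post.loglik)
        assert np.abs(post.gamma.sum(axis=1) - 1).max() < 1e-8

    def test_singular_covariance_reports_regularization(self):
        params_cov = np.stack([np.eye(2), np.array([[1.0, 1.0], [1.0, 1.0]])])
        params = ds.HMMParams([0.5, 0.5], np.full((2, 2), 0.5), params_cov)
        with pytest.raises(np.linalg.LinAlgError, match="regulariz"):
            ds.forward_backward(params, np.zeros((5, 2)))


class TestViterbi:
    def test_matches_exhaustive_argmax(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            K = int(rng.integers(2, 4))
            T = int(rng.integers(2, 6))
            params = random_hmm_params(rng, K, 2)
            X = rng.normal(size=(T, 2))
            path = ds.viterbi(params, X)
            _, _, _, best = enumerate_posteriors(params, X)
            assert np.array_equal(path, best)

    def test_single_state_constant_path(self):
        params = ds.HMMParams([1.0], [[1.0]], np.eye(1)[None])
        path = ds.viterbi(params, np.random.default_rng(6).normal(size=(30, 1)))
        assert np.all(path == 1)

    def test_identical_states_tie_breaks_to_state_one(self):
        cov = np.eye(2)
        params = ds.HMMParams([0.5, 0.5], np.full((2, 2), 0.5),
                              np.stack([cov, cov]))
        path = ds.viterbi(params, np.random.default_rng(7).normal(size=(25, 2)))
        assert np.all(path == 1)


class TestEMFit:
    def test_two_state_parameter_recovery(self):
        rng = np.random.default_rng(8)
        A = np.array([[0.95, 0.05], [0.1, 0.9]])
        covs = np.stack([np.diag([1.0, 1.0, 0.2]), np.diag([0.2, 0.2, 1.5])])
        _, X = simulate_gaussian_hmm(rng, A, covs, 60_000)
        model = ds.TDEHMM(X, 2)
        res = model.fit(seed=0, n_restarts=2, max_iter=60)
        perm = align_states(res.params.covariances, covs)
        A_hat = res.params.transition_matrix[np.ix_(perm, perm)]
        assert np.abs(A_hat - A).max() < 0.02

    def test_single_state_covariance_closed_form(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(5000, 3))
        res = ds.TDEHMM(X, 1).fit(seed=0, n_restarts=1, max_iter=5, reg=1e-6)
        S = X.T @ X / X.shape[0]
        expected = S + 1e-6 * np.mean(np.diag(S)) * np.eye(3)
        assert np.abs(res.params.covariances[0] - expected).max() < 1e-10

    def test_loglik_trace_monotone_nondecreasing(self):
        rng = np.random.default_rng(10)
        A = np.array([[0.9, 0.1], [0.2, 0.8]])
        covs = np.stack([np.eye(2), 4 * np.eye(2)])
        _, X = simulate_gaussian_hmm(rng, A, covs, 10_000)
        res = ds.TDEHMM(X, 2).fit(seed=1, n_restarts=1, max_iter=40)
        diffs = np.diff(res.loglik_trace)
        assert np.all(diffs > -1e-6 * np.abs(res.loglik_trace[:-1]))

    def test_xi_sum_consistent_with_transition_update(self):
        rng = np.random.default_rng(11)
        A = np.array([[0.9, 0.1], [0.2, 0.8]])
        covs = np.stack([np.eye(2), 4 * np.eye(2)])
        _, X = simulate_gaussian_hmm(rng, A, covs, 20_000)
        model = ds.TDEHMM(X, 2)
        res = model.fit(seed=2, n_restarts=1, max_iter=40)
        xi = res.posterior.xi_sum
        A_from_xi = xi / xi.sum(axis=1, keepdims=True)
        # the M-step transition update is exactly the row-normalized counts
        updated, _ = model._m_step(res.posterior.gamma, xi, 1e-6)
        assert np.abs(A_from_xi - updated.transition_matrix).max() < 1e-12
        # and at convergence the fitted A has stabilized at that fixed point
        assert np.abs(A_from_xi - res.params.transition_matrix).max() < 1e-3

    def test_label_permutation_leaves_loglik_unchanged(self):
        rng = np.random.default_rng(12)
        params = random_hmm_params(rng, 3, 2)
        X = rng.normal(size=(500, 2))
        ll = ds.forward_backward(params, X).loglik
        perm = np.array([2, 0, 1])
        permuted = ds.HMMParams(
            params.initial_dist[perm],
            params.transition_matrix[np.ix_(perm, perm)],
            params.covariances[perm],
        )
        assert ds.forward_backward(permuted, X).loglik == pytest.approx(ll, abs=1e-8)

    def test_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(13)
        _, X = simulate_gaussian_hmm(
            rng, np.array([[0.9, 0.1], [0.1, 0.9]]),
            np.stack([np.eye(2), 3 * np.eye(2)]), 5000,
        )
        r1 = ds.TDEHMM(X, 2).fit(seed=3, n_restarts=2, max_iter=20)
        r2 = ds.TDEHMM(X, 2).fit(seed=3, n_restarts=2, max_iter=20)
        assert r1.loglik == r2.loglik
        assert np.array_equal(r1.params.transition_matrix, r2.params.transition_matrix)

    def test_overfit_states_handled_without_crash(self):
        # one-Gaussian data, five requested states: collapsing states must be
        # reinitialized or dropped, never crash
        rng = np.random.default_rng(14)
        X = rng.normal(size=(2000, 2))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", EmptyStateWarning)
            res = ds.TDEHMM(X, 5).fit(seed=4, n_restarts=1, max_iter=30)
        assert 1 <= res.params.n_states <= 5
        assert np.abs(res.posterior.gamma.sum(axis=1) - 1).max() < 1e-8

    def test_posteriors_match_reference_implementation(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(15)
        params = random_hmm_params(rng, 3, 2)
        X = rng.normal(size=(300, 2))
        ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="full", init_params="")
        ref.startprob_ = params.initial_dist
        ref.transmat_ = params.transition_matrix
        ref.means_ = np.zeros((3, 2))
        ref.covars_ = params.covariances
        post = ds.forward_backward(params, X)
        assert np.abs(post.gamma - ref.predict_proba(X)).max() < 1e-8
        assert post.loglik == pytest.approx(ref.score(X), abs=1e-6)


class TestConcatAndFit:
    def test_single_subject_equals_plain_fit(self):
        rng = np.random.default_rng(16)
        _, X = simulate_gaussian_hmm(
            rng, np.array([[0.9, 0.1], [0.1, 0.9]]),
            np.stack([np.eye(2), 3 * np.eye(2)]), 8000,
        )
        r1 = ds.TDEHMM(X, 2).fit(seed=5, n_restarts=1, max_iter=30)
        r2 = ds.concat_and_fit([X], 2, seed=5, n_restarts=1, max_iter=30)
        assert r1.loglik == pytest.approx(r2.loglik)

    def test_duplicated_subject_gives_same_transitions(self):
        rng = np.random.default_rng(17)
        A = np.array([[0.95, 0.05], [0.1, 0.9]])
        covs = np.stack([np.diag([1.0, 0.2]), np.diag([0.2, 1.5])])
        _, X = simulate_gaussian_hmm(rng, A, covs, 40_000)
        r1 = ds.concat_and_fit([X], 2, seed=6, n_restarts=2, max_iter=60)
        r2 = ds.concat_and_fit([X, X], 2, seed=6, n_restarts=2, max_iter=60)
        p1 = align_states(r1.params.covariances, covs)
        p2 = align_states(r2.params.covariances, covs)
        A1 = r1.params.transition_matrix[np.ix_(p1, p1)]
        A2 = r2.params.transition_matrix[np.ix_(p2, p2)]
        assert np.abs(A1 - A2).max() < 0.01

    def test_inconsistent_dimensionality_rejected(self):
        with pytest.raises(ValueError, match="dimensionality"):
            ds.concat_and_fit([np.zeros((100, 3)), np.zeros((100, 4))], 2)

    def test_mismatched_parcel_labels_rejected(self):
        rng = np.random.default_rng(18)
        a = ds.time_delay_embed(
            ds.ParcelTimeSeries(rng.normal(size=(50, 2)), fs=250.0,
                                parcel_labels=["m1", "v1"]), np.array([0]))
        b = ds.time_delay_embed(
            ds.ParcelTimeSeries(rng.normal(size=(50, 2)), fs=250.0,
                                parcel_labels=["v1", "m1"]), np.array([0]))
        with pytest.raises(ValueError, match="labels"):
            ds.concat_and_fit([a, b], 2)


def test_summary_reports_model_shape():
    rng = np.random.default_rng(19)
    _, X = simulate_gaussian_hmm(
        rng, np.array([[0.9, 0.1], [0.1, 0.9]]),
        np.stack([np.eye(2), 3 * np.eye(2)]), 4000,
    )
    res = ds.TDEHMM(X, 2).fit(seed=7, n_restarts=1, max_iter=20)
    text = res.summary()
    assert "states:              2" in text
    assert "log-likelihood" in text
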