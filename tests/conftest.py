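import itertools

import numpy as np
import pytest

import dynstates as ds


@pytest.fixture(scope="session")
def cohort_table():
    return ds.load_stroke_cohort()


def random_hmm_params(rng, n_states, n_features):
    """A random valid parameter set with well-conditioned covariances."""
    A = rng.dirichlet(np.ones(n_states), n_states)
    pi = rng.dirichlet(np.ones(n_states))
    covs = []
    for _ in range(n_states):
        M = rng.normal(size=(n_features, n_features))
        covs.append(M @ M.T + 0.3 * np.eye(n_features))
    return ds.HMMParams(pi, A, np.stack(covs))


def simulate_gaussian_hmm(rng, A, covs, n_samples, pi=None):
    """Sample (states 0-based, observations) from a zero-mean Gaussian HMM."""
    K = A.shape[0]
    Q = covs.shape[1]
    if pi is None:
        pi = np.full(K, 1.0 / K)
    states = np.empty(n_samples, dtype=int)
    states[0] = rng.choice(K, p=pi)
    cumA = np.cumsum(A, axis=1)
    u = rng.random(n_samples)
    for t in range(1, n_samples):
        states[t] = np.searchsorted(cumA[states[t - 1]], u[t])
    X = np.empty((n_samples, Q))
    for k in range(K):
        idx = states == k
        if idx.any():
            X[idx] = rng.multivariate_normal(np.zeros(Q), covs[k], size=int(idx.sum()))
    return states, X


def align_states(est_covs, true_covs):
    """Permutation of estimated states minimizing total covariance distance."""
    K = true_covs.shape[0]
    best = None
    for perm in itertools.permutations(range(K)):
        err = sum(np.abs(est_covs[perm[k]] - true_covs[k]).sum() for k in range(K))
        if best is None or err < best[0]:
            best = (err, perm)
    return np.asarray(best[1])
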