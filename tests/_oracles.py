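"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own algorithms: posteriors come from
exhaustive path enumeration, rank-test p-values from direct enumeration of
group assignments / sign flips / permutations.
"""

import itertools

import numpy as np
from scipy import stats


def enumerate_posteriors(params, X):
    """Exact gamma, xi_sum, loglik and most-probable path by summing over all
    K^T hidden paths (feasible for K <= 3, T <= 8)."""
    K = params.n_states
    T = X.shape[0]
    logB = params.log_obs(X)
    logpi = np.log(params.initial_dist)
    logA = np.log(np.maximum(params.transition_matrix, 1e-300))
    logps = []
    paths = list(itertools.product(range(K), repeat=T))
    for path in paths:
        lp = logpi[path[0]] + logB[0, path[0]]
        for t in range(1, T):
            lp += logA[path[t - 1], path[t]] + logB[t, path[t]]
        logps.append(lp)
    logps = np.asarray(logps)
    total = np.logaddexp.reduce(logps)
    w = np.exp(logps - total)
    gamma = np.zeros((T, K))
    xi = np.zeros((K, K))
    for path, wi in zip(paths, w):
        for t, k in enumerate(path):
            gamma[t, k] += wi
        for t in range(1, T):
            xi[path[t - 1], path[t]] += wi
    best = paths[int(np.argmax(logps))]
    return gamma, xi, float(total), np.asarray(best) + 1


def mannwhitney_exact_p(x, y):
    """Two-sided exact p by enumerating all group assignments of the pooled
    sample; extremeness measured as |U - n1*n2/2|."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, N = x.size, x.size + y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    mu = n1 * y.size / 2
    obs = abs(ranks[:n1].sum() - n1 * (n1 + 1) / 2 - mu)
    count = tot = 0
    for comb in itertools.combinations(range(N), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        tot += 1
        if abs(u - mu) >= obs - 1e-12:
            count += 1
    return count / tot


def wilcoxon_exact_p(diffs):
    """Two-sided exact p over all 2^n sign assignments (zeros dropped)."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    mu = ranks.sum() / 2
    obs = abs(ranks[d > 0].sum() - mu)
    n = d.size
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= obs - 1e-12:
            count += 1
    return count / 2**n


def spearman_exact_p(x, y):
    """Two-sided exact p over all n! permutations of y."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return np.sum(a * b) / np.sqrt(np.sum(a**2) * np.sum(b**2))

    obs = abs(corr(rx, ry))
    count = tot = 0
    for perm in itertools.permutations(ry):
        tot += 1
        if abs(corr(rx, np.asarray(perm))) >= obs - 1e-12:
            count += 1
    return count / tot
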