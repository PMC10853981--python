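"""Gaussian-observation hidden Markov model on time-delay-embedded data.

The model: K mutually exclusive states, a first-order Markov chain over them,
and per-state zero-mean multivariate Gaussian emissions in the embedded (PCA)
space — so states are distinguished by their autocovariance (spectral and
cross-spectral content), not by mean level.  Inference is maximum-likelihood
EM with scaled forward-backward recursions (stable for T ~ 1e6), Viterbi
decoding with a deterministic lowest-index tie-break, and best-of-restarts
model selection.

Follows the statsmodels convention: build a :class:`TDEHMM` model from data,
call :meth:`~TDEHMM.fit`, and work with the returned :class:`TDEHMMResults`.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

from . import prep
from .prep import EmbeddedMatrix, ParcelTimeSeries

__all__ = [
    "HMMParams",
    "StatePosterior",
    "forward_backward",
    "viterbi",
    "TDEHMM",
    "TDEHMMResults",
    "concat_and_fit",
]

try:  # fast path; the numpy fallback below is exact but slower
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap


# ---------------------------------------------------------------------------
# parameters and posterior containers
# ---------------------------------------------------------------------------


@dataclass
class HMMParams:
    """K-state model parameters.

    ``covariances`` holds one Q x Q symmetric positive-definite matrix per
    state.  With ``mean_mode='zero'`` (the embedded-space convention) the
    means are pinned at zero; ``'free'`` estimates them.
    """

    initial_dist: np.ndarray
    transition_matrix: np.ndarray
    covariances: np.ndarray
    means: np.ndarray | None = None
    mean_mode: str = "zero"

    def __post_init__(self) -> None:
        self.initial_dist = np.asarray(self.initial_dist, dtype=float)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        K = self.initial_dist.size
        if self.transition_matrix.shape != (K, K):
            raise ValueError("transition_matrix shape must be (K, K)")
        if not np.allclose(self.initial_dist.sum(), 1.0, atol=1e-8):
            raise ValueError("initial_dist must sum to 1")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition rows must sum to 1 within 1e-10")
        if self.covariances.ndim != 3 or self.covariances.shape[0] != K:
            raise ValueError("covariances must be (K, Q, Q)")
        if self.means is None:
            self.means = np.zeros((K, self.covariances.shape[1]))
        self.means = np.asarray(self.means, dtype=float)

    @property
    def n_states(self) -> int:
        return self.initial_dist.size

    @property
    def n_features(self) -> int:
        return self.covariances.shape[1]

    def log_obs(self, X: np.ndarray) -> np.ndarray:
        """T x K log density of each sample under each state's Gaussian."""
        X = np.asarray(X, dtype=float)
        T, Q = X.shape
        if Q != self.n_features:
            raise ValueError(
                f"data has {Q} features, model expects {self.n_features}"
            )
        logB = np.empty((T, self.n_states))
        for k in range(self.n_states):
            try:
                L = np.linalg.cholesky(self.covariances[k])
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    f"state {k + 1} covariance is singular; increase the ridge "
                    "regularization (reg) or reduce the embedding dimension"
                ) from err
            dev = X - self.means[k]
            z = solve_triangular(L, dev.T, lower=True).T
            logdet = 2.0 * np.sum(np.log(np.diag(L)))
            logB[:, k] = -0.5 * (
                np.sum(z**2, axis=1) + logdet + Q * np.log(2 * np.pi)
            )
        return logB

    def hash(self) -> str:
        """SHA-256 over the parameter arrays (frozen-model contract checks)."""
        h = hashlib.sha256()
        for a in (self.initial_dist, self.transition_matrix, self.covariances, self.means):
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()


@dataclass
class StatePosterior:
    """Posterior state estimates for one (possibly multi-segment) dataset.

    ``gamma`` rows sum to 1; ``viterbi_path`` is 1-based; ``boundaries`` lists
    segment start offsets plus the terminal length, e.g. ``[0, T1, T1+T2]``.
    """

    gamma: np.ndarray
    xi_sum: np.ndarray
    viterbi_path: np.ndarray
    loglik: float
    boundaries: list[int] = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return self.gamma.shape[1]

    def segment(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(gamma, viterbi_path) of segment ``i``."""
        a, b = self.boundaries[i], self.boundaries[i + 1]
        return self.gamma[a:b], self.viterbi_path[a:b]


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fb_kernel(pi, A, logB):  # pragma: no cover - exercised via wrapper
    T, K = logB.shape
    gamma = np.empty((T, K))
    xi_sum = np.zeros((K, K))
    alpha = np.empty((T, K))
    c = np.empty(T)
    m = np.empty(T)
    Bs = np.empty((T, K))
    for t in range(T):
        mt = logB[t, 0]
        for k in range(1, K):
            if logB[t, k] > mt:
                mt = logB[t, k]
        m[t] = mt
        for k in range(K):
            Bs[t, k] = np.exp(logB[t, k] - mt)
    s = 0.0
    for k in range(K):
        alpha[0, k] = pi[k] * Bs[0, k]
        s += alpha[0, k]
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += alpha[t - 1, j] * A[j, k]
            alpha[t, k] = acc * Bs[t, k]
            s += alpha[t, k]
        c[t] = s
        for k in range(K):
            alpha[t, k] /= s
    beta = np.ones(K)
    for k in range(K):
        gamma[T - 1, k] = alpha[T - 1, k]
    for t in range(T - 2, -1, -1):
        nb = np.empty(K)
        for j in range(K):
            acc = 0.0
            for k in range(K):
                acc += A[j, k] * Bs[t + 1, k] * beta[k]
            nb[j] = acc / c[t + 1]
        for j in range(K):
            for k in range(K):
                xi_sum[j, k] += (
                    alpha[t, j] * A[j, k] * Bs[t + 1, k] * beta[k] / c[t + 1]
                )
        g = 0.0
        for k in range(K):
            gamma[t, k] = alpha[t, k] * nb[k]
            g += gamma[t, k]
        for k in range(K):
            gamma[t, k] /= g
        beta = nb
    ll = 0.0
    for t in range(T):
        ll += np.log(c[t]) + m[t]
    return gamma, xi_sum, ll


@njit(cache=True)
def _viterbi_kernel(logpi, logA, logB):  # pragma: no cover - via wrapper
    T, K = logB.shape
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = logpi[k] + logB[0, k]
    for t in range(1, T):
        for k in range(K):
            best = delta[t - 1, 0] + logA[0, k]
            arg = 0
            for j in range(1, K):
                v = delta[t - 1, j] + logA[j, k]
                if v > best:  # strict: ties keep the lowest index
                    best = v
                    arg = j
            delta[t, k] = best + logB[t, k]
            psi[t, k] = arg
    path = np.empty(T, dtype=np.int64)
    best = delta[T - 1, 0]
    arg = 0
    for k in range(1, K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            arg = k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def _fb_numpy(pi, A, logB):
    """Pure-numpy scaled forward-backward (reference / fallback)."""
    T, K = logB.shape
    m = logB.max(axis=1)
    Bs = np.exp(logB - m[:, None])
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * Bs[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * Bs[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    gamma = np.empty((T, K))
    xi_sum = np.zeros((K, K))
    beta = np.ones(K)
    gamma[T - 1] = alpha[T - 1]
    for t in range(T - 2, -1, -1):
        w = Bs[t + 1] * beta
        xi_sum += np.outer(alpha[t], w) * A / c[t + 1]
        beta = (A @ w) / c[t + 1]
        g = alpha[t] * beta
        gamma[t] = g / g.sum()
    return gamma, xi_sum, float(np.log(c).sum() + m.sum())


def _viterbi_numpy(logpi, logA, logB):
    T, K = logB.shape
    delta = logpi + logB[0]
    psi = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + logA
        psi[t] = np.argmax(scores, axis=0)  # argmax -> first max -> lowest index
        delta = scores[psi[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=int)
    path[T - 1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def _segments(T: int, boundaries) -> list[tuple[int, int]]:
    if boundaries is None:
        boundaries = [0, T]
    boundaries = list(boundaries)
    if boundaries[0] != 0 or boundaries[-1] != T or sorted(boundaries) != boundaries:
        raise ValueError("boundaries must be sorted, start at 0 and end at T")
    return list(zip(boundaries[:-1], boundaries[1:]))


def forward_backward(
    params: HMMParams, X: np.ndarray, boundaries=None
) -> StatePosterior:
    """Exact posterior marginals, expected transition counts and Viterbi path.

    Runs the scaled recursions independently within each segment (transitions
    never bridge segment boundaries), summing log-likelihoods and transition
    counts across segments.
    """
    X = np.asarray(X, dtype=float)
    logB = params.log_obs(X)
    T, K = logB.shape
    segs = _segments(T, boundaries)
    gamma = np.empty((T, K))
    xi_sum = np.zeros((K, K))
    ll = 0.0
    vpath = np.empty(T, dtype=int)
    logpi = np.log(np.maximum(params.initial_dist, 1e-300))
    logA = np.log(np.maximum(params.transition_matrix, 1e-300))
    fb = _fb_kernel if _HAVE_NUMBA else _fb_numpy
    vit = _viterbi_kernel if _HAVE_NUMBA else _viterbi_numpy
    for a, b in segs:
        g, x, l = fb(params.initial_dist, params.transition_matrix, logB[a:b])
        gamma[a:b] = g
        xi_sum += x
        ll += l
        vpath[a:b] = vit(logpi, logA, logB[a:b])
    return StatePosterior(
        gamma=gamma,
        xi_sum=xi_sum,
        viterbi_path=vpath + 1,
        loglik=float(ll),
        boundaries=[s for s, _ in segs] + [T],
    )


def viterbi(params: HMMParams, X: np.ndarray, boundaries=None) -> np.ndarray:
    """Most probable state path (1-based); ties break toward the lower index."""
    X = np.asarray(X, dtype=float)
    logB = params.log_obs(X)
    T = logB.shape[0]
    logpi = np.log(np.maximum(params.initial_dist, 1e-300))
    logA = np.log(np.maximum(params.transition_matrix, 1e-300))
    vit = _viterbi_kernel if _HAVE_NUMBA else _viterbi_numpy
    path = np.empty(T, dtype=int)
    for a, b in _segments(T, boundaries):
        path[a:b] = vit(logpi, logA, logB[a:b])
    return path + 1


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class EmptyStateWarning(UserWarning):
    pass


@dataclass
class _PrepState:
    """Frozen preprocessing needed to project new data into model space."""

    band: tuple[float, float] | None
    target_fs: float | None
    fs: float
    lag_set: np.ndarray
    template: EmbeddedMatrix  # carries pca mean/basis
    parcel_scales: dict[str, np.ndarray]
    parcel_labels: list[str]
    orthogonalize: bool


class TDEHMM:
    """Hidden Markov model over (time-delay-embedded) multichannel data.

    Parameters
    ----------
    endog : ndarray, shape (T, Q)
        Observation matrix (typically embedded-PCA scores), already
        concatenated over subjects.
    n_states : int
        Number of hidden states K (10 in the resting-state analysis this
        package reproduces; any K >= 1 is accepted).
    boundaries : list of int, optional
        Subject/segment start offsets plus terminal T; transitions are never
        estimated across a boundary.
    subject_ids : list of str, optional
        One id per segment, used to key per-subject posteriors and metrics.
    mean_mode : {'zero', 'free'}
        'zero' pins state means at the origin (the embedded-space convention:
        states are autocovariance patterns, not offsets).
    """

    def __init__(
        self,
        endog: np.ndarray,
        n_states: int,
        boundaries=None,
        subject_ids=None,
        mean_mode: str = "zero",
        fs: float | None = None,
    ):
        self.endog = np.asarray(endog, dtype=float)
        if self.endog.ndim != 2:
            raise ValueError("endog must be 2-D")
        if n_states < 1:
            raise ValueError("n_states must be >= 1")
        if mean_mode not in ("zero", "free"):
            raise ValueError("mean_mode must be 'zero' or 'free'")
        T = self.endog.shape[0]
        self.boundaries = list(boundaries) if boundaries is not None else [0, T]
        _segments(T, self.boundaries)  # validate
        n_seg = len(self.boundaries) - 1
        if subject_ids is None:
            subject_ids = [f"s{i:02d}" for i in range(n_seg)]
        if len(subject_ids) != n_seg:
            raise ValueError("one subject id per segment required")
        self.subject_ids = list(subject_ids)
        self.n_states = n_states
        self.mean_mode = mean_mode
        self.fs = fs
        self.prep_state: _PrepState | None = None

    # -- construction from parcel time series --------------------------------

    @classmethod
    def from_parcels(
        cls,
        ts_list: list[ParcelTimeSeries],
        n_states: int = 10,
        band: tuple[float, float] | None = (1.0, 40.0),
        target_fs: float | None = None,
        orthogonalize: bool = True,
        lag_set: np.ndarray | None = None,
        n_components: int | None = None,
        mean_mode: str = "zero",
    ) -> "TDEHMM":
        """Run the conditioning chain and build the model.

        Per subject: band-pass, optional resampling, symmetric
        orthogonalization, per-channel z-scoring (each subject scaled by its
        own statistics so between-subject amplitude differences do not
        dominate the shared covariance model), time-delay embedding; then PCA
        on the concatenation.  ``n_components`` defaults to twice the parcel
        count.
        """
        if not ts_list:
            raise ValueError("need at least one recording")
        labels = ts_list[0].parcel_labels
        for ts in ts_list[1:]:
            if ts.parcel_labels != labels:
                raise ValueError("parcel labels must match across subjects")
        if lag_set is None:
            lag_set = prep.default_lag_set()
        if n_components is None:
            n_components = 2 * len(labels)
        blocks, scales, ids = [], {}, []
        fs = None
        for ts in ts_list:
            if band is not None:
                ts = prep.bandpass(ts, *band)
            if target_fs is not None:
                ts = prep.downsample(ts, target_fs)
            if orthogonalize:
                ts = prep.symmetric_orthogonalize(ts)
            ts, sc = prep.zscore_parcels(ts)
            scales[ts.subject_id] = sc
            emb = prep.time_delay_embed(ts, lag_set)
            blocks.append(emb)
            ids.append(ts.subject_id)
            fs = ts.fs
        X = np.concatenate([b.data for b in blocks], axis=0)
        stacked = EmbeddedMatrix(
            data=X, lag_set=np.asarray(lag_set), offset=blocks[0].offset,
            parcel_labels=list(labels),
        )
        reduced = prep.pca_reduce(stacked, n_components)
        bnd = np.concatenate([[0], np.cumsum([b.n_samples for b in blocks])])
        model = cls(
            reduced.data,
            n_states,
            boundaries=list(map(int, bnd)),
            subject_ids=ids,
            mean_mode=mean_mode,
            fs=fs,
        )
        model.prep_state = _PrepState(
            band=band,
            target_fs=target_fs,
            fs=fs,
            lag_set=np.asarray(lag_set),
            template=reduced,
            parcel_scales=scales,
            parcel_labels=list(labels),
            orthogonalize=orthogonalize,
        )
        return model

    # -- EM ------------------------------------------------------------------

    def _m_step(self, gamma, xi_sum, reg_scale):
        X = self.endog
        K = gamma.shape[1]
        starts = self.boundaries[:-1]
        pi = gamma[starts].sum(axis=0)
        pi = pi / pi.sum()
        A = xi_sum / np.maximum(xi_sum.sum(axis=1, keepdims=True), 1e-300)
        Q = X.shape[1]
        covs = np.empty((K, Q, Q))
        means = np.zeros((K, Q))
        Ng = gamma.sum(axis=0)
        for k in range(K):
            w = gamma[:, k]
            if self.mean_mode == "free":
                means[k] = (w @ X) / max(Ng[k], 1e-12)
            dev = X - means[k]
            S = (dev * w[:, None]).T @ dev / max(Ng[k], 1e-12)
            reg = reg_scale * np.mean(np.diag(S))
            covs[k] = S + reg * np.eye(Q)
        return HMMParams(pi, A, covs, means=means, mean_mode=self.mean_mode), Ng

    def _init_gamma(self, rng, K, mean_block: int = 200, soft: float = 0.1):
        """Random block-wise responsibilities.

        Contiguous blocks of geometric length (mean ``mean_block`` samples)
        are soft-assigned to random states.  Blocky initial responsibilities
        give the initial M-step distinct state covariances; fully independent
        per-timepoint draws would average every state's covariance to the
        global one, a symmetric saddle EM escapes only slowly.
        """
        T = self.endog.shape[0]
        gamma = np.full((T, K), soft / max(K - 1, 1)) if K > 1 else np.ones((T, 1))
        t = 0
        while t < T:
            ln = int(rng.geometric(1.0 / mean_block))
            gamma[t : t + ln, int(rng.integers(K))] = 1.0 - soft
            t += ln
        return gamma / gamma.sum(axis=1, keepdims=True)

    def _soft_xi(self, gamma):
        K = gamma.shape[1]
        xi = np.zeros((K, K))
        for a, b in _segments(self.endog.shape[0], self.boundaries):
            xi += gamma[a : b - 1].T @ gamma[a + 1 : b]
        return xi

    def fit(
        self,
        max_iter: int = 100,
        tol: float = 1e-6,
        reg: float = 1e-6,
        seed: int = 0,
        n_restarts: int = 5,
        verbose: bool = False,
    ) -> "TDEHMMResults":
        """Fit by EM, best of ``n_restarts`` random initializations.

        Each restart draws random per-timepoint responsibilities (seeded) and
        alternates exact E-steps with closed-form M-steps.  The per-iteration
        log-likelihood is checked to be non-decreasing (within numerical
        tolerance); iteration stops when the relative improvement falls below
        ``tol``.  ``reg`` is a ridge added to each state covariance as a
        fraction of its mean diagonal (embedded dimensions are highly
        collinear).  A state whose occupancy collapses is reinitialized from a
        random data segment once, then dropped to K-1 with a warning.
        """
        ss = np.random.SeedSequence(seed)
        best = None
        restart_lls = []
        for r, child in enumerate(ss.spawn(max(n_restarts, 1))):
            rng = np.random.default_rng(child)
            out = self._fit_once(rng, max_iter, tol, reg, verbose)
            restart_lls.append(out[2][-1])
            if best is None or out[2][-1] > best[2][-1]:
                best = out
        params, post, trace, converged = best
        return TDEHMMResults(
            model=self,
            params=params,
            posterior=post,
            loglik_trace=np.asarray(trace),
            restart_logliks=np.asarray(restart_lls),
            converged=converged,
        )

    def _fit_once(self, rng, max_iter, tol, reg, verbose):
        K = self.n_states
        T, Q = self.endog.shape
        gamma = self._init_gamma(rng, K)
        params, _ = self._m_step(gamma, self._soft_xi(gamma), reg)
        trace = []
        post = None
        reinit_done = np.zeros(K, dtype=bool)
        converged = False
        it = 0
        while it < max_iter:
            post = forward_backward(params, self.endog, self.boundaries)
            ll = post.loglik
            if trace and ll < trace[-1] - 1e-6 * (1.0 + abs(trace[-1])):
                raise RuntimeError(
                    f"EM log-likelihood decreased: {trace[-1]} -> {ll}"
                )
            stop = bool(trace) and (ll - trace[-1]) < tol * abs(trace[-1])
            trace.append(ll)
            if verbose:
                print(f"  iter {it:3d}  loglik {ll:.4f}")
            # empty-state handling before the M-step
            Ng = post.gamma.sum(axis=0)
            dead = np.where(Ng < Q + 1)[0]
            if dead.size and K > 1:
                k = int(dead[0])
                if not reinit_done[k]:
                    reinit_done[k] = True
                    seg_len = min(max(4 * Q, 100), T)
                    s = int(rng.integers(0, T - seg_len + 1))
                    chunk = self.endog[s : s + seg_len]
                    S = chunk.T @ chunk / seg_len
                    params.covariances[k] = S + reg * np.mean(np.diag(S)) * np.eye(Q)
                    it += 1
                    continue
                warnings.warn(
                    f"state {k + 1} lost all occupancy twice; dropping to "
                    f"{K - 1} states",
                    EmptyStateWarning,
                )
                keep = [j for j in range(K) if j != k]
                gamma = post.gamma[:, keep]
                gamma = gamma / gamma.sum(axis=1, keepdims=True)
                K -= 1
                reinit_done = np.delete(reinit_done, k)
                params, _ = self._m_step(gamma, self._soft_xi(gamma), reg)
                trace = []
                it += 1
                continue
            if stop:
                converged = True
                break
            params, _ = self._m_step(post.gamma, post.xi_sum, reg)
            it += 1
        if post is None or len(trace) == 0 or trace[-1] != post.loglik:
            post = forward_backward(params, self.endog, self.boundaries)
            if not trace or post.loglik >= trace[-1] - 1e-9:
                trace.append(post.loglik)
        return params, post, trace, converged


def concat_and_fit(
    subject_data: list[np.ndarray | EmbeddedMatrix],
    n_states: int,
    subject_ids=None,
    mean_mode: str = "zero",
    fs: float | None = None,
    **fit_kwargs,
) -> "TDEHMMResults":
    """Temporally concatenate subjects, fit one shared model, and return the
    group result (per-subject posteriors via ``results.subject_posterior``).

    Transitions never bridge subject boundaries.  All subjects must share the
    same dimensionality (and parcel labels, when :class:`EmbeddedMatrix`
    inputs carry them).
    """
    arrays, labels = [], None
    for d in subject_data:
        if isinstance(d, EmbeddedMatrix):
            if labels is None:
                labels = d.parcel_labels
            elif d.parcel_labels != labels:
                raise ValueError("parcel labels must match across subjects")
            arrays.append(d.data)
        else:
            arrays.append(np.asarray(d, dtype=float))
    Q = arrays[0].shape[1]
    for a in arrays:
        if a.shape[1] != Q:
            raise ValueError("inconsistent dimensionality across subjects")
    X = np.concatenate(arrays, axis=0)
    bnd = np.concatenate([[0], np.cumsum([a.shape[0] for a in arrays])])
    model = TDEHMM(
        X,
        n_states,
        boundaries=list(map(int, bnd)),
        subject_ids=subject_ids,
        mean_mode=mean_mode,
        fs=fs,
    )
    return model.fit(**fit_kwargs)


class TDEHMMResults:
    """Fitted TDE-HMM: parameters, posteriors, diagnostics and derived metrics."""

    def __init__(self, model, params, posterior, loglik_trace, restart_logliks, converged):
        self.model = model
        self.params = params
        self.posterior = posterior
        self.loglik_trace = loglik_trace
        self.restart_logliks = restart_logliks
        self.converged = converged

    @property
    def loglik(self) -> float:
        return self.posterior.loglik

    @property
    def n_states(self) -> int:
        return self.params.n_states

    def subject_posterior(self, subject_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(gamma, viterbi_path) for one subject's segment."""
        i = self.model.subject_ids.index(subject_id)
        return self.posterior.segment(i)

    def params_hash(self) -> str:
        return self.params.hash()

    # -- metrics -------------------------------------------------------------

    def temporal_metrics(self, fs: float | None = None, edge_visits: str = "exclude",
                         fo_source: str = "viterbi"):
        """Per subject x state life-time, interval time and fractional occupancy.

        See :func:`dynstates.characterize.temporal_metrics` for definitions.
        """
        from .characterize import subject_metrics

        fs = fs or self.model.fs
        if fs is None:
            raise ValueError("sampling rate unknown; pass fs")
        return subject_metrics(
            self.posterior, fs, self.model.subject_ids,
            n_states=self.n_states, edge_visits=edge_visits, fo_source=fo_source,
        )

    # -- frozen-model decoding ----------------------------------------------

    def decode(self, X: np.ndarray, boundaries=None) -> StatePosterior:
        """Posterior inference on new data with frozen parameters."""
        return forward_backward(self.params, X, boundaries)

    def project_parcels(self, ts: ParcelTimeSeries) -> np.ndarray:
        """Condition + embed + project a new recording into model space using
        the stored filters, normalization and PCA basis (no refitting)."""
        st = self.model.prep_state
        if st is None:
            raise ValueError("model was not built from parcel time series")
        if ts.parcel_labels != st.parcel_labels:
            raise ValueError("parcel labels do not match the fitted model")
        if st.band is not None:
            ts = prep.bandpass(ts, *st.band)
        if st.target_fs is not None and ts.fs != st.target_fs:
            ts = prep.downsample(ts, st.target_fs)
        if st.orthogonalize:
            ts = prep.symmetric_orthogonalize(ts)
        scale = st.parcel_scales.get(ts.subject_id)
        ts, _ = prep.zscore_parcels(ts, scale)
        emb = prep.time_delay_embed(ts, st.lag_set)
        return prep.project_embedded(emb, st.template)

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        p = self.params
        fo = self.posterior.gamma.mean(axis=0)
        lines = [
            "Time-delay-embedded HMM results",
            "=" * 47,
            f"states:              {p.n_states}",
            f"feature dim:         {p.n_features}",
            f"observations:        {self.model.endog.shape[0]}",
            f"segments:            {len(self.model.boundaries) - 1}",
            f"log-likelihood:      {self.loglik:.2f}",
            f"EM iterations:       {len(self.loglik_trace)}",
            f"converged:           {self.converged}",
            f"restarts (loglik):   "
            + ", ".join(f"{v:.1f}" for v in self.restart_logliks),
            "-" * 47,
            "state   FO      a_kk",
        ]
        for k in range(p.n_states):
            lines.append(
                f"{k + 1:>5}   {fo[k]:.3f}   {p.transition_matrix[k, k]:.3f}"
            )
        return "\n".join(lines)
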