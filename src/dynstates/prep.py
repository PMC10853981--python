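"""Signal conditioning: from parcel time courses to the embedded matrix the HMM sees.

The conditioning chain is deterministic: band-pass filter (zero-phase), resample,
symmetric orthogonalization (source-leakage correction), per-channel z-scoring,
time-delay embedding, and PCA reduction.  The fitted scaling and PCA basis are
stored so that held-out (task) data can be projected into the identical space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import PCA

__all__ = [
    "ParcelTimeSeries",
    "EmbeddedMatrix",
    "bandpass",
    "downsample",
    "symmetric_orthogonalize",
    "time_delay_embed",
    "pca_reduce",
    "default_lag_set",
]


def default_lag_set(n_lags: int = 15) -> np.ndarray:
    """Symmetric lag set of ``n_lags`` odd count, e.g. 15 lags -> -7..+7 samples.

    At 250 Hz the default spans 30 ms in each direction, so each embedded row
    carries the local autocovariance structure of a ~60 ms window.
    """
    if n_lags < 1 or n_lags % 2 == 0:
        raise ValueError("n_lags must be a positive odd integer")
    h = n_lags // 2
    return np.arange(-h, h + 1)


@dataclass
class ParcelTimeSeries:
    """A time x parcels source-space recording.

    Parameters
    ----------
    data : ndarray, shape (T, P)
        Parcel time courses, arbitrary source units.
    fs : float
        Sampling rate in Hz.
    parcel_labels : list of str, optional
        One label per parcel; defaults to ``p00..``.
    subject_id : str
    session : str
        One of ``rest-week3 | rest-week12 | control | task`` (free-form allowed).
    group : str
        One of ``stroke-L | stroke-R | control`` (free-form allowed).
    """

    data: np.ndarray
    fs: float
    parcel_labels: list[str] | None = None
    subject_id: str = "s00"
    session: str = "rest-week3"
    group: str = "control"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (time x parcels)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.parcel_labels is None:
            self.parcel_labels = [f"p{i:02d}" for i in range(self.n_parcels)]
        if len(self.parcel_labels) != self.n_parcels:
            raise ValueError("parcel_labels length does not match parcel count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "ParcelTimeSeries":
        return replace(self, data=data, fs=self.fs if fs is None else fs)


@dataclass
class EmbeddedMatrix:
    """Time-delay-embedded (optionally PCA-reduced) data.

    ``data`` has ``T' = T - (span of lag_set)`` rows.  Column order before PCA is
    parcel-major, lag-minor: column ``p * L + l`` holds parcel ``p`` at lag
    ``lag_set[l]``.  ``offset`` is the number of samples cropped from the start
    of the original recording, for aligning posteriors back to raw samples.
    """

    data: np.ndarray
    lag_set: np.ndarray
    offset: int
    pca_mean: np.ndarray | None = None
    pca_basis: np.ndarray | None = None  # (P*L, Q), orthonormal columns
    variance_retained: float = 1.0
    per_parcel_scale: np.ndarray | None = None  # (2, P): mean, sd used to z-score
    parcel_labels: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


def bandpass(ts: ParcelTimeSeries, lo: float, hi: float, order: int = 4) -> ParcelTimeSeries:
    """Zero-phase Butterworth band-pass filter.

    Forward-backward (``sosfiltfilt``) application doubles the effective order
    and cancels group delay, so filtered and raw samples stay aligned.
    """
    nyq = ts.fs / 2.0
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    if hi >= nyq:
        raise ValueError(f"hi={hi} Hz must be below the Nyquist frequency {nyq} Hz")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=ts.fs, output="sos")
    out = sps.sosfiltfilt(sos, ts.data, axis=0)
    return ts.with_data(out)


def downsample(ts: ParcelTimeSeries, target_fs: float) -> ParcelTimeSeries:
    """Resample to ``target_fs`` with anti-alias filtering.

    Polyphase FIR resampling (zero-phase, Kaiser-windowed anti-alias filter)
    for any rational rate ratio; non-integer ratios are resampled, never
    truncated.  Duration is preserved to within one output sample.
    """
    if target_fs > ts.fs:
        raise ValueError("target_fs must not exceed the current rate")
    if target_fs == ts.fs:
        return ts
    from fractions import Fraction

    frac = Fraction(target_fs / ts.fs).limit_denominator(1000)
    out = sps.resample_poly(
        ts.data, frac.numerator, frac.denominator, axis=0, window=("kaiser", 12.0)
    )
    return ts.with_data(out, fs=target_fs)


def symmetric_orthogonalize(
    ts: ParcelTimeSeries, max_iter: int = 500, tol: float = 1e-12
) -> ParcelTimeSeries:
    """Leakage correction: closest set of mutually orthogonal time courses.

    Finds the matrix ``Z`` with mutually orthogonal columns (zero inner
    products) minimizing ``||X - Z||_F``, by alternating an orthogonal
    Procrustes projection with per-column rescaling.  The objective is
    non-increasing; iteration stops when it improves by less than ``tol``
    (relative to the input energy).

    Raises on rank-deficient input (naming the most collinear column pair) and
    on non-convergence (reporting the final objective).
    """
    X = ts.data
    T, P = X.shape
    if T < P:
        raise ValueError("need at least as many samples as parcels")
    s = np.linalg.svd(X, compute_uv=False)
    if s[-1] < 1e-10 * s[0]:
        C = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(C, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(C)), C.shape)
        raise ValueError(
            "rank-deficient input: columns "
            f"{ts.parcel_labels[i]!r} and {ts.parcel_labels[j]!r} are collinear "
            f"(|r|={abs(C[i, j]):.6f})"
        )
    scale = float(np.sum(X**2))
    d = np.ones(P)
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        U, _, Vt = np.linalg.svd(X * d, full_matrices=False)
        O = U @ Vt  # orthonormal columns closest to X*diag(d)
        d = np.einsum("ij,ij->j", X, O)
        Z = O * d
        obj = float(np.sum((X - Z) ** 2))
        if obj > prev + 1e-9 * scale:  # pragma: no cover - safety net
            raise RuntimeError("orthogonalization objective increased")
        if prev - obj < tol * scale:
            converged = True
            break
        prev = obj
    if not converged:
        raise RuntimeError(
            f"symmetric orthogonalization did not converge in {max_iter} "
            f"iterations (final objective {obj:.6g})"
        )
    return ts.with_data(Z)


def time_delay_embed(ts: ParcelTimeSeries, lag_set: np.ndarray | None = None) -> EmbeddedMatrix:
    """Embed each parcel with its lagged copies.

    Row ``t`` of the output holds, for each parcel, its values at ``t + lag``
    for every lag in ``lag_set`` (parcel-major, lag-minor column order).  Rows
    whose lags fall outside the recording are dropped, ``max(lag)`` at the end
    and ``-min(lag)`` at the start; ``offset`` records the start crop.
    """
    if lag_set is None:
        lag_set = default_lag_set()
    lag_set = np.asarray(lag_set, dtype=int)
    X = ts.data
    T, P = X.shape
    lo, hi = int(lag_set.min()), int(lag_set.max())
    span = hi - lo
    if span >= T:
        raise ValueError("lag span must be smaller than the number of samples")
    T2 = T - span
    offset = -lo if lo < 0 else 0
    start = max(0, -lo)
    cols = []
    for p in range(P):
        for lag in lag_set:
            cols.append(X[start + lag : start + lag + T2, p])
    data = np.column_stack(cols)
    return EmbeddedMatrix(
        data=data, lag_set=lag_set, offset=start, parcel_labels=list(ts.parcel_labels)
    )


def pca_reduce(
    emb: EmbeddedMatrix, n_components: int, standardize: bool = False
) -> EmbeddedMatrix:
    """Project the embedded matrix onto its leading principal components.

    The mean and orthonormal basis are stored on the returned object so that
    new (task) data can be projected into the identical space.  When
    ``standardize`` the embedded columns are scaled to unit variance first.
    """
    X = emb.data
    T2, D = X.shape
    if not (1 <= n_components <= min(T2, D)):
        raise ValueError(f"n_components must be in [1, {min(T2, D)}]")
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    basis = pca.components_.T
    var = float(np.sum(pca.explained_variance_ratio_))
    if standardize:
        # fold the standardization into the stored projection
        basis = basis / sd[:, None]
        mean = emb.data.mean(axis=0)
    else:
        mean = pca.mean_
    return EmbeddedMatrix(
        data=scores,
        lag_set=emb.lag_set,
        offset=emb.offset,
        pca_mean=mean,
        pca_basis=basis,
        variance_retained=var,
        per_parcel_scale=emb.per_parcel_scale,
        parcel_labels=emb.parcel_labels,
    )


def project_embedded(emb_new: EmbeddedMatrix, fitted: EmbeddedMatrix) -> np.ndarray:
    """Project new embedded data into a previously fitted PCA space."""
    if fitted.pca_basis is None:
        raise ValueError("fitted EmbeddedMatrix carries no PCA basis")
    if emb_new.data.shape[1] != fitted.pca_basis.shape[0]:
        raise ValueError(
            f"dimensionality mismatch: data has {emb_new.data.shape[1]} columns, "
            f"stored basis expects {fitted.pca_basis.shape[0]}"
        )
    return (emb_new.data - fitted.pca_mean) @ fitted.pca_basis


def zscore_parcels(
    ts: ParcelTimeSeries, scale: np.ndarray | None = None
) -> tuple[ParcelTimeSeries, np.ndarray]:
    """Per-channel z-scoring; returns the (mean, sd) used so task data can reuse it."""
    if scale is None:
        mu = ts.data.mean(axis=0)
        sd = ts.data.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        scale = np.vstack([mu, sd])
    else:
        mu, sd = scale
    return ts.with_data((ts.data - mu) / sd), scale
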