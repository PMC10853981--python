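"""Synthetic cohorts with known ground truth.

Real source-space MEG for this problem is not publicly deposited, so every
downstream stage is exercised on Markov-switching multichannel signals whose
generating dynamics are known exactly: a hidden chain with chosen transition
matrix switches the oscillatory content of the parcels (e.g. a 10 Hz
sensorimotor-like state, a 4 Hz default-mode-like state), on top of broadband
Gaussian noise.  Clinical score tables with a planted rank correlation between
a network metric and week-3 arm function complete the cohort.

All randomness flows from one integer seed through documented sub-streams
(`numpy.random.SeedSequence.spawn`), so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .prep import ParcelTimeSeries

__all__ = [
    "GroundTruth",
    "StatePath",
    "simulate_markov_chain",
    "synthesize_parcel_signals",
    "generate_clinical_scores",
    "load_stroke_cohort",
    "default_truth",
    "stationary_distribution",
]


def _validate_stochastic(A: np.ndarray, name: str) -> None:
    if np.any(A < 0) or np.any(A > 1):
        raise ValueError(f"{name} entries must be probabilities in [0, 1]")
    if not np.allclose(A.sum(axis=-1), 1.0, atol=1e-12):
        raise ValueError(f"{name} rows must sum to 1 within 1e-12")


@dataclass
class GroundTruth:
    """Generative description of a Markov-switching parcel recording.

    ``state_amplitudes[k]`` gives the per-parcel amplitude of state k's
    oscillation (arbitrary units) and ``state_freqs[k]`` its frequency in Hz.
    """

    transition_matrix: np.ndarray  # (K, K)
    initial_dist: np.ndarray  # (K,)
    state_amplitudes: np.ndarray  # (K, P)
    state_freqs: np.ndarray  # (K,)
    noise_sd: float = 1.0
    fs: float = 250.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.initial_dist = np.asarray(self.initial_dist, dtype=float)
        self.state_amplitudes = np.atleast_2d(np.asarray(self.state_amplitudes, dtype=float))
        self.state_freqs = np.atleast_1d(np.asarray(self.state_freqs, dtype=float))
        K = self.transition_matrix.shape[0]
        if self.transition_matrix.shape != (K, K):
            raise ValueError("transition_matrix must be square")
        _validate_stochastic(self.transition_matrix, "transition_matrix")
        _validate_stochastic(self.initial_dist[None, :], "initial_dist")
        if self.initial_dist.shape != (K,):
            raise ValueError("initial_dist length must match K")
        if self.state_amplitudes.shape[0] != K or self.state_freqs.shape[0] != K:
            raise ValueError("per-state signatures must have one row per state")
        if np.any(self.state_freqs <= 0) or np.any(self.state_freqs >= self.fs / 2):
            raise ValueError("state frequencies must lie in (0, fs/2)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.state_amplitudes.shape[1]


@dataclass
class StatePath:
    """A realized hidden-state sequence; states are 1-based."""

    states: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        if self.states.size < 1:
            raise ValueError("path must contain at least one sample")
        if self.states.min() < 1:
            raise ValueError("states are 1-based")

    @property
    def n_samples(self) -> int:
        return self.states.size


def stationary_distribution(A: np.ndarray) -> np.ndarray:
    """Leading left eigenvector of a stochastic matrix, normalized to sum 1."""
    w, v = np.linalg.eig(np.asarray(A, dtype=float).T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    return pi / pi.sum()


def simulate_markov_chain(truth: GroundTruth, n_samples: int, seed: int | None = None) -> StatePath:
    """Draw a hidden-state path from the ground-truth chain.

    Marginal state frequencies converge to the stationary distribution of the
    transition matrix as the path grows; per-state dwell times are geometric
    with mean ``1 / (1 - a_kk)`` samples.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    K = truth.n_states
    A = truth.transition_matrix
    cumA = np.cumsum(A, axis=1)
    states = np.empty(n_samples, dtype=int)
    states[0] = rng.choice(K, p=truth.initial_dist)
    u = rng.random(n_samples)
    for t in range(1, n_samples):
        states[t] = np.searchsorted(cumA[states[t - 1]], u[t], side="right")
    return StatePath(states=states + 1, fs=truth.fs)


def synthesize_parcel_signals(
    path: StatePath, truth: GroundTruth, seed: int | None = None
) -> ParcelTimeSeries:
    """Render parcel signals for a given hidden path.

    During samples of state k, the parcels weighted by ``state_amplitudes[k]``
    carry a sinusoid at ``state_freqs[k]`` (continuous phase per state, random
    initial phase), plus white Gaussian noise of ``noise_sd`` on every parcel.
    Amplitude-modulated sinusoids keep the state-conditioned spectra
    analytically known, which is what makes spectral-recovery tests exact.
    """
    if path.fs != truth.fs:
        raise ValueError("path and truth sampling rates differ")
    if truth.state_amplitudes.shape[1] != truth.n_parcels:
        raise ValueError("amplitude vector length mismatch")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    T = path.n_samples
    t = np.arange(T) / truth.fs
    X = rng.normal(0.0, truth.noise_sd, size=(T, truth.n_parcels))
    for k in range(truth.n_states):
        phase = rng.uniform(0, 2 * np.pi)
        osc = np.sin(2 * np.pi * truth.state_freqs[k] * t + phase)
        gate = (path.states == k + 1).astype(float)
        X += (gate * osc)[:, None] * truth.state_amplitudes[k][None, :]
    return ParcelTimeSeries(data=X, fs=truth.fs, session="rest-week3")


def default_truth(
    n_parcels: int = 8,
    stickiness: float = 0.95,
    noise_sd: float = 0.5,
    fs: float = 250.0,
    seed: int = 0,
) -> GroundTruth:
    """Two-state default cohort: a 10 Hz sensorimotor-like state on the first
    parcels and a 4 Hz default-mode-like state on the last parcels.

    The 0.95 self-transition probability gives geometric dwell times with mean
    20 samples (80 ms at 250 Hz), in the range reported for fast resting-state
    network dynamics.
    """
    if n_parcels < 4:
        raise ValueError("need at least 4 parcels for disjoint signatures")
    amp = np.zeros((2, n_parcels))
    half = n_parcels // 2
    amp[0, :half] = 1.0  # "SMN": alpha/mu-band
    amp[1, half:] = 1.0  # "DMN": theta-band
    A = np.full((2, 2), 1 - stickiness)
    np.fill_diagonal(A, stickiness)
    return GroundTruth(
        transition_matrix=A,
        initial_dist=np.array([0.5, 0.5]),
        state_amplitudes=amp,
        state_freqs=np.array([10.0, 4.0]),
        noise_sd=noise_sd,
        fs=fs,
        seed=seed,
    )


def generate_clinical_scores(
    n_patients: int,
    metric_values: np.ndarray,
    rho_target: float,
    seed: int = 0,
    missing_week12_frac: float = 8 / 37,
) -> pd.DataFrame:
    """Synthesize a clinical score table with a planted rank correlation.

    The week-3 arm-function score (ARAT, 0-57 integers) is generated so that
    its Spearman correlation with ``metric_values`` approaches ``rho_target``
    as n grows (Gaussian copula with the Pearson parameter inverted from the
    Spearman target); FM-UE (0-66) tracks ARAT with noise; week-12 scores show
    improvement, with a fraction missing (absent, never 0 — 0 is a valid ARAT
    score).  Ages, sex, affected side, onset timing, NIHSS and mRS are drawn
    from ranges typical of a subacute subcortical-stroke cohort.
    """
    if n_patients < 3:
        raise ValueError("need at least 3 patients")
    if abs(rho_target) > 1:
        raise ValueError("rho_target must lie in [-1, 1]")
    metric_values = np.asarray(metric_values, dtype=float)
    if metric_values.shape != (n_patients,):
        raise ValueError("metric_values must have one value per patient")
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]

    r = stats.rankdata(metric_values)
    z = stats.norm.ppf(r / (n_patients + 1))
    if abs(rho_target) == 1.0:
        latent = np.sign(rho_target) * z
    else:
        rho_pearson = 2 * np.sin(np.pi * rho_target / 6)  # invert the copula map
        latent = rho_pearson * z + np.sqrt(1 - rho_pearson**2) * rngs[0].standard_normal(
            n_patients
        )
    lr = stats.rankdata(latent, method="ordinal")
    arat_w3 = np.round((lr - 1) / max(n_patients - 1, 1) * 57).astype(int)
    fm_latent = latent + 0.5 * rngs[1].standard_normal(n_patients)
    fr = stats.rankdata(fm_latent, method="ordinal")
    fmue_w3 = np.round((fr - 1) / max(n_patients - 1, 1) * 66).astype(int)

    gain_a = rngs[1].integers(0, 25, n_patients)
    gain_f = rngs[1].integers(0, 28, n_patients)
    arat_w12 = np.minimum(arat_w3 + gain_a, 57)
    fmue_w12 = np.minimum(fmue_w3 + gain_f, 66)

    df = pd.DataFrame(
        {
            "id": np.arange(1, n_patients + 1),
            "age": rngs[2].integers(30, 78, n_patients),
            "sex": rngs[2].choice(["M", "F"], n_patients, p=[0.65, 0.35]),
            "affected_hand": rngs[2].choice(["L", "R"], n_patients),
            "days_post_stroke": rngs[2].integers(14, 29, n_patients),
            "nihss_day0": rngs[2].integers(1, 16, n_patients),
            "mrs": rngs[2].integers(1, 6, n_patients),
            "arat_w3": arat_w3,
            "fmue_w3": fmue_w3,
            "arat_w12": arat_w12.astype(float),
            "fmue_w12": fmue_w12.astype(float),
            "second_meg": 0,
        }
    )
    n_missing = int(round(missing_week12_frac * n_patients))
    if n_missing:
        drop = rngs[3].choice(n_patients, size=n_missing, replace=False)
        df.loc[drop, ["arat_w12", "fmue_w12"]] = np.nan
    return df


def load_stroke_cohort() -> pd.DataFrame:
    """The bundled 37-patient subacute-stroke clinical table.

    Per-patient age, sex, affected hand, days post-stroke, day-0 NIHSS, mRS,
    week-3 and week-12 ARAT / FM-UE, and a flag for patients with a second
    resting recording at week 12.  Missing week-12 scores are NaN (absent),
    never 0.
    """
    with resources.files("dynstates.data").joinpath("stroke_cohort.csv").open() as fh:
        df = pd.read_csv(fh)
    for c in ("arat_w12", "fmue_w12"):
        df[c] = df[c].astype(float)
    df["second_meg"] = df["second_meg"].astype(bool)
    return df
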