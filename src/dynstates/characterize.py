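"""State descriptions: temporal metrics, state-conditioned spectra, network labels.

Temporal metrics follow the standard dynamic-network definitions: the
life-time (dwell-time) of a state is the average time elapsed between entering
and exiting it, the interval time is the average time between consecutive
visits to it, and the fractional occupancy (FO) is the proportion of samples
assigned to it.  Metrics are computed from the hard (Viterbi) state sequence;
FO can alternatively be read from the mean posterior probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "temporal_metrics",
    "subject_metrics",
    "StateSpectra",
    "state_conditioned_spectra",
    "NetworkLabeling",
    "label_networks",
    "pool_ipsi_contra",
]


def _runs(path: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(state, start, length) of each maximal run in a 1-based path."""
    path = np.asarray(path, dtype=int)
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [path.size]]))
    return path[starts], starts, lengths


def temporal_metrics(
    path: np.ndarray,
    fs: float,
    n_states: int | None = None,
    edge_visits: str = "exclude",
) -> pd.DataFrame:
    """Life-time, interval time and FO per state for one hard state sequence.

    A "visit" is a maximal run of one state.  ``life_time_ms`` is the mean
    visit duration, ``interval_time_ms`` the mean gap between consecutive
    visits to the same state, both in milliseconds.  Visits truncated by the
    recording edges are censored: with ``edge_visits='exclude'`` (default)
    they and the intervals they flank are left out of the means (FO always
    keeps every sample); ``'include'`` counts them anyway.

    States that never occur get FO 0 and absent (NaN) durations — never 0,
    since a zero life-time is not a possible observation.
    """
    path = np.asarray(path, dtype=int)
    if path.size == 0:
        raise ValueError("empty state path")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if edge_visits not in ("exclude", "include"):
        raise ValueError("edge_visits must be 'exclude' or 'include'")
    K = int(n_states if n_states is not None else path.max())
    if path.min() < 1 or path.max() > K:
        raise ValueError("path values must lie in 1..n_states")
    states, starts, lengths = _runs(path)
    n_runs = states.size
    interior = np.ones(n_runs, dtype=bool)
    if edge_visits == "exclude":
        interior[0] = False
        interior[-1] = False
    ms = 1000.0 / fs
    rows = []
    T = path.size
    for k in range(1, K + 1):
        idx = np.flatnonzero(states == k)
        fo = float(np.sum(lengths[idx]) / T)
        keep = idx[interior[idx]]
        life = float(np.mean(lengths[keep]) * ms) if keep.size else np.nan
        # gaps between consecutive visits; kept only when both flanking
        # visits are themselves uncensored
        gaps = []
        for a, b in zip(idx[:-1], idx[1:]):
            if edge_visits == "include" or (interior[a] and interior[b]):
                gaps.append((starts[b] - (starts[a] + lengths[a])) * ms)
        interval = float(np.mean(gaps)) if gaps else np.nan
        rows.append(
            {
                "state": k,
                "n_visits": int(keep.size if edge_visits == "exclude" else idx.size),
                "life_time_ms": life,
                "interval_time_ms": interval,
                "fractional_occupancy": fo,
            }
        )
    return pd.DataFrame(rows)


def subject_metrics(
    posterior,
    fs: float,
    subject_ids: list[str],
    n_states: int | None = None,
    edge_visits: str = "exclude",
    fo_source: str = "viterbi",
) -> pd.DataFrame:
    """Temporal metrics per subject from a multi-segment posterior.

    Each subject contributes one mean per state.  ``fo_source='gamma'``
    replaces the Viterbi-based FO with the mean posterior probability.
    """
    if fo_source not in ("viterbi", "gamma"):
        raise ValueError("fo_source must be 'viterbi' or 'gamma'")
    K = n_states or posterior.n_states
    frames = []
    for i, sid in enumerate(subject_ids):
        gamma, path = posterior.segment(i)
        df = temporal_metrics(path, fs, n_states=K, edge_visits=edge_visits)
        if fo_source == "gamma":
            df["fractional_occupancy"] = gamma.mean(axis=0)
        df.insert(0, "subject_id", sid)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@dataclass
class StateSpectra:
    """Per-state spectral description over a frequency grid."""

    state: int
    freqs: np.ndarray  # (F,)
    psd: np.ndarray  # (P, F), >= 0
    coherence: np.ndarray  # (P, P, F), in [0, 1]
    peak_frequency: float
    parcel_labels: list[str] | None = None


def state_conditioned_spectra(
    data: np.ndarray,
    fs: float,
    gamma: np.ndarray,
    window_s: float = 2.0,
    overlap: float = 0.5,
    fmin: float = 1.0,
    fmax: float = 40.0,
) -> list[StateSpectra]:
    """Welch-style spectra weighted by each state's posterior probability.

    Sliding Hann windows (default 2 s, 50% overlap) are Fourier transformed;
    each window's periodogram and cross-spectra enter state k's average with
    weight equal to the window-mean of ``gamma[:, k]``.  Coherence is the
    magnitude-squared cross-spectrum normalized by the auto-spectra.  The peak
    frequency is the argmax of the parcel-mean PSD within [fmin, fmax].

    A state whose total posterior mass is below one window's worth of samples
    yields no spectra (skipped with a warning).
    """
    data = np.asarray(data, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    T, P = data.shape
    if gamma.shape[0] != T:
        raise ValueError("gamma rows must align with data samples")
    K = gamma.shape[1]
    nper = int(round(window_s * fs))
    step = max(1, int(round(nper * (1 - overlap))))
    if T < nper:
        raise ValueError("recording shorter than one spectral window")
    win = sps.get_window("hann", nper)
    norm = fs * np.sum(win**2)
    freqs = np.fft.rfftfreq(nper, 1 / fs)
    sel = (freqs >= fmin) & (freqs <= fmax)
    starts = np.arange(0, T - nper + 1, step)
    # FFT of every window, all parcels: (n_win, P, F)
    segs = np.stack([data[s : s + nper] * win[:, None] for s in starts])
    F = np.fft.rfft(segs, axis=1).transpose(0, 2, 1)  # (n_win, P, F)
    wgt = np.stack([gamma[s : s + nper].mean(axis=0) for s in starts])  # (n_win, K)
    out = []
    for k in range(K):
        w = wgt[:, k]
        if w.sum() * nper < nper:  # less than one window of occupancy
            warnings.warn(f"state {k + 1}: too little occupancy for spectra")
            continue
        w = w / w.sum()
        # weighted cross-spectral matrix (P, P, F)
        S = np.einsum("n,npf,nqf->pqf", w, F, np.conj(F)) * (2.0 / norm)
        psd = np.real(np.einsum("ppf->pf", S))
        denom = np.sqrt(psd[:, None, :] * psd[None, :, :])
        coh = np.abs(S) / np.maximum(denom, 1e-300)
        np.clip(coh, 0.0, 1.0, out=coh)
        mean_psd = psd[:, sel].mean(axis=0)
        peak = float(freqs[sel][np.argmax(mean_psd)])
        out.append(
            StateSpectra(
                state=k + 1,
                freqs=freqs[sel],
                psd=psd[:, sel],
                coherence=coh[:, :, sel],
                peak_frequency=peak,
            )
        )
    return out


@dataclass
class NetworkLabeling:
    """Mapping from HMM state to functional-network label."""

    mapping: dict[int, str]  # state -> label
    provenance: str  # 'auto' | 'manual-config'
    scores: dict[str, dict[int, float]] | None = None
    ambiguous: list[str] | None = None


KNOWN_LABELS = ("iSMN", "cSMN", "SMN", "left-SMN", "right-SMN", "DMN", "VN", "TPN", "other")


def label_networks(
    spectra: list[StateSpectra],
    templates: dict[str, dict] | None = None,
    manual: dict[int, str] | None = None,
    score_tol: float = 0.05,
) -> NetworkLabeling:
    """Assign functional-network labels to states.

    Manual mode takes an explicit ``{state: label}`` map (each label at most
    once).  Auto mode scores every state against config-supplied templates —
    each a dict with ``weights`` (per-parcel amplitude map) and ``band``
    (frequency window in Hz, e.g. alpha for sensorimotor/visual, 3-5 Hz theta
    for default-mode) — using the spatial correlation between the template
    weights and the state's band-limited power map, requiring the state's
    peak frequency to fall inside the band.  When the two best states for a
    label score within ``score_tol`` the label is flagged as ambiguous rather
    than silently assigned.
    """
    states = [s.state for s in spectra]
    if manual is not None:
        labels = list(manual.values())
        if len(set(labels)) != len(labels):
            raise ValueError("each label may be claimed at most once in manual config")
        for st in manual:
            if st not in states:
                raise ValueError(f"manual config references unknown state {st}")
        return NetworkLabeling(mapping=dict(manual), provenance="manual-config")
    if not templates:
        raise ValueError("auto labeling needs template maps")
    scores: dict[str, dict[int, float]] = {}
    mapping: dict[int, str] = {}
    ambiguous: list[str] = []
    for label, spec_t in templates.items():
        w = np.asarray(spec_t["weights"], dtype=float)
        if not np.any(w):
            raise ValueError(f"template {label!r} has all-zero weights")
        lo, hi = spec_t.get("band", (1.0, 40.0))
        per_state = {}
        for s in spectra:
            band_sel = (s.freqs >= lo) & (s.freqs <= hi)
            power_map = s.psd[:, band_sel].mean(axis=1)
            if w.size != power_map.size:
                raise ValueError("template weight length must match parcel count")
            wd = w - w.mean()
            pd_ = power_map - power_map.mean()
            denom = np.sqrt(np.sum(wd**2) * np.sum(pd_**2))
            # constant template or power map cannot discriminate states
            r = np.sum(wd * pd_) / denom if denom > 0 else -np.inf
            if not (lo <= s.peak_frequency <= hi):
                r = -np.inf  # peak outside the template band: not a candidate
            per_state[s.state] = float(r)
        scores[label] = per_state
        ranked = sorted(per_state.items(), key=lambda kv: -kv[1])
        if not np.isfinite(ranked[0][1]):
            continue
        if len(ranked) > 1 and ranked[0][1] - ranked[1][1] < score_tol and np.isfinite(ranked[1][1]):
            ambiguous.append(label)
    # greedy assignment by descending score, each label and state used once
    pairs = sorted(
        ((sc, label, st) for label, per in scores.items()
         for st, sc in per.items() if np.isfinite(sc) and label not in ambiguous),
        key=lambda t: -t[0],
    )
    taken_labels: set[str] = set()
    for sc, label, st in pairs:
        if label in taken_labels or st in mapping:
            continue
        mapping[st] = label
        taken_labels.add(label)
    return NetworkLabeling(
        mapping=mapping, provenance="auto", scores=scores, ambiguous=ambiguous
    )


def pool_ipsi_contra(
    metrics: pd.DataFrame,
    labeling: NetworkLabeling,
    lesion_side: dict[str, str | None],
    control_reference: str = "R",
) -> pd.DataFrame:
    """Re-key hemisphere-specific sensorimotor metrics to ipsi/contralesional.

    For each stroke subject the sensorimotor state in the lesioned hemisphere
    becomes ``iSMN`` and the other ``cSMN``; left- and right-lesion subjects
    can then be pooled.  Controls have no lesion: they are assigned by the
    convention of the comparison group (``control_reference`` names the
    lesioned side of the stroke group they are concatenated with, so a
    control's right-hemisphere SMN enters the iSMN column when compared with
    right-lesion patients).
    """
    inv = {v: k for k, v in labeling.mapping.items()}
    try:
        left_state, right_state = inv["left-SMN"], inv["right-SMN"]
    except KeyError as err:
        raise ValueError(
            "labeling must contain hemisphere-specific 'left-SMN' and "
            "'right-SMN' states"
        ) from err
    rows = []
    for sid, sub in metrics.groupby("subject_id", sort=False):
        side = lesion_side.get(sid, "missing")
        if side == "missing":
            raise ValueError(f"unknown lesion side for subject {sid!r}")
        if side is None:  # control
            side = control_reference
        elif side not in ("L", "R"):
            raise ValueError(f"lesion side for {sid!r} must be 'L', 'R' or None")
        ipsi = left_state if side == "L" else right_state
        contra = right_state if side == "L" else left_state
        for region, st in (("iSMN", ipsi), ("cSMN", contra)):
            row = sub[sub["state"] == st]
            if row.empty:
                continue
            r = row.iloc[0].to_dict()
            r["region"] = region
            rows.append(r)
    out = pd.DataFrame(rows)
    cols = ["subject_id", "region"] + [
        c for c in out.columns if c not in ("subject_id", "region")
    ]
    return out[cols]
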