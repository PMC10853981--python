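"""Rest-to-task transfer: frozen state models applied to epoched task data.

The generalizability analysis takes the state descriptions inferred from
resting data and — without refitting any parameter — runs posterior inference
on task epochs, then extracts the same temporal metrics.  Trials are decoded
independently (epochs are discontinuous excerpts, so transitions must not
bridge trial boundaries), and per-trial metrics are averaged per subject with
equal weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .characterize import temporal_metrics
from .hmm import StatePosterior, TDEHMMResults, forward_backward
from .prep import ParcelTimeSeries, project_embedded, time_delay_embed, zscore_parcels

__all__ = ["EpochedData", "epoch", "decode_task"]


@dataclass
class EpochedData:
    """Trials x time x parcels array cut around event onsets.

    ``window`` is in seconds relative to the onset, default (-3, +3); the
    window must contain the onset and all trials have equal length.
    """

    data: np.ndarray
    fs: float
    window: tuple[float, float] = (-3.0, 3.0)
    event: str = "paretic-hand"
    subject_id: str = "s00"
    parcel_labels: list[str] = field(default_factory=list)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x time x parcels")
        if not (self.window[0] <= 0.0 <= self.window[1]):
            raise ValueError("window must contain the event onset (0 s)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def epoch(
    ts: ParcelTimeSeries,
    onsets: np.ndarray,
    window: tuple[float, float] = (-3.0, 3.0),
    event: str = "paretic-hand",
) -> EpochedData:
    """Cut trials around event onsets; half-open sample windows.

    Trial t covers samples ``[onset_t + round(window[0]*fs),
    onset_t + round(window[1]*fs))``.  Onsets whose window falls outside the
    recording are dropped with a warning, and the dropped count is recorded.
    """
    onsets = np.asarray(onsets, dtype=int)
    lo = int(round(window[0] * ts.fs))
    hi = int(round(window[1] * ts.fs))
    trials = []
    dropped = 0
    for o in onsets:
        if o + lo < 0 or o + hi > ts.n_samples:
            dropped += 1
            continue
        trials.append(ts.data[o + lo : o + hi])
    if dropped:
        warnings.warn(f"dropped {dropped} of {onsets.size} trials outside the recording")
    data = np.stack(trials) if trials else np.empty((0, hi - lo, ts.n_parcels))
    return EpochedData(
        data=data,
        fs=ts.fs,
        window=window,
        event=event,
        subject_id=ts.subject_id,
        parcel_labels=list(ts.parcel_labels),
        n_dropped=dropped,
    )


def decode_task(
    results: TDEHMMResults,
    epochs: EpochedData,
    edge_visits: str = "exclude",
) -> tuple[list[StatePosterior], pd.DataFrame, pd.DataFrame]:
    """Decode task epochs with the frozen rest model and extract metrics.

    Each trial is projected into the rest model's embedded-PCA space with the
    stored normalization and basis, decoded independently by forward-backward
    and Viterbi, and summarized with the same temporal metrics as rest.
    Returns per-trial posteriors, the per-trial metric table, and the
    subject-level table (equal-weight average over trials; FO re-normalized).
    The model parameters are asserted bit-identical before and after.
    """
    st = results.model.prep_state
    h0 = results.params_hash()
    posteriors: list[StatePosterior] = []
    frames = []
    fs = epochs.fs
    for i in range(epochs.n_trials):
        trial = epochs.data[i]
        if st is not None:
            if epochs.parcel_labels and epochs.parcel_labels != st.parcel_labels:
                raise ValueError("epoch parcel labels do not match the fitted model")
            scale = st.parcel_scales.get(epochs.subject_id)
            ts = ParcelTimeSeries(
                trial, fs=fs, parcel_labels=st.parcel_labels,
                subject_id=epochs.subject_id, session="task",
            )
            ts, _ = zscore_parcels(ts, scale)
            emb = time_delay_embed(ts, st.lag_set)
            X = project_embedded(emb, st.template)
        else:
            X = trial
        if X.shape[1] != results.params.n_features:
            raise ValueError(
                f"trial dimensionality {X.shape[1]} does not match the stored "
                f"basis ({results.params.n_features})"
            )
        post = results.decode(X)
        posteriors.append(post)
        df = temporal_metrics(
            post.viterbi_path, fs, n_states=results.n_states, edge_visits=edge_visits
        )
        df.insert(0, "trial", i)
        frames.append(df)
    if results.params_hash() != h0:  # frozen-model contract
        raise RuntimeError("model parameters changed during task decoding")
    per_trial = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if frames:
        subject = (
            per_trial.groupby("state", as_index=False)
            .agg(
                n_visits=("n_visits", "sum"),
                life_time_ms=("life_time_ms", "mean"),
                interval_time_ms=("interval_time_ms", "mean"),
                fractional_occupancy=("fractional_occupancy", "mean"),
            )
        )
        subject.insert(0, "subject_id", epochs.subject_id)
        subject.insert(1, "event", epochs.event)
    else:
        subject = pd.DataFrame()
    return posteriors, per_trial, subject
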