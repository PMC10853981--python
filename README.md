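# dynstates

Dynamic brain-network states from parcel-level electrophysiology, with the
clinical statistics used to relate those dynamics to post-stroke motor
recovery.

## The problem

Resting-state MEG/EEG source recordings can be decomposed, in a data-driven
way, into a small number of recurring network states: mutually exclusive
spatio-spectral patterns that switch on millisecond timescales. In people
with subacute stroke, the temporal behaviour of the sensorimotor network
state in the lesioned hemisphere (its dwell time and how much of the
recording it occupies) carries clinical information about concurrent and
future upper-limb function. This package implements the full analysis chain
for that kind of study, starting from parcel time courses:

1. **Signal conditioning** — zero-phase band-pass (default 1–40 Hz),
   resampling (default 250 Hz), symmetric orthogonalization for
   source-leakage correction, per-channel scaling.
2. **Time-delay embedding + PCA** — each parcel is augmented with its lagged
   copies (default 15 lags, −7..+7 samples ≙ ±30 ms at 250 Hz), then reduced
   to principal components, so that model states capture autocovariance
   (spectral and cross-spectral) structure rather than mean levels.
3. **Hidden Markov model** — a K-state HMM (default K = 10) with zero-mean
   Gaussian observations per state, fitted by maximum-likelihood EM
   (scaled forward–backward recursions, Viterbi decoding, multi-restart
   model selection), with subjects temporally concatenated and transitions
   barred across subject boundaries.
4. **State characterization** — per subject and state: life-time (mean
   dwell), interval time and fractional occupancy (FO); gamma-weighted
   Welch spectra and coherence per state; automatic or manual mapping of
   states to functional networks (SMN/DMN/VN/…), including pooling of
   hemisphere-specific sensorimotor states into ipsi-/contralesional
   (iSMN/cSMN) columns by lesion side.
5. **Rest→task transfer** — the frozen rest-fitted model decodes epoched
   task data (default −3..+3 s around movement onsets) with the stored
   filters, normalization and PCA basis; no parameter is refitted.
6. **Clinical statistics** — median/IQR summaries (Tukey hinges), MCID
   counts for ARAT and FM-UE, recovery subgrouping, Mann–Whitney U and
   Wilcoxon signed-rank tests (midrank ties, exact enumeration at small n,
   effect size r = |Z|/√N), 2×2 mixed-design ANOVA with partial η²,
   Spearman and partial Spearman rank correlation, Bonferroni correction.

Because raw clinical MEG is not freely distributable, the package ships a
**synthetic cohort generator** (Markov-switching oscillatory parcel signals
with known ground truth, plus clinical score tables with a planted
metric–score correlation) and a bundled 37-patient clinical table, so every
stage is testable against a known truth.

## The model

Observations are embedded vectors `x_t ∈ R^Q`. A hidden chain
`z_t ∈ {1..K}` follows `P(z_t = j | z_{t-1} = i) = A_ij`; given `z_t = k`,
`x_t ~ N(0, Σ_k)`. The state time course is summarized by, per state k:

- life-time: mean duration of a maximal visit to k (ms),
- interval time: mean gap between consecutive visits to k (ms),
- FO: fraction of samples assigned to k (Σ_k FO_k = 1).

Inference is classical Baum–Welch: E-step forward–backward marginals
`γ_t(k)` and transition counts `ξ(i,j)`, M-step closed-form updates of
`π, A, Σ_k` (ridge-regularized), monotone log-likelihood, best of seeded
restarts.

## Worked example

```python
import numpy as np
import dynstates as ds

# clinical side: the bundled cohort table
table = ds.load_stroke_cohort()
med, q1, q3 = ds.median_iqr(table["arat_w3"])
print(f"Week-3 ARAT median (IQR): {med:g} ({q1:g}-{q3:g})")
arat_n, fmue_n, n_pairs = ds.mcid_counts(table)
print(f"FM-UE MCID improvements: {fmue_n}/{n_pairs}")

# signal side: synthetic two-state cohort -> TDE-HMM
truth = ds.default_truth(n_parcels=6, noise_sd=0.4, seed=0)
ts_list = []
for i in range(2):
    path = ds.simulate_markov_chain(truth, 20_000, seed=10 + i)
    ts = ds.synthesize_parcel_signals(path, truth, seed=20 + i)
    ts.subject_id = f"s{i:02d}"
    ts_list.append(ts)
model = ds.TDEHMM.from_parcels(ts_list, n_states=2,
                               lag_set=np.arange(-3, 4), n_components=8)
res = model.fit(seed=0, n_restarts=2, max_iter=50)
print(res.summary())
print(res.temporal_metrics().round(3).to_string(index=False))
```

prints

```
Week-3 ARAT median (IQR): 32 (6-56)
FM-UE MCID improvements: 14/29
Time-delay-embedded HMM results
===============================================
states:              2
feature dim:         8
observations:        39988
segments:            2
log-likelihood:      -628080.71
EM iterations:       10
converged:           True
restarts (loglik):   -628080.8, -628080.7
-----------------------------------------------
state   FO      a_kk
    1   0.485   0.962
    2   0.515   0.964
subject_id  state  n_visits  life_time_ms  interval_time_ms  fractional_occupancy
       s00      1       342       113.626           120.282                 0.486
       s00      2       341       120.282           112.612                 0.514
       s01      1       348       112.931           116.519                 0.491
       s01      2       347       116.519           113.283                 0.509
```

The cohort table numbers read exactly as a clinician would report them: a
median week-3 ARAT of 32 with Tukey-hinge IQR 6–56, and 14 of the 29
patients seen at both visits improving by more than the FM-UE minimal
clinically important difference. On the signal side the model recovers two
states with balanced occupancy; note that dwell times estimated through the
embedding pipeline read slightly longer than the generating 80 ms because
consecutive embedded vectors share samples (see `docs/methods.md`).

A command-line pipeline wraps the same machinery:

```bash
dynstates simulate --out cohort/
dynstates fit --data cohort/ --out model/
dynstates stats --model model/ --clinical cohort/clinical.csv --out results/
```

Each stage validates its YAML config up front and writes the resolved
config plus a SHA-256 manifest next to its outputs.

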