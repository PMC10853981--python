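# Methods

This note records the modelling choices, numerical conventions and known
limitations of the package. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Model

Parcel time courses (time × parcels, sampling rate `fs`) are conditioned and
embedded, and a K-state hidden Markov model with zero-mean Gaussian
observations is fitted to the result. States are therefore distinguished by
their autocovariance — oscillatory content and cross-parcel covariance —
rather than by signal mean. The hidden chain is first-order Markov; exactly
one state is active per sample. Both assumptions are simplifications (real
networks can coactivate, and dwell distributions need not be geometric), and
they are what makes the temporal metrics well defined.

### Conditioning chain

1. **Band-pass** 1–40 Hz, 4th-order Butterworth applied forward–backward
   (`sosfiltfilt`): zero phase, so filtered samples stay aligned with raw
   samples; the effective order is doubled. The stop-band requirement used in
   tests is ≥ 20 dB at 0.1 Hz and 60 Hz relative to the 10 Hz passband
   response.
2. **Resampling** to 250 Hz by polyphase FIR with a Kaiser window (β = 12).
   One anti-aliased code path serves integer and rational ratios; duration is
   preserved to within one output sample.
3. **Symmetric orthogonalization** (leakage correction): the closest set of
   mutually orthogonal time courses in the least-squares sense, found by
   alternating an orthogonal-Procrustes projection with per-column rescaling.
   The objective is non-increasing and iteration stops on a relative change
   below `tol` (default 1e-12). Orthogonality here means zero *inner
   products*; inputs are band-passed and hence effectively zero-mean, so this
   coincides with zero correlation to numerical precision, and
   already-orthogonal inputs are an exact fixed point. Rank-deficient input
   is refused, naming the most collinear parcel pair.
4. **Per-channel z-scoring, per subject**: each subject's parcels are scaled
   by that subject's own statistics before concatenation, so between-subject
   amplitude differences do not dominate the shared covariance model. The
   (mean, sd) pairs are stored for task transfer.
5. **Time-delay embedding**: 15 lags, −7..+7 samples (±30 ms at 250 Hz),
   parcel-major/lag-minor column order; edge rows that would need
   out-of-range samples are dropped, not padded — padding would fabricate
   data at recording boundaries and bias dwell estimates. The crop offset is
   kept so posteriors can be aligned back to raw samples.
6. **PCA** to `n_components` (default 2 × parcels). The mean and orthonormal
   basis are stored; task data are projected with the identical basis.

### Inference

- Scaled forward–backward recursions (per-sample normalization plus a
  per-row max-shift of the log-densities), stable for T ~ 1e6. Exactness is
  tested against brute-force enumeration over all hidden paths for small
  instances.
- Viterbi decoding in log space; ties break toward the lower state index, so
  decoding is deterministic (two identical states yield a constant path at
  state 1).
- EM (Baum–Welch), maximum likelihood. The variational-Bayes scheme of the
  original MEG toolbox is deliberately not reproduced: the quantities
  consumed downstream (posteriors, Viterbi paths, temporal metrics) are
  inference-scheme-agnostic at the precision this package tests.
- M-step: π from segment starts; A from expected transition counts, which
  never cross subject boundaries; Σ_k as the γ-weighted second moment plus a
  ridge `reg × mean(diag)` (default `reg = 1e-6`) — embedded dimensions are
  highly collinear and the ridge keeps Cholesky factorizations well posed.
  `mean_mode='free'` estimates means as well (useful for testing; the
  embedded-space convention is zero).
- Initialization: random responsibilities in contiguous blocks (geometric
  block lengths, mean 200 samples, 0.9/0.1 soft assignment), seeded per
  restart. Fully independent per-timepoint random responsibilities are a
  symmetric saddle — every state's weighted covariance equals the global
  covariance — from which EM escapes only slowly; blocky responsibilities
  give the first M-step distinct covariances. Default 5 restarts, best final
  log-likelihood wins; everything is driven by one integer seed through
  `SeedSequence` spawning.
- Stopping: relative log-likelihood improvement below `tol` (default 1e-6)
  or `max_iter`. The trace is checked to be non-decreasing within numerical
  tolerance; a decrease raises.
- Empty states: a state whose occupancy collapses (below Q+1 samples) has
  its covariance reinitialized once from a random contiguous data segment
  (seeded); if it collapses again the model drops to K−1 states with a
  warning, never a crash.

## Temporal metrics

A *visit* is a maximal run of one state in the Viterbi path. Life-time is
the mean visit duration × 1000/fs; interval time is the mean gap between
consecutive visits to the same state; FO is the fraction of samples in the
state (sums to 1 over states by construction). Visits truncated by the
recording edges are censored: by default they, and the intervals they flank,
are excluded from the duration means, while FO keeps every sample. The
switch `edge_visits='include'` counts them anyway, since the convention is
not universal. States that never occur get FO 0 and *absent* (NaN)
durations — never 0, which would be a valid-looking but impossible
observation. Metrics are computed from the hard path because the definitions
("time between entering and exiting") presuppose one; FO is alternatively
available as mean γ (`fo_source='gamma'`). Each subject contributes one mean
per state to group statistics.

One caveat the synthetic tests make visible: dwell times estimated through
the full embedding pipeline read systematically longer than the generating
chain's (e.g. ~115 ms for an 80 ms truth in the README example), because
consecutive embedded vectors share samples and are therefore autocorrelated,
which smooths the decoded path. Parameter-recovery accuracy is therefore
assessed on observations drawn directly from the Gaussian HMM (where the
model is correctly specified): there, transition matrices recover to <0.02
entrywise, FO to <0.03 and life-times to a few percent.

## State spectra and network labels

State-conditioned spectra use γ-weighted Welch averaging: Hann windows
(default 2 s, 50% overlap) are Fourier transformed, and each window enters
state k's cross-spectral average with weight equal to the window-mean of
γ_k. Coherence is the normalized cross-spectrum magnitude; the peak
frequency is the argmax of the parcel-mean PSD in 1–40 Hz. This estimator
has an intrinsic resolution constraint: it separates states only when dwell
times are at least comparable to the window length. For fast-switching
regimes (e.g. 80 ms dwells against 2 s windows) every window mixes states
and the per-state spectra converge to the common mixture; the acceptance
script therefore measures spectral peaks on a slow-switching cohort (mean
dwell 400 ms, 1 s windows). States with less than one window's worth of
posterior mass yield no spectrum, with a warning.

Network labeling is either manual (explicit state → label, each label at
most once) or automatic: states are scored against template parcel-weight
maps by spatial correlation of band-limited power, a state only being a
candidate for a label when its peak frequency lies in the template's band
(alpha-range templates for sensorimotor and visual networks, 3–5 Hz theta
for the default-mode network). Assignment is greedy by descending score with
each label and each state used at most once; a label whose two best states
score within `score_tol` is flagged ambiguous rather than silently assigned.
For lesion-split models carrying left- and right-hemisphere sensorimotor
states, `pool_ipsi_contra` re-keys each stroke subject's metrics to
iSMN/cSMN by lesion side; controls, who have no lesion, take the convention
of the comparison group (a control's right-hemisphere SMN enters the iSMN
column when the comparison group has right-hemisphere lesions).

## Task transfer

Epochs (default −3..+3 s around movement onset, half-open sample windows,
out-of-range onsets dropped with a logged count) are projected with the rest
pipeline's stored filters, per-subject scaling and PCA basis, and decoded
per trial independently — epochs are discontinuous excerpts, so transitions
must not bridge trial boundaries (decoding a concatenation with boundaries
at trial edges is verified to equal independent decoding). Per-trial metrics
are averaged per subject with equal weights. No model parameter is updated;
a SHA-256 hash of the parameter arrays is asserted unchanged, and decoding
the rest data itself reproduces the rest metrics exactly.

## Clinical statistics

- **Median/IQR**: Tukey hinges by default (the halves include the overall
  median when n is odd); linear interpolation available. Medians of odd-n
  columns are exact integers and byte-stable.
- **MCID counts** (week 3 → week 12, complete pairs only): FM-UE counts an
  improvement strictly greater than 12.4 points; ARAT counts ≥ 12 points
  when the affected hand is the dominant right hand and ≥ 17 otherwise
  (the cohort is right-handed). On the bundled table the FM-UE count is
  14/29; the ARAT count under these thresholds is 13 and no >/≥ or
  side-assignment reading reproduces a different published tally exactly, so
  only the FM-UE count is treated as a fixed reference value.
- **Recovery subgroups**: "nearly fully recovered" is week-3 ARAT > 55 or
  FM-UE > 64; "not fully recovered" is ARAT < 56 and FM-UE < 65. For
  integer scores the definitions are exact complements, which is asserted.
- **Mann–Whitney U**: midrank ties; reported as min(U, n₁n₂−U) with the
  direction made explicit, since the literature quotes U on both
  conventions' scales. Z uses the tie-corrected variance with a 0.5
  continuity correction; r = |Z|/√N. For n₁+n₂ ≤ 12 the p-value is exact
  (all group assignments enumerated; two-sided extremeness measured as
  |U − n₁n₂/2|).
- **Wilcoxon signed-rank**: zero differences dropped by default (the Pratt
  variant is a switch); midranks on |Δ|; tie-corrected variance, no
  continuity correction; r = |Z|/√n over nonzero pairs; exact sign-flip
  enumeration for n ≤ 14. All-zero differences return an explicit
  "undefined" result rather than a number.
- **2×2 mixed ANOVA**: sum/difference decomposition. With subject means
  s = (y₁+y₂)/2 and differences d = y₁−y₂, the group effect is the one-way
  ANOVA on s; the region effect tests the *unweighted* grand mean of d
  (Type III marginality, the SPSS GLM default, which differs from
  weighted-mean conventions when group sizes are unequal); the interaction
  is the group contrast on d and reduces exactly to the squared two-sample
  t on differences. η_p² = SS_effect/(SS_effect+SS_error) within each error
  stratum. Missing measures are excluded listwise with a logged count.
- **Spearman**: Pearson correlation of midranks; p from the t
  approximation, or exhaustive permutation for n ≤ 9 (the n! enumeration
  grows too fast beyond that; the threshold is a parameter). The partial
  variant rank-transforms all three variables and applies the first-order
  partial-correlation formula with df = n−3; zero residual variance is
  signalled as undefined, not returned as a number.
- **Bonferroni**: α/m thresholds and decisions reported beside raw
  p-values; p-values are carried at full precision and only formatted at
  the reporting layer.

## Synthetic cohorts

The generator emulates what the downstream analysis needs from source-space
recordings, not the physics of MEG. A hidden chain with configurable
transition matrix switches which parcels carry a sinusoid (continuous phase,
random onset phase) at the state's frequency; independent Gaussian noise is
added everywhere. Amplitude-modulated sinusoids were chosen over AR
processes because the state-conditioned spectra are then analytically known,
making spectral-recovery tests exact. The default two-state cohort has a
10 Hz sensorimotor-like state on the first half of the parcels and a 4 Hz
default-mode-like state on the second half, self-transition probability
0.95 (mean dwell 20 samples = 80 ms at 250 Hz, in the range of fast
resting-state network dynamics) and noise sd 0.5. Not emulated: sensor-level
physics, head movement, physiological artefacts, 1/f background, volume
conduction (beyond what orthogonalization removes by construction) and
inter-subject spatial variability — so passing tests demonstrate
correctness of the algorithms under the model's assumptions, not performance
on real recordings.

Clinical tables are generated with a Gaussian copula: the week-3 ARAT is a
monotone integer transform of a latent variable correlated with the supplied
metric values, with the Pearson parameter inverted from the target Spearman
correlation (ρ_P = 2 sin(πρ_S/6)), so the sample Spearman correlation
converges to the requested value. FM-UE tracks the same latent with noise;
week-12 scores add non-negative gains clipped to the instrument ranges
(ARAT 0–57, FM-UE 0–66); a configurable fraction of week-12 entries is
missing — encoded as absent, never 0, because 0 is a valid score. The
default missing fraction 8/37 matches the bundled cohort's follow-up rate.

## Problem sizes

The test suite and acceptance script run at sizes chosen to make the
statistical tolerances meaningful on a single CPU: exact-inference checks
at K ≤ 3, T ≤ 8 (100 instances); parameter recovery at five subjects ×
60 000 samples for K = 2, 3, 4; dwell-time and stationarity checks at
2×10⁵–10⁶ samples; the end-to-end pipeline examples at 2 subjects ×
20 000–30 000 samples with 6–8 parcels and 7 lags. The forward–backward,
Viterbi and EM inner loops are numba-compiled with a pure-numpy fallback.

## Known limitations

- Maximum-likelihood EM, not variational Bayes: no automatic state-count
  selection or posterior uncertainty over parameters; K is a user choice.
- Metrics from the Viterbi path inherit its smoothing; rare brief visits
  can be absorbed into neighbours, and embedding autocorrelation lengthens
  apparent dwells (quantified above).
- The spectral estimator trades resolution for simplicity; for
  fast-switching regimes a multitaper or time-frequency estimator keyed to
  sample-level state membership would be needed.
- The mixed ANOVA covers the 2×2 design used here, not general factorial
  layouts.
- The pipeline starts at parcel time courses; co-registration, beamforming,
  parcellation and artefact rejection are upstream and out of scope.
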