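# Methods

## Information-flow estimation

The pairwise estimator follows the linear (Gaussian) formulation of the
Liang–Kleeman information flow rate. For each ordered pair (transmitter
`i`, receiver `j`) we compute population-normalized (divide by N) sample
moments on a common index set: both series are truncated to their first
`N - k` samples and paired with the receiver's forward-difference
derivative `(x[n+k] - x[n]) / (k dt)` at the same index (`k = 1` by
default, `k = 2` selectable). Covariance normalization cancels in every
ratio that enters the flow, so the population form is used throughout for
internal consistency.

The derivative cross-correlations are normalized by the product of the
*series* standard deviations (`r_{i,dj} = C_{i,dj} / (sigma_i sigma_j)`),
not by the derivative's own standard deviation. This is the convention
under which the correlation form of the flow,
`T = r_ij/(1 - r_ij^2) * (r_{i,dj} - r_ij r_{j,dj})`, is algebraically
identical to the covariance form
`T = a_ij C_ij / C_jj`, where `a_ij` is the least-squares coefficient of
the transmitter in the receiver-derivative regression
`dx_j ~ a_jj x_j + a_ij x_i`. An alternative normalization by the
derivative's standard deviation is available behind a flag; it rescales
`T` by a positive factor and leaves signs and the `|tau| <= 1` contract
intact.

### The normalizer Z

The receiver's entropy-rate budget has three magnitude components: the
transmitter's contribution `|T|`, the receiver's own dynamics
`|a_jj|`, and the noise contribution `g_j / (2 C_jj)` with noise
intensity `g_j = dt * mse` (mean squared residual of the same
least-squares fit, scaled to intensity units by the sampling interval).
`Z` is their sum, so `tau = T / Z` satisfies `|tau| <= 1` and
`sign(tau) = sign(T)` identically — both are enforced as property tests.
When `Z = 0` (possible only for exactly degenerate inputs) `tau` is
reported as 0 with a flag.

Degenerate pairs — zero-variance rows, near-collinear series
(`|r| >= 1 - 1e-10`) — are masked as NaN with a warning instead of
aborting the participant's matrix; one flat ROI should not discard a
recording.

### Estimator bias and the synthetic oracle

On linear stochastic systems simulated by Euler–Maruyama, the regression
underlying the estimator is exact at the discrete stationary covariance,
so two error sources remain: discretization (the discrete stationary
covariance differs from the continuous Lyapunov solution by O(dt)) and a
finite-span sampling bias of the moment-ratio estimator that decays like
1/(n dt), i.e. with the number of autocorrelation times covered. The
two-node benchmark therefore defaults to dt = 0.04 s with unit-rate
dynamics: at n = 50,000 a path spans 2,000 correlation times with 25
samples per correlation time, keeping both error terms inside the
Monte-Carlo confidence interval of a few-hundred-replicate mean. The
analytic target is `T = a12 * sigma_12 / sigma_11` at the stationary
covariance solving `A S + S A' + Q = 0`.

## Synthetic cohorts

*Coupled-dynamics track.* Each participant is an independent realization
of a ten-node linear SDE `dx = A x dt + Sigma dW`, simulated by
Euler–Maruyama from an exact stationary start (no burn-in). The default
self-feedback rate is −25 /s (40 ms autocorrelation, the scale of
broadband source activity at 250 Hz); planted directed couplings are half
that rate. Two topologies are provided: a three-edge motif (top-k
recovery stays checkable) and a seeded random dense motif
(`random_coupling_spec`, default 20 of 90 edges) whose group-level gain
emulates a cohort-wide magnitude elevation. The "concussed-like" group
scales all off-diagonal couplings by `group_gain` (default 1.5);
stability of the scaled drift is verified and violations are rejected
with the offending eigenvalue named.

*Raw-EEG track.* Each recording mixes eight band-limited 8–12 Hz
oscillatory sources through a seeded near-orthonormal 64-channel mixing
matrix, plus per-channel 1/f-amplitude noise (FFT-shaped, unit
variance). The class effect scales the oscillation amplitude of one class
by `1 + class_effect_size`, so the class signal lives in *relative*
alpha-band power and survives per-epoch amplitude normalization. What the
generator does **not** emulate: volume conduction and realistic forward
head models, artifacts (blinks, EMG, motion), non-stationarity across a
session, and inter-participant anatomical variability. Passing tests
therefore demonstrate correctness of the estimation and training
machinery under known ground truth, not clinical performance on real EEG.

## Group-level statistics

Per-participant matrices are reduced to |tau|; group means are elementwise
with pairwise NaN exclusion. Rankings break ties lexicographically on the
fixed ROI order (LF, RF, LC, RC, LP, RP, LT, RT, LO, RO) for
reproducibility. Pooled distributions concatenate each participant's 90
off-diagonal values; descriptive statistics use the sample (ddof = 1)
standard deviation, COV = SD/mean, Fisher–Pearson moment skewness, and
raw (Pearson, normal = 3) kurtosis with the excess value reported
alongside, since conventions differ across toolboxes. Cohen's d uses the
pooled-SD two-sample formula.

The permutation null shuffles the *transmitter's* samples uniformly at
random (receiver untouched), recomputes |tau| per connection, and pools
values across participants and connections into one group-level null; the
95th percentile is the significance threshold (the 5th is reported but
uninformative after taking absolute values). On white-noise cohorts the
fraction of fresh null |tau| values exceeding the pooled p95 calibrates
at ~5%, which the acceptance suite verifies.

**Known caveat.** The 90 values a participant contributes are not
mutually independent (they share the same realization and nodes), so
two-sample K-S/Kruskal–Wallis tests on pooled values are anticonservative
under the null: on exchangeable synthetic groups the K-S test rejects at
roughly 3–4x the nominal 5% level. Group-difference p-values from pooled
connection values should be read accordingly; the power analysis in the
acceptance suite compares rejection *frequencies* across coupling gains
rather than trusting the nominal level.

Subsample shape features (COV, skewness, kurtosis of pooled values over
random k-of-n participant subsets, default k = 6, 100,000 reps) are
computed from per-participant power sums, making the full default rep
count a vectorized O(reps x k) operation.

## Degree assortativity

Nodes are ROIs, edges are |tau| weights. Weighted in-/out-degrees are
column/row sums. The coefficient r_w is the *edge-weight-weighted*
Pearson correlation, across directed edges, between the source node's
degree and the target node's degree — the default pairing is out-degree
(source) vs in-degree (target), with all four pairings selectable since
the directed variant used in the literature varies. Note this
edge-weighted formulation differs from networkx's
`degree_pearson_correlation_coefficient`, which weights degrees but
counts each edge once; the two coincide on equal-weight graphs (used as a
cross-check). Regular configurations (e.g. complete graphs with equal
weights, pure stars) have zero endpoint-degree variance and yield an
explicit undefined flag rather than a spurious value. Group comparison is
a Welch unequal-variance t-test with Welch–Satterthwaite degrees of
freedom, mean difference with 95% CI, and Cohen's d with a large-sample
CI.

## ConcNet classifier

Preprocessing mirrors minimal-intervention raw-EEG practice: 4 s trimmed
at each end, polyphase anti-aliased resampling to 250 Hz, causal 5th-order
Butterworth low-pass at 100 Hz (zero-phase available by flag), contiguous
non-overlapping 10 s epochs (trailing remainder dropped).

The network is two bidirectional LSTM layers of 24 units per direction —
the first sequence-to-sequence, the second emitting the concatenated
final hidden states (48 features) — with dropout 0.32 after every learned
layer, a dense ReLU layer of 8 units, and a 2-unit softmax output: 31,514
trainable parameters at 64 input channels. Training uses softmax
cross-entropy, Adam at learning rate 0.03, batch size 12, 5 epochs,
seeded weight initialization, shuffling and dropout, and global gradient
clipping at norm 5 for stability at this high learning rate. Per-channel
z-scoring of each epoch (disable-able) bounds the inputs; an integer
`time_decimation` factor subsamples the epoch's time axis before the
network. The engine is pure NumPy with full backpropagation through time,
verified against numerical gradients.

Cross-validation is subject-wise and class-balanced: with 15 + 11
participants and 6 folds each fold trains on 8 + 8 participants, holds
out 1 + 1 for validation monitoring, and tests 6 + 2 (cyclic blocks so
every participant is tested at least once per repeat); 5 repeats x 6
folds give 30 realizations, re-shuffling participants each repeat. Fold
construction asserts participant-level disjointness on every plan. A
participant's prediction is the *median* of their per-epoch concussed
probabilities, labeled concussed iff strictly above 0.5. Metrics
(confusion counts; accuracy, recall, specificity, precision, F1; ROC/AUC
by threshold sweep) are computed per realization and summarized as mean
with a normal-approximation 95% CI; the median ROC is taken pointwise
over a common FPR grid across repeats. A per-participant
tested/misclassified table supports error-pattern analysis.

### Problem sizes in the test and acceptance runs

Training the bLSTM on full 2,500-step sequences is expensive in pure
NumPy, so the shipped test suite and acceptance script exercise the
identical architecture and hyperparameters on reduced realizations:
recordings of 50–80 s, epochs decimated by 10 (250 steps at an effective
25 Hz, which keeps the 8–12 Hz band below Nyquist), 4–6 folds and 1–2
repeats. Bracketing results under these conditions: a null cohort (zero
class effect) stays within sampling error of 50% accuracy, and a
strongly separable cohort (alpha amplitude doubled, 13 + 13 participants)
reaches mean AUC above 0.9. Probability calibration at the 0.5 threshold
is noticeably poorer than ranking performance (AUC) at these small
training sizes — specificity suffers first — which mirrors the
recall/specificity asymmetry commonly reported for this architecture.

## Reproducibility

Every stochastic routine takes an explicit seed; the pipeline driver
spawns per-stage child seeds from a master seed via `SeedSequence`, so a
stage's outputs are reproducible independently of which stages are
enabled. Identical configuration + seed reproduces all outputs
bit-for-bit (asserted in tests).

## Known limitations

- The flow estimator is bivariate: indirect influences through third
  nodes are not conditioned away, and frequency-resolved or nonlinear
  flow is out of scope.
- Whole-recording estimation (one matrix per participant) assumes the
  recording is homogeneous; per-epoch estimation is not provided.
- Pooled-distribution hypothesis tests inherit the dependence caveat
  above.
- The synthetic EEG generator's simplifications mean classifier results
  bound mechanism correctness, not clinical accuracy.
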