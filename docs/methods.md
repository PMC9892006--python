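# Methods

`dopaseq` implements the computational machinery linking sub-second
behavioural syllables to striatal dopamine fluctuations: fiber-photometry
preprocessing, syllable–dopamine statistics, a dopamine-dependent sequence
decoding model, Q-learning agents with dopamine as reward, and closed-loop
opto-reinforcement quantification — together with a synthetic-session
generator that plants every coupling the analyses are meant to detect, so the
whole pipeline can be validated end to end without recordings.

## The dopamine-dependent sequence model

Behaviour is a sequence of discrete syllables s_t (sub-second modules, no
self-transitions) and each instance carries a dopamine peak da_t, the maximum
z-scored sensor fluorescence in the 300 ms after syllable onset.  The model
scores the next syllable with

    P(s_t = i) ∝ exp( α_a Σ_{n=1}^{250} da_{t−n} e^{−n/τ_a} 1[s_{t−n} = i]
                      ────────────────────────────────────────────────────
                      α_b Σ_{n=1}^{250} da_{t−n} e^{−n/τ_b}               )

* **α_a** (usage gain, ≥ 0, fitted) — how strongly dopamine paired with a
  syllable promotes that syllable's future use.
* **τ_a = 100 syllable steps** — the usage-coupling timescale (fixed).
* **α_b = 1 (fixed), τ_b = 10 steps** — recent global dopamine acts as a
  choice temperature: high recent dopamine flattens the choice distribution
  over a ~10-step horizon.
* **window = 250 steps** — history truncation; earlier steps use partial sums
  (no padding).

Numerical choices:

* **Denominator floor.** With per-session z-scored dopamine the trailing sum
  in the denominator crosses zero.  Because the denominator is a temperature,
  it is floored at ε = 0.05 · α_b · Σ e^{−n/τ_b} (the dopamine-free value of
  the sum).  A sign-preserving clamp was rejected: a negative temperature
  flips the direction of the usage coupling at every step where recent
  dopamine sums below −ε, which cancels the positive dopamine→usage coupling
  the model exists to express.  The floor fraction is configurable
  (`guard_frac`) and a sensitivity test verifies the fitted gain is stable
  over a 5× range.
* **Self-transition mask (`mask_self`, default on).** The data contain no
  self-transitions.  Leaving the previous syllable in the softmax support
  biases the fitted usage gain down by roughly a factor of two, because the
  impossible self candidate carries the largest-weight (most recent) dopamine
  term in its usage sum.  With the mask, grid fitting recovers a planted gain
  of 1.0 exactly.  The bare unmasked form remains available
  (`mask_self=False`); its α_a = 0 likelihood is the closed form −T ln K.

**Fitting** scans a grid of α_a values (default 0 … 2 in steps of 0.25) and
maximizes the summed sequence log-likelihood over training sessions, with
dopamine from *all* instances feeding the history sums and only steps whose
label is in the modelled syllable set (default: the ten most frequent)
scored.

**Evaluation** is by simulation: the fitted model is rolled over each
held-out session teacher-forced — at every step it receives the session's
actual history (labels and dopamine) and samples one syllable from its
predictive distribution.  Simulated and actual per-syllable count series are
smoothed with a 50-step rolling mean and pooled into one Pearson correlation.
Control models rerun the identical pipeline with dopamine circularly
phase-shifted (random integer shift in [1, 1000]) or replaced by
unit-variance white noise, redrawn on every restart.  Note one property of
this design: a zero-gain model's simulated counts anticorrelate slightly with
the actual counts through the shared no-self-transition constraint, so the
control baseline sits a little below zero rather than at it; the model-vs-
control comparison is unaffected because both arms share the constraint.

**Exogenous dopamine ("extra DA").** For closed-loop stimulation sessions the
dopamine on each stimulated target instance is replaced by the catch-trial
mean plus a candidate offset, and the stimulation-session likelihood is
profiled over offsets; the argmax estimates the exogenously added dopamine in
z-units.

## The synthetic-session generator

Sessions are generated *from the decoding model itself*, mixed with a
first-order Markov prior: next-syllable logits are log base-transition
probabilities (diagonal zero ⇒ no self-transitions) plus the decoding-model
exponent evaluated with the true couplings.  Every instance draws its
dopamine amplitude from a per-syllable normal distribution.  Defaults:

* **K = 10 syllables**, base transitions drawn from a per-row symmetric
  Dirichlet (diagonal removed, renormalized).
* **Dopamine amplitudes** N(μ_i, 1) with μ_i spanning −1 … +1 z: amplitudes
  are generated directly on the z-scored-peak scale the downstream models
  consume, which makes the raw fluorescence scale a free rendering choice.
  Photometry-chain validation instead uses a positive regime
  (μ ≈ 1.2 … 3.0 z, σ = 0.8) matching the observed spontaneous transient
  amplitude of about 2.1 ± 0.8 z, because a windowed-max peak extractor
  cannot register negative-going transients.
* **Durations** log-normal with median 400 ms and log-s.d. 0.88, the
  dispersion implied by a reported spread of roughly 400 ± 636 ms
  (solve sd² = m² e^{σ²}(e^{σ²} − 1)).
* **Couplings** α_a = 1, α_b = 1, τ_a = 100, τ_b = 10, window 250.

**Fluorescence rendering.**  signal = bleach(t) · (1 + transients +
artifacts) + noise;  reference = gain · bleach(t) · (1 + artifacts) + offset
+ independent noise.  Transients are bi-exponential (rise 67 ms, decay
100 ms), unit-peak-normalized, scaled by amplitude × 1% ΔF/F per z, and
locked to syllable onset so the kernel peak (~80 ms after onset) falls inside
the 300-ms extraction window — the window is only meaningful if the dopamine
rise follows onset.  Artifacts are Poisson-timed biphasic bumps (~0.4 s wide,
2% ΔF/F) shared by both channels; they are written as fractional modulations
of the bleaching baseline in both channels so the two ΔF/F series see the
same artifact up to the gain/offset the robust fit estimates.  Defaults
(noise 0.1% ΔF/F per frame, artifact rate 0.02 Hz, bleach τ 2400 s) model a
*typical included* recording: synthetic sessions pass the amplitude gate with
signal–reference correlation ≈ 0.2–0.3, comfortably inside the 0.6 rejection
threshold, rather than at its edge.

**Kinematics** are piecewise per-syllable velocity templates plus smoothed
noise; acceleration is the velocity derivative.  They carry no dopamine
coupling, which is what makes the "sequence effect without movement effect"
control meaningful.

**Closed-loop stimulation** follows the three-day schedule: two baseline, two
stimulation, two post sessions.  During stimulation sessions each target
detection is stimulated with probability 0.75, and stimulated instances carry
`extra_da` additional z-units *before sequence generation continues*, so the
planted reinforcement propagates through the usage coupling exactly as the
decoding model assumes.

What the generator does **not** emulate: pose dynamics and real syllable
identities, session-scale behavioural nonstationarities (fatigue,
habituation), sensor kinetics variability, hemodynamic or pH confounds
beyond a generic shared artifact, and any dopamine autocorrelation beyond
what the couplings induce.  Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes, at realistic noise — not that
real recordings satisfy those assumptions.

## Photometry preprocessing

1. ΔF/F0 with F0 the 10th percentile in a 5-s sliding window (centred,
   edge-truncated), both channels.
2. Active referencing: reference low-passed (2nd-order Butterworth, 3 Hz,
   zero-phase forward–backward), robustly fit to the signal by RANSAC OLS
   (residual threshold 1 median absolute deviation of the filtered
   reference, 100 trials, fixed sub-seed), then subtracted.
3. Sliding z-score in a 20-s centred window (forced odd so centring is
   exactly symmetric), single-sample step; zero within-window s.d. emits 0
   with a warning.
4. QC: include a session iff max %ΔF/F0 > 1.5 *and* signal–reference Pearson
   r < 0.6.
5. Transient detection: local maxima above a z threshold (default 2; there is no
   canonical published value, so it is exposed as configuration) separated by ≥ 167 ms
   (5 frames).

Amplitude fidelity of the chain is validated on resolvable-transient
sessions (median duration 700 ms): rank correlation of extracted vs injected
amplitudes ≥ 0.9 at default noise.  At the default 400-ms duration
distribution ~40% of instances are shorter than the 300-ms peak window, so
neighbouring transients share windows and the rank correlation falls to
≈ 0.55 — an intrinsic limit of windowed-max extraction on overlapping
transients, not of the referencing or normalization.

## Syllable–dopamine statistics

* **Peak table**: one row per instance; peak = max z over frames
  [onset, onset + 9] (10 samples at 30 Hz, onset inclusive); per-session and
  per-mouse-per-syllable z-scored peak columns.
* **Expanding-bin correlations**: the outcome (own-syllable counts, velocity,
  dopamine autocorrelation) is aggregated over the *following n* syllables
  (n = 5 … 400, index instance excluded).  Correlations are computed within
  syllable and averaged across syllables — static cross-syllable dopamine
  level differences would otherwise produce a horizon-independent
  correlation that carries no timescale.  Sequence-randomness mode bins each
  syllable's peaks into 20 equal-width amplitude bins (per-syllable min–max
  range), pools outgoing transitions over the following n syllables per bin,
  and correlates conditional entropy with the bin level.  All curves are
  computed within five equal-length session segments and averaged, and
  z-scored against dopamine shuffles (circular shift within session by
  default, preserving autocorrelation; full permutation available).
* **Decay fits**: a·exp(−n/τ) + c by least squares over 1,000 bootstrap
  resamples — segments (rows of the curve) are resampled when available,
  residuals otherwise; constant curves are flagged non-identifiable, and a
  resample failure rate above 20% is an error.  One caveat this package
  documents rather than hides: for a causal exponential coupling the
  expanding-window correlation *rises* to a peak near n ≈ 1.25 τ before
  decaying like 1/√n, so the fitted τ tracks the rise and lands near τ/3 of
  the planted coupling timescale.  τ estimates from this procedure order
  timescales correctly (τ_counts > τ_entropy) but are not calibrated absolute
  values.
* **Cross-correlation of dopamine and usage**: per syllable, 3-minute binned
  mean peak vs binned counts at integer window lags, both standardized
  within syllable across windows before pooling; shuffle-z-scored.
* **Huber regression** (scikit-learn `HuberRegressor`) with five-fold
  cross-validation repeated 100 times; the p-value is the fraction of
  shuffled-outcome refits whose held-out r reaches the observed one
  (with the +1 small-sample correction).
* **Movement initiations**: z-score → 50-point boxcar → first difference
  scaled to per-second units → cube → `find_peaks(height=1, width=1,
  prominence=1)`.  The per-second scaling makes the stated height threshold
  attainable for step-like onsets.
* **Endogenous-dopamine influence**: s.d. across bin sizes of the
  shuffle-z-scored correlation curve, per mouse or per mouse × syllable
  (per-syllable curves restrict the correlation pairs to that syllable while
  the forward windows still run over the full sequence).

## Encoding models

* **Binned model**: features (counts, entropy, velocity) per
  (mouse, syllable, bin size ∈ {5, 10, 25, 50, 100, 200, 300, 400, 800,
  1600}), z-scored within mouse, ZCA-whitened (W = C^{−1/2}, symmetric;
  rank-deficient covariances ridge-regularized with a warning), then Bayesian
  linear regression.  The posterior uses scikit-learn's `BayesianRidge`
  (normal prior on coefficients, Gamma hyperpriors) as an analytic
  approximation; the contract is posterior means and intervals, not sampler
  identity.  Separate models per bin size quantify the temporal relationship;
  feature subsets are evaluated at their best bin sizes (kinematics/entropy
  10 steps, counts 100).
* **Kernel model**: dopamine at frame t is the sum over features of the
  feature convolved with a learned kernel over lags −2 … +2 s (121 taps at
  30 Hz).  Implemented as a lagged design matrix fit with a Huber loss and
  mild L2 (default 1e-4, for conditioning); features are standardized within
  session (recorded in provenance); the target is smoothed with a 60-sample
  boxcar; evaluation is twofold cross-validation by session.

## Q-learning agents

States are syllables, actions are transitions, reward is the dopamine peak
of the entered syllable.  The Q-table starts uniform off-diagonal (default
1.0; any constant is policy-equivalent by softmax shift-invariance, though
not update-equivalent) with the diagonal fixed at 0.  Two reward readings:
the standard temporal-difference update (``reward``) and the observed
dopamine substituting the whole bracketed error term (``rpe``:
Q ← Q + α·da).  The policy is a softmax over non-self actions.

* **Action attribution**: the data's actual next syllable is both the scored
  action and the update target — the likelihood of observed actions is the
  only coherent fitting target when the agent is fed recorded sessions.  A
  free-running mode (agent selects actions, reward drawn from per-action
  empirical dopamine pools) preserves the alternative reading.
* **Dynamic temperature**: τ(t) = ν·exp(−Δt/τ_decay) + τ_baseline, Δt the
  steps since the reward last crossed λ (crossings reset Δt).  The decaying
  kick is the only reading consistent with a *brief* increase in choice
  variability; ν = 0 reduces the dynamic agent to the static one exactly.
* **Evaluation**: each row of the Q-table and of the empirical transition
  matrix is z-scored over its off-diagonal entries, flattened, and
  correlated; significance is against agents refit with time-shuffled
  dopamine (100 shuffles).  Grid search (defaults α ∈ {0.01, 0.05, 0.1,
  0.3}, γ ∈ {0, 0.5, 0.9} — reward mode only, τ ∈ {0.1, 0.5, 1, 2}) selects
  parameters by held-out likelihood; mode comparison z-scores held-out
  log-likelihoods against between-session dopamine shuffles (n = 10) over 50
  session bootstraps.

## Opto-reinforcement quantification

Excess target counts: target occurrences per non-overlapping 30-s bin,
cumulative sum, minus the mean of the baseline sessions' cumulative sums.
Learners are mice whose mean excess strictly exceeds the maximum among
no-opsin controls.  Temporal adjacency uses each non-target syllable's mean
signed syllable-step distance to the *nearest* target instance (within ±10;
the nearest-instance reading bounds offsets), frequency-weighted within
offset bins; velocity similarity bins count changes by the syllable's
instance-z-scored velocity difference from the target; both reuse the 30-s
cumulative machinery for per-syllable count changes.  Post-stimulation
dynamics are five-syllable-bin metrics with the pre-onset value subtracted,
z-scored per bin against catch trials.  Learning scores are log2 fold changes
of stimulation- vs baseline-day counts, z-scored against all non-stimulation
day pairs, with add-one smoothing (flagged) for zero counts.

## Problem sizes

The validation suite runs the decoding-dominance comparison at 20 sessions ×
5,000 transitions × 50 restarts; parameter-recovery ensembles use 20 seeds of
4–6 sessions × 2,000–3,000 transitions; photometry validation uses ~800-step
sessions; RL shuffle tests use 4 sessions × 2,500 transitions with 100
shuffles.  These sizes give stable statistics (the dominance comparison is
deterministic at U = 2,500 across seeds) while keeping the full suite in the
minutes range on one CPU.
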