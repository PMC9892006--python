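# dopaseq

Analysis toolkit linking **sub-second behavioural syllables** to **striatal
dopamine fluctuations** measured by fiber photometry.

Spontaneous rodent behaviour decomposes into brief (~400 ms), re-used motifs
("syllables").  Dopamine sensors such as dLight report fast transients in the
dorsolateral striatum, and the peak fluorescence in the 300 ms after a
syllable's onset behaves like a moment-to-moment teaching signal: syllables
paired with more dopamine are used more over the following ~100 syllables,
and recent global dopamine transiently changes how random the next choice is
(~10-syllable timescale).  `dopaseq` implements the full computational chain
for testing those ideas — for systems-neuroscience groups working with
syllable-segmented behaviour plus photometry, and for anyone who wants a
self-contained, simulation-validated reference implementation.

## What's inside

| module | contents |
|---|---|
| `dopaseq.generate` | synthetic sessions with planted couplings: Markov syllable sequences (no self-transitions), per-instance dopamine amplitudes, bi-exponential fluorescence rendering (rise 67 ms, decay 100 ms) on a bleaching baseline with a shared-artifact reference channel, kinematics, closed-loop stimulation (75% delivery) |
| `dopaseq.photometry` | ΔF/F0 (sliding 10th percentile, 5 s), active referencing (3 Hz Butterworth + RANSAC fit + subtraction), 20-s sliding z-score, QC gates, transient detection |
| `dopaseq.stats` | syllable-peak tables, expanding-bin dopamine–usage/entropy/velocity correlations with shuffle z-scoring, exponential decay fits, usage cross-correlation, Huber regression with repeated CV, movement initiations, kinematic partialing, endogenous-dopamine influence index |
| `dopaseq.encoding` | ZCA whitening + Bayesian linear regression of dopamine on binned behavioural features; convolution-kernel model predicting instantaneous dopamine (Huber loss, ±2 s kernels) |
| `dopaseq.decoding` | the dopamine-dependent sequence model (below): likelihood, grid fitting, cross-validated simulation tests, phase-shift/noise controls, the "extra DA" estimator for opto sessions |
| `dopaseq.rl` | Q-learning over syllable transitions with dopamine as reward or as the full prediction-error term, static and dynamic-temperature variants, shuffle-null evaluation against empirical transition matrices |
| `dopaseq.opto` | closed-loop stimulation effects: cumulative excess target counts, learner classification, temporal/velocity specificity, post-stimulation dynamics, learning scores |

## The core model

The decoding model predicts the next syllable from past dopamine:

```
P(s_t = i) ∝ exp( α_a Σ_{n=1..250} da_{t−n} e^{−n/τ_a} 1[s_{t−n} = i]
                  ─────────────────────────────────────────────────── )
                  α_b Σ_{n=1..250} da_{t−n} e^{−n/τ_b}
```

with `da_t` the syllable-associated dopamine peak (z-scored per session),
τ_a = 100 and τ_b = 10 syllable steps, α_b fixed and only the usage gain α_a
fitted (grid likelihood).  Fitted models are judged by the held-out Pearson
correlation between 50-step-smoothed simulated and actual syllable counts,
against controls with phase-shifted or white-noise dopamine.  See
`docs/methods.md` for every modelling decision and caveat.

## Worked example

```python
import numpy as np
from dopaseq import make_generative_params, simulate_session, DopamineSequenceModel

T = np.ones((10, 10)) / 9                  # uniform non-self Markov prior
np.fill_diagonal(T, 0.0)
params = make_generative_params(10, seed=0, base_transitions=T, alpha_a_true=1.0)
sessions = [simulate_session(params, n_steps=3000, seed=k, render=False)
            for k in range(5)]

model = DopamineSequenceModel(sessions)
result = model.fit_cv(np.arange(0, 2.01, 0.25), n_restarts=10, seed=0)
print(result.summary())
```

prints

```
Dopamine-dependent sequence decoding model
==========================================
sessions: 5   modelled syllables: 10
alpha_a (fitted): 1
alpha_b (fixed):  1   tau_a: 100   tau_b: 10   window: 250
log-likelihood at alpha_a: -8287.19
held-out counts r: median 0.985 over 10 restarts
```

The grid fit recovers the planted usage gain (α_a = 1.0) exactly, and the
fitted model's simulations track held-out syllable usage (median r ≈ 0.99 on
these strongly coupled synthetic sessions; on noisy real data this number is
far smaller).  Replacing dopamine with white noise
(`dopaseq.decoding.control_models(sessions, variant="noise", ...)`) collapses
the held-out correlation to chance.

A thin CLI wraps the main pipeline stages
(`dopaseq simulate|preprocess|stats|decode|rl|opto`); sessions travel as
plain-text directories (`syllables.tsv`, `photometry.tsv`, ...).

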