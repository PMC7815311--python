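# Methods

This note documents the models, estimators and simulators in `itdlab`, the
numerical choices behind them, and what the synthetic-data generators do and
do not capture about real behavioral and electrophysiological data.

## Stimulus construction (`itdlab.stimgen`)

Electric stimuli are binaural biphasic pulse trains: each pulse is a positive
phase, a zero gap and a negative phase, specified in *integer samples* at the
stimulator rate. The defaults (3/2/3 samples at 48 828.125 Hz) give phase
durations of 61.44 µs / 40.96 µs / 61.44 µs, the clinical-style duty cycle.
Acoustic stimuli are trains of single-sample unit impulses ("digital delta
clicks") at 48 000 Hz; the physical tube resonance that colors real clicks is
deliberately not modeled, since it is a property of the delivery rig and has
no bearing on ITD analysis.

ITDs are realized by delaying one channel by an integer number of samples —
no fractional-delay filtering — so the achievable grid is one sample period:
20.48 µs (electric) or 20.83 µs (acoustic). `quantize_itd` rounds a requested
ITD to the nearest sample (half-sample requests round away from zero) and
reports the realized value; quantizing a realized ITD is idempotent. The sign
convention is a single signed axis, arrival-left minus arrival-right, with
negative ITD = left ear leading; positive `itd_us` delays the right channel.
The ILD audit is `20·log10(rms(left)/rms(right))` dB (positive = left
louder); because an integer-sample shift permutes samples, equal-amplitude
ITD stimuli have exactly 0 dB ILD.

Pulse trains start with the positive phase at the beginning of each pulse
epoch; epoch starts are `round(i·fs/rate)`. The pulse count is
`floor(rate·duration)`, i.e. a fractional trailing pulse is dropped. Specs
whose ITD meets or exceeds one inter-pulse interval are rejected.

## Behavioral simulator (`itdlab.behavior_sim`)

Choices in the two-alternative forced-choice (2AFC) lateralization task are
Bernoulli draws from the four-parameter probit model

    p_R(ITD) = Φ(ITD·α + β)·(1 − γ) + γ/2 + δ

with ITD in ms, sensitivity α (1/ms), ear bias β, lapse rate γ ∈ [0, 1] and
spout bias δ. Values of δ large enough to push p_R outside [0, 1] are clamped
and flagged. The task structure mirrors rodent training practice: after each
correct trial a new ITD is drawn uniformly from the stimulus set; after each
incorrect trial the same ITD repeats as a *correction trial* (repeating until
correct, or until an optional `max_corrections` cap re-randomizes). Positive
ITD (right ear leading) is reinforced at the right spout; zero-ITD trials are
rewarded at a uniformly random side so they are uninformative about bias in
expectation. Correction trials carry a flag and are excluded from analysis by
`filter_analysis_trials`.

The default ITD set is {0, ±25, ±50, ±75, ±100, ±125, ±150, ±160} µs: a
25 µs grid with ±160 µs endpoints, fully configurable since hardware
quantization (20.48 / 20.83 µs steps) makes any nominal grid approximate.
Session logistics (timeouts, water rewards, session boundaries, learning
across training days) are not simulated — analysis consumes only the trial
log, and the constant-γ lapse model stands in for any slow motivational
dynamics. Passing recovery tests therefore shows the estimator is correct
*for data generated by the model it fits*, not that real rats lack
history-dependent structure.

## Psychometric fitting (`itdlab.psychometrics`)

The fit maximizes the Bernoulli likelihood of non-correction trials.
Internally trials are aggregated to per-ITD-level binomial counts — the
log-likelihood sum is identical, and the fit is consequently invariant to
trial order. Optimization is multi-start L-BFGS-B (default 6 starts: one from
a probit regression of per-level proportions, the rest jittered from it with
a seeded generator) under box constraints α ∈ [0, 300]/ms (one 20.48 µs
hardware step can span the whole curve at the upper bound), β ∈ [−5, 5],
γ ∈ [0, 0.5], δ ∈ [−0.3, 0.3]. Likelihood probabilities are clamped to
[1e−9, 1 − 1e−9] with a warning. Fits at a box bound, or on the flat
near-zero-deviance ridge produced by perfectly separable data, are flagged
`at_boundary`.

Summaries:

- **Slope**: φ(0)·α·(1 − γ) in %/µs (the per-ms value divided by 10), with
  φ(0) ≈ 0.3989 the standard normal density at zero. This is the
  conventional summary and *ignores β*; the true derivative of the fitted
  curve at ITD = 0 is φ(β)·α·(1 − γ), available via `exact=True`. The two
  coincide when β = 0.
- **75 %-correct threshold**: the mean of |ITD| at the 25 % and 75 %
  crossings of the fitted curve, found by root bracketing on ±10 ms with
  1e−4 ms tolerance. When γ or δ cap the curve short of a level the
  threshold is undefined (returned as `None`, not an exception). For
  β = γ = δ = 0 it reduces to Φ⁻¹(0.75)/α ≈ 53.8 µs at α = 12.53/ms.
- **Wilson 95 % score intervals** per ITD level (statsmodels implementation;
  tests verify it against a direct score-equation root-finder).
- **Group comparison**: Wilcoxon signed-rank (paired, default) with zero
  differences dropped — Wilcoxon's original convention — and exact p-values
  for n ≤ 25 tie-free samples (at n = 5 the exact two-sided p-values live on
  a 1/32 lattice); Mann-Whitney rank-sum for unpaired data. All-zero
  differences return p = 1.

## Neural simulator (`itdlab.neuro_sim`)

The generator renders an ITD-tuning experiment as a raw extracellular trace:
white Gaussian noise, plus biphasic spike waveforms (1.2 ms
derivative-of-Gaussian template, peak amplitude `snr·noise_sd`, ±20 %
amplitude jitter) at times drawn from an inhomogeneous Poisson process, plus
a 2.5 ms damped-oscillation transient after every stimulus onset that mimics
electrical stimulus artifact and exercises artifact blanking downstream.
Firing rate is `base_rate_hz` (default 20 Hz) everywhere except the response
window of each stimulus — 3–15 ms post-onset for `onset` responses, 3–80 ms
for `sustained` — where it follows a parametric tuning shape (`peak`,
`sigmoid`, `trough`, `multipeak`; Gaussian bump, logistic, inverted bump,
raised cosine) interpolating between `driven_rate_hz·(1 − depth)` and
`driven_rate_hz` (default 150 Hz). `depth = 0` makes the rate
ITD-independent, the null condition.

The default trial schedule is the standard recording design: 17 ITD levels
from −163.84 to +163.84 µs in 20.48 µs steps, 30 repeats per level in
pseudo-random order (a full shuffle by default; repeat-blocked order
available), 500 ms inter-stimulus interval — 510 events, so a one-way ANOVA
per site has 16 between and 493 within degrees of freedom, 29 repeat df per
level. The default sample rate is 24 414.0625 Hz. Ground truth (tuning
function and spike times) is retained in the container.

Not modeled: biophysical spike shapes and bursting, 1/f and line noise,
electrode drift, spike sorting, correlated multi-channel geometry (optional
extra channels are independent), and the physics of the electrical artifact
beyond a placeholder transient. The simulator's job is to give the analysis
chain a known answer, not to be a tissue model.

## Neural quantification (`itdlab.neurometrics`)

**AMUA.** The analog multi-unit activity chain band-passes the trace to the
spike band (300 Hz–6 kHz), takes the absolute value, and low-passes at
6 kHz, all at the native rate with no resampling. Filters are 4th-order
Butterworth applied forward-backward (zero-phase), which preserves window
alignment; the chain is positively homogeneous, so AMUA-based statistics are
gain-invariant. Band edges at or above Nyquist are clipped to 0.99·Nyquist
with a warning.

**Spike detection.** Threshold crossings of the band-passed signal at
`k_sd = 4` standard deviations (plain SD, optionally estimated excluding
artifact spans), either polarity, with a 1 ms refractory merge. Used for
raster-style displays and cross-checks; tuning quantification uses AMUA.

**Response matrix.** Per stimulus, the mean AMUA (or spike count) in the
response window 3–80 ms post-onset, with the first 2.5 ms artifact span
blanked (the blank lies before the 3 ms window start, so it only matters for
earlier custom windows, where the effective start is `max(start, blank)`);
baseline is 300–500 ms post-onset. Events whose windows fall outside the
trace are dropped with a warning, and ragged designs are subsampled to the
common repeat count (the ANOVA itself also accepts ragged group lists using
the general unbalanced formulas).

**Tuning curves** are per-level means minus the grand baseline mean,
normalized by the maximum baseline-corrected mean (peak = 1 when any level
exceeds baseline; otherwise normalized by |max| and flagged), with SEM per
level.

**STVR.** The signal-to-total variance ratio of a one-way ANOVA grouped by
ITD: `STVR = SS_group / SS_total ∈ [0, 1]`, the fraction of trial-to-trial
response variance explained by ITD, with
`F = (SS_group/df_b)/(SS_within/df_w)` and the parametric p-value from the F
distribution; a site counts as significantly tuned when p ≤ 0.01. STVR is
invariant under affine transforms of the responses. Under exchangeability
its null mean is (k−1)/(N−1) = 16/509 ≈ 0.031 for the 17×30 design. A
permutation companion (`stvr_null_distribution`) recomputes STVR under label
shuffles, with p = (1 + #{null ≥ obs})/(n_perm + 1), and agrees with the
parametric p on Gaussian data.

## Problem sizes

Simulation-backed checks use: 54 behavioral sessions of 3000 analysis trials
(α ∈ {5, 12.5, 25}/ms × γ ∈ {0, 0.1}, 9 replicates) for parameter recovery;
5000 null 17×30 matrices for type-I calibration; 100 seeded recordings per
depth condition (sigmoid tuning, SNR 10) for end-to-end recovery; 100 random
unbalanced matrices for the brute-force ANOVA cross-check. These sizes make
every stochastic check decisive (binomial error well inside the asserted
margins) while keeping the whole suite a few minutes of compute.

## Known limitations

- The behavioral simulator has no learning, motivation or history effects
  beyond the correction-trial rule; γ is constant.
- Tuning-shape classification (peak vs multi-peak, etc.) is not implemented;
  shapes exist only as generative options.
- No bootstrap or Bayesian uncertainty on psychometric parameters; the
  Wilson intervals quantify per-level proportion uncertainty only.
- The slope summary inherits the φ(0) convention; for strongly biased fits
  (|β| large) it overstates the true slope at ITD = 0 — use `exact=True` to
  quantify the difference.
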