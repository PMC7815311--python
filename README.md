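# itdlab

Tools for quantifying sensitivity to interaural time differences (ITDs) in
bilateral cochlear-implant experiments: microsecond-precise binaural
stimulus construction, simulation and maximum-likelihood analysis of
two-alternative forced-choice (2AFC) lateralization behavior, and
quantification of neural ITD tuning from extracellular recordings.

## Who this is for

Auditory neuroscientists and psychophysicists who need a tested, scriptable
implementation of the standard analysis chain for binaural ITD experiments —
from the stimulus timing arithmetic (integer-sample ITD quantization, duty
cycles, residual-ILD audits) through psychometric curve fitting to the
signal-to-total variance ratio (STVR) used to score neural tuning — together
with synthetic-data generators so every stage can be validated end to end
with known ground truth, no animal data required.

## The models at the core

**Behavior.** The probability of a "right" choice is a four-parameter probit
psychometric function

    p_R(ITD) = Φ(ITD·α + β)·(1 − γ) + γ/2 + δ

with ITD in ms (arrival-left − arrival-right; negative = left ear leading),
sensitivity α (1/ms), ear bias β, lapse rate γ and spout bias δ, fitted by
maximum likelihood to non-correction trials. Sensitivity is summarized by
the slope at ITD = 0, `φ(0)·α·(1 − γ)` (reported in % "right" per µs), and
by the 75%-correct threshold, the mean |ITD| at which the fitted curve
crosses 25% and 75%.

**Neural tuning.** Raw traces are reduced to analog multi-unit activity
(AMUA: band-pass 300 Hz–6 kHz → rectify → low-pass 6 kHz), averaged over a
3–80 ms post-onset response window per trial, grouped by ITD, and scored by
the STVR of a one-way ANOVA:

    STVR = SS_group / SS_total ∈ [0, 1],

the fraction of trial-to-trial response variance explained by ITD, with
significance at p ≤ 0.01 from the F test.

## Worked example

```python
import numpy as np
from itdlab import behavior_sim, psychometrics, neuro_sim, neurometrics

# --- behavior: simulate a session, then fit it blind -----------------------
truth = behavior_sim.GroundTruthModel(alpha_per_ms=12.53, gamma=0.05)
log = behavior_sim.simulate_session(truth, n_trials=3000, seed=42, count="analysis")
fit, report = psychometrics.fit_psychometric(log)
print(f"alpha = {fit.alpha_per_ms:.2f}/ms, slope = {report.slope_pct_per_us:.3f} %/us, "
      f"threshold75 = {report.threshold75_us:.1f} us")

# --- neural: simulate a tuned site, then score it --------------------------
tuning = neuro_sim.TuningFunction(shape="sigmoid", depth=0.8)
schedule = neuro_sim.make_trial_schedule(seed=1)      # 17 ITDs x 30 repeats
rec = neuro_sim.simulate_recording(tuning, schedule, snr=10.0, seed=1)
matrix = neurometrics.build_response_matrix(rec)       # mean AMUA per trial
res = neurometrics.compute_stvr(matrix)
print(f"STVR = {res.stvr:.3f}, F({res.df_between},{res.df_within}) = {res.f_stat:.1f}, "
      f"p = {res.p_value:.2e}, significant = {res.significant}")
```

Output:

```
alpha = 12.50/ms, slope = 0.480 %/us, threshold75 = 56.4 us
STVR = 0.501, F(16,493) = 30.9, p = 4.36e-64, significant = True
```

The fitted sensitivity (12.50/ms vs the generative 12.53/ms) and slope
(0.480 %/µs vs the analytic 0.475 %/µs for these parameters) show parameter
recovery from a single 3000-trial session; the 75% threshold sits near the
closed-form Φ⁻¹(0.75)/α. On the neural side, a site whose firing is strongly
ITD-modulated (depth 0.8 at SNR 10) yields an STVR of 0.50 — ITD explains
half the trial-to-trial response variance — and is flagged significantly
tuned; an untuned site (depth 0) lands near the null expectation
(k−1)/(N−1) ≈ 0.031 and is not.

A command-line interface mirrors the library
(`itdlab stimgen / simulate-behavior / fit / simulate-neuro / amua / stvr /
pipeline / selftest`); see `itdlab --help`.

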