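# Methods

## The model

`ned_mcgurk` implements the noisy encoding of disparity (NED) account of
McGurk fusion. Each McGurk stimulus *i* carries an intrinsic audiovisual
disparity *D<sub>i</sub>*; on every presentation, participant *j* encodes
that disparity with Gaussian sensory noise, X ~ N(D<sub>i</sub>,
σ<sub>j</sub>), and reports the fusion percept whenever the encoded
disparity falls below their personal integration threshold
*T<sub>j</sub>*. The long-run fusion probability is therefore the normal
CDF

P(fusion | i, j) = Φ((T<sub>j</sub> − D<sub>i</sub>) / σ<sub>j</sub>).

The model is descriptive rather than mechanistic: it does not explain
*why* auditory "ba" + visual "ga" fuses to "da", only how fusion rates
vary across stimuli (one parameter each) and participants (two
parameters each).

## Parameter scale and identifiability

The fusion probability depends only on (T − D)/σ, so adding a constant to
every D and T, or rescaling all three parameter sets together, leaves
every prediction unchanged. We anchor the scale with box constraints:
D, T ∈ [0, 1] and σ ∈ [0.01, 2]. The unit interval matches the reading
of T as a prior probability of integration. Because the anchor is a
convention, all correctness tests compare *predictions* (and parameter
*rankings*), never raw parameter values.

## Fitting

The objective is the mean absolute error (MAE) between predicted
probabilities and observed per-cell fusion proportions over non-missing
cells — the literal cell-level reading of fitting "each participant for
each stimulus". Stimulus-level and participant-level MAEs (absolute
differences of stimulus/participant means) are reporting summaries, not
objectives. Cells observed at exactly 0 or 1 are used as-is: MAE, unlike
a log-likelihood, is finite there.

The optimizer is deterministic block-coordinate descent:

1. **D block.** Given (T, σ), each D<sub>i</sub> affects only column
   *i*, so all stimulus subproblems are solved simultaneously by a
   13-point bracketing grid over the box followed by 40 vectorized
   golden-section iterations.
2. **T block, σ block.** Given D, each participant's coordinates affect
   only their row; same grid-plus-golden-section scheme, vectorized over
   participants.
3. **Polish.** Alternating scalar searches can stall at nonsmooth points
   of the MAE surface where T and σ couple, so after the sweeps converge
   we re-solve each participant's (T, σ) pair jointly with bounded
   Nelder–Mead, interleaved with D re-solves, until the objective
   improves by less than the tolerance. On noiseless tables this drives
   the objective from ~10⁻³ to ~10⁻¹⁰.

Every candidate set includes the incumbent, so the recorded objective
trace is non-increasing by construction. The outer loop stops when a
full sweep improves the objective by < 1e-6 (cap: 500 sweeps, then 50
polish rounds), and the fit is flagged unconverged if the cap is hit.
Initialization is a probit-link moment match (σ = 0.3) to the row and
column means — data-driven but deterministic. There is no randomness
anywhere in the fit, so refits are bit-identical.

Degenerate input (all cells identical) produces a warning about weak
identifiability rather than an error.

## Scoring raw responses

Responses typed in Latin letters, hiragana, or katakana are
NFKC-normalized, casefolded, stripped of punctuation (including the
long-vowel mark and small tsu), and transliterated by longest-prefix
lookup in a static kana table covering the percept syllables and common
distractors. Anything unmapped is preserved and lands in "other";
free-text fuzzy matching is deliberately out of scope. Trials that
normalize to the empty string are flagged invalid, logged, and excluded
from both fusion proportions and congruent-accuracy denominators.

Scoring assigns each response to auditory / visual / fusion / other
(fusion = "da", "ta", "tha" and their doublings). Double-syllable
stimuli are split into two morae by greedy longest-prefix match against
the stimulus's known syllable units, each worth half a point ("bada" →
0.5 auditory + 0.5 fusion); a response that does not split into exactly
two known units is scored as a whole unit, so three-mora or partly
unknown strings route to "other". The fusion-proportion denominator
includes "other" trials.

Participants below 90% congruent accuracy (strict: 0.899 fails, 0.90
passes) are excluded with a logged reason; an empty surviving set
aborts.

## Hold-out generalization

For each participant, disparities are fit once on the table without that
participant's row (cached per participant, not per cell — the row never
enters, so per-cell refits would change nothing but runtime). Then, per
held-out stimulus, the participant's (T, σ) are re-estimated from their
remaining cells with D frozen, and the held-out cell is predicted.
Leakage-freedom is asserted by mutation tests: corrupting the held-out
cell, or the whole row during the disparity stage, cannot move the
prediction. Because the study's single hold-out number is ambiguous
between a mean over cells and over participants, the report emits both.

## Stepwise-BIC regression

Covariate models start from the full main-effects model, consider every
single-term deletion and re-addition, move only when BIC strictly
decreases, never form interactions, and floor at the intercept-only
model. Ties are broken by the fixed candidate order (deletions first).
Categorical predictors enter as dummy blocks; education is collapsed to
an ordinal scale (high school < professional/bachelor < higher), since
the source coding is not recorded. BIC is computed from the Gaussian
likelihood with the residual sum of squares floored at 1e-12 of the
total sum of squares: exactly noiseless responses otherwise make
log-likelihood differences between perfect fits pure rounding noise.
Selection matches R's `step(direction="both", k=log(n))` exactly on
shared datasets (tested via Rscript).

A known property of this procedure, verified both here and with the R
oracle: with four candidate noise predictors at n = 80, BIC admits a
predictor whose incremental r² exceeds 1 − 80^(−1/80) ≈ 0.053 (a
per-predictor type-I rate of ≈ 3.9%), so the intercept-only model is
retained on only ≈ 86% of pure-noise datasets, not ≈ 95% as one might
hope from BIC's consistency at large n.

## Synthetic cohorts

The generator draws trials from the model's own generative story, so
recovered parameters can be compared against known truth. Defaults
mirror the emulated study design: 80 participants × 15 McGurk stimuli
(12 voiced AbaVga, 3 unvoiced ApaVka, four of them doubled) × 10
repetitions, plus 90 congruent trials per participant (30 stimuli × 3).
Population distributions are not recorded in the source study; the
defaults — D ~ U(0.05, 0.95), T ~ Beta(2, 5) on [0, 1] (skewed low,
echoing the ~23% mean fusion), σ ~ U(0.05, 0.4) — were chosen once as
plausible for this literature and are fully overridable.

The *study-like* configuration (`study_cohort_config`) additionally
stratifies disparities by voicing class — voiced D ~ U(0.45, 0.85),
unvoiced D ~ U(0.05, 0.30) — calibrated a priori so the *expected* class
fusion means under the default T and σ populations equal the study's
printed 12% and 65% (which jointly imply its ~23% grand mean). It also
appends 21 high-lapse (0.35) participants to the 80 attentive ones
(lapse 0.02), emulating the study's 101 → 80 exclusion flow.

Congruent lapses substitute a uniformly drawn wrong syllable from
{ba, ga, pa, ka} minus the target, never a fusion token, so congruent
trials cannot contain illusory fusion reports. Demographic tables can be
generated with planted parameter–covariate associations (defaults: σ–age
slope 0.003 at R² 0.07; T–English slope −0.07 at R² 0.06) constructed by
inverting the simple-regression moments, emulating the study's two
reported demographic effects.

What the generator does **not** emulate: visual-only and "other"
response categories (the NED model predicts fusion vs auditory only),
response-time structure, stimulus-order effects, within-participant
attention drift, and any real articulatory variability behind the
disparities. Passing recovery tests therefore demonstrates that the
pipeline estimates the model's parameters correctly when the model is
true — not that the model is true of any real cohort.

## Problem sizes and numerical choices

Recovery and hold-out tests run at the study's own scale (80 × 15 × 10;
a full two-level hold-out takes ~2–3 minutes), with smaller cohorts
(10–30 participants) for unit-level properties. Golden-section
iterations (40) place coordinate minima far below the 1e-6 outer
tolerance; the quadrature check pins the CDF to 1e-8. Rank consistency
uses Spearman correlation with average-rank ties; participants with
zero variance across stimuli are excluded from it and logged.

## Known limitations

- MAE fitting has no likelihood, so no standard errors or posterior
  uncertainty for the parameters; the hold-out procedure is the only
  internal gauge of predictive uncertainty.
- Coordinate descent with polish is a local method; the multi-point
  bracketing grid and data-driven start make it reliable in practice
  (noiseless self-consistency to 1e-4 and better is tested), but global
  optimality is not guaranteed.
- The romanization table is a fixed inventory; free-form Japanese text
  outside it is scored "other" by design.
- Leave-whole-participant-out prediction is impossible in this model
  class: a new participant's (T, σ) must be estimated from at least two
  of their own cells.
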