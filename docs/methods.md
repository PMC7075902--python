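# Methods

`pavo2` simulates and analyses a two-cue probabilistic Pavlovian conditioning
study in which haemodynamic (tissue-oxygen, T_O2) signals are recorded from
nucleus accumbens (NAc) and orbitofrontal cortex (OFC) while rats learn cue
values, followed by an acute amphetamine challenge. Because no recordings are
deposited anywhere, the package ships a first-class synthetic-data generator
whose statistical structure matches what the analyses assume; every analysis
stage is validated by recovering that designed-in structure.

## Task model

A session presents 56 ten-second auditory cues, 28 per cue. CS_High is
rewarded on exactly 21/28 (75%) of its presentations and CS_Low on 7/28
(25%), with the outcome immediately at cue offset. Inter-trial intervals are
uniform on [30, 60] s (mean 45 s). Cue roles are counterbalanced over two
physical sounds (clicker/tone) across two groups. Nine training sessions are
followed by a tenth drug-challenge session (vehicle or amphetamine); session
nine doubles as the pre-drug baseline.

Reward proportions are enforced exactly per session rather than sampled
Bernoulli. This makes per-session reward counts a deterministic property of
the design, so the generator's design parameters can be checked exactly. The
ITI law is uniform because only its mean and range are constrained.

## Behavioural model family

Cue-period head-entry rates are modelled by Rescorla–Wagner variants. Value
of the presented cue updates as

    V <- V + alpha_eff * (r - V),      alpha_eff = alpha * beta_sound,

with `beta_tone = 1` fixed and `beta_clicker` a free salience multiplier
(`alpha_eff` clipped to (0, 1]); optional split learning rates use
`alpha_pos` on rewarded and `alpha_neg` on non-rewarded trials. V starts at 0
for both cues (naive animals) and carries across sessions. The predicted
rate is

    rate(t) = gain * V_cue(t) + k_term(sound) + baseline_term(t)

where `k_term` is unconditioned magazine responding (absent, shared `k`, or
cue-specific `k_clicker`/`k_tone`) and the baseline term is either the
trial's observed pre-cue rate with a fitted coefficient (`w_pre`) or a
recency-weighted smoother `b(t) = gamma*b(t-1) + (1-gamma)*pre_rate(t-1)`
with `b(1)` set to the first session's mean pre-cue rate.

Observed rates are Gaussian around the prediction with free `sigma`. The
likelihood is a modelling choice here: a Gaussian on continuous rates is the
simplest emission consistent with fitting head-entry counts as rates, and it
matches the generator's truncated-Gaussian emission. `gain` and `sigma`
count as free parameters everywhere, so the standard model has 3 parameters
(alpha, gain, sigma) and the full model (salience + cue-specific k + recency
baseline) has 7.

Models are compared by BIC = `n_params * ln(n_obs) + 2 * NLL`, `n_obs` being
the number of cue presentations fitted (56 per session). The distributed
grid holds the standard model, each single-component variant and the full
model (8 specs); all 2x2x3x3 flag combinations are constructible.

### Optimisation

`fit_model` runs bounded multi-start local search (L-BFGS-B, default 20
restarts from Latin-hypercube draws; bounds: alpha, gamma in (0.001, 0.999),
beta_clicker in (0.01, 10], k, gain, w_pre in [0, 20], sigma in (1e-3, 50)).
Because gain, k and w_pre enter the prediction linearly and sigma has a
closed-form MLE, each evaluation of the nonlinear parameters profiles them
out with bounded least squares (`scipy.optimize.lsq_linear`, BVLS); the
search therefore runs over only 1–4 dimensions but returns the joint maximum
over all parameters, all of which are reported and counted in BIC. Restarts
are deterministic given the seed; ties in BIC break toward fewer parameters,
then grid order.

## Tissue-oxygen generator

Traces are sums of haemodynamic impulse responses at the behavioural events
plus a linear drift and AR(1) noise, sampled at 1 Hz. The kernel is a
gamma-shaped HRF with unit peak at 4 s and FWHM 4 s (25-s support): rodent
haemodynamics peak faster than the canonical human response, and no specific
shape is mandated by the data being emulated, only smooth low-pass temporal
mixing. Event amplitudes come from the agent's latents:

- cue onset: `w_cue_value * V(t)`,
- outcome: `w_outcome * r + w_value_at_outcome * V + w_unsigned_pe * |r - V|`.

Region presets encode the signatures the analyses are designed to detect —
NAc: (1, 1, −1, 0), i.e. outcome amplitude `r − V`, a signed reward
prediction error; OFC: (1, 0.5, +1, 1.5), i.e. unsigned-PE (surprise)
dominated with a *positive* value contribution at outcome. Noise sd 0.3 with
AR(1) coefficient 0.8 yields per-trial AUC signal-to-noise near 1, so single
trials are noisy but ~500-trial regressions are decisive, qualitatively like
event-related haemodynamic data; drift is 1e-4 units/s. Weights of order 1
keep evoked responses and noise on a common scale.

On an amphetamine session the expressed value is shrunk toward the two cues'
running mean by `drug_effect` (learning itself continues unchanged); this
collapse propagates to behaviour and to neural cue amplitudes, and outcome
amplitudes on CS_Low trials are additionally scaled by `1 − drug_effect`
(selective blunting of low-expectation outcome responses).

## Population (cohort) defaults

Per-animal parameters are drawn once and recorded as ground truth: alpha ~
U(0.05, 0.30) (wide enough that individual differences dominate fitting
noise, supporting rank-based recovery checks), beta_clicker ~ LogNormal(ln
1.5, 0.2) (clicker more salient than tone), k_clicker ~ N(1.5, 0.3) and
k_tone ~ N(0.25, 0.1) clipped at 0 (stronger unconditioned responding to the
clicker), gamma ~ U(0.5, 0.9), gain ~ N(6, 1) head entries per unit value,
emission noise sd 1.0, pre-cue baseline mean 1.0 (sd 0.5). Animals are
assigned round-robin to counterbalance and, orthogonally, to
vehicle/amphetamine groups; `drug_effect` defaults to 0.9 for amphetamine
animals and 0 otherwise. Each animal gets one NAc-profile and one
OFC-profile electrode by default. All randomness derives from one master
seed through `numpy.random.SeedSequence` with documented integer/CRC-32 keys.

## Signal analysis

Epochs snap to the native sample grid (no interpolation). Cue-aligned epochs
are baseline-corrected by the mean over [−5, 0) s before cue onset (the
pre-event window length is a package choice); outcome-aligned epochs are
normalised to the sample at the outcome. AUC is the trapezoidal integral on
the native grid over 5–10 s post cue or 0–30 s post outcome. Trials whose
outcome window would cross the next cue onset are excluded and logged
(possible only at the 30-s minimum ITI). Training-stage summaries partition
the nine sessions into three equal stages (1–3, 4–6, 7–9).

## Model-based GLM

Per electrode, trial-by-trial AUC responses are regressed (OLS, intercept
included) on latents from the animal's best-BIC behavioural fit. Regressors
and response are z-scored within each electrode-session, so coefficients are
standardized effect sizes. Designs: cue AUC ~ V(t); outcome AUC ~ r(t) +
V(t−1); outcome AUC ~ |r(t) − V(t−1)|. `V(t−1)` is the presented cue's value
before the current outcome's update; `r` is coded {0, 1}. An additional
single-regressor design exposes the composite form `V(t) + r(t) − V(t−1)`
for users who prefer a one-column PE regressor; the two-component
decomposition is the primary analysis because it makes the sign of the value
influence directly readable. Group inference treats the electrode as the
unit of analysis (one-sample two-sided t test of per-electrode betas; at
least 3 electrodes per region; electrodes from the same animal are not
pooled). The three cardinal RPE criteria are: positive value effect on the
cue signal, positive outcome effect, and negative value effect at outcome —
each requiring the correct group-level sign with p < 0.05.

## Drug contrast

Per-animal discrimination index = mean(CS_High) − mean(CS_Low) of head-entry
rates or cue AUC. The drug effect is tested with a permutation
difference-of-differences statistic, `mean over amphetamine of (drug − pre)
minus mean over vehicle of (drug − pre)`, permuting drug-group labels across
animals. When the number of distinct assignments is at most `n_perm`
(default 10,000) the null is enumerated exactly and p includes the observed
assignment, so p > 0 always; otherwise random permutations are used with the
add-one estimator. A permutation test replaces the mixed ANOVA used on real
data because it is distribution-free and exactly reproducible from the seed
while preserving the cue x session x drug interaction logic. With 8 animals
(4 per group) the exact null has 70 assignments, so the smallest attainable
p is 1/70 and the realised test size at alpha = 0.05 is 3/70 ≈ 0.043.

## Problem sizes used in the shipped checks

Recovery analyses use 20 animals for behavioural parameter/model recovery
(grid of 8 specs, 10 restarts), 20 seeded 6-animal cohorts for the regional
PE signatures (full-model fits, 6 restarts, 12 electrodes per cohort), 20
cohorts of 8 animals for contrast power and 500 for its empirical size. These
sizes give stable rates while keeping a full run in minutes on one core.

## What the generator does and does not emulate

It emulates: exact session design; counterbalance-dependent unconditioned
responding and salience; learning carried across sessions; HRF-smoothed
event responses with drift and autocorrelated noise; shared value latents
across regions (hence positive cross-region correlation); drug-induced
discrimination collapse and selective CS_Low outcome blunting. It does not
emulate electrode drift or calibration chemistry, movement or
licking artifacts, non-linear haemodynamic saturation, inter-electrode noise
correlations within an animal, or any pharmacokinetics beyond the
session-level collapse. Passing recovery tests therefore shows the analysis
code is correct and adequately powered under these assumptions — not that
real amperometry data meet them.

## Numerical choices and degenerate inputs

Windows on the sample grid are closed for integration ([5, 10] s contains
both endpoints); the pre-event baseline window is half-open [−5, 0).
Constant regressors within a session (e.g. all trials rewarded) raise a
rank-deficiency error rather than silently producing unstable z-scores.
Epochs falling outside a trace are excluded and logged, not fatal. Gaussian
emission rates are truncated at zero. BIC ties break toward parsimony.
Optimiser failures on every restart raise a named error; a single successful
restart suffices.

## Known limitations

- The Gaussian likelihood treats head-entry rates as continuous; a Poisson
  count option exists in the generator's conceptual design space but the
  fitted likelihood is Gaussian-only.
- alpha and beta_clicker trade off within clicker trials; alpha is identified
  mainly through tone-cue learning, so recovery of their product is tighter
  than of each factor.
- Per-session z-scoring shrinks late-training value variance, weakening
  value effects once learning has converged; group-level inference across
  electrodes compensates in the shipped configurations.
- The permutation test conditions on group sizes; very small cohorts give a
  coarse p-value grid (documented above).
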