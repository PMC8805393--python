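# Methods

## The problem

Four drugs are licensed for the cognitive symptoms of dementia: the
acetylcholinesterase inhibitors donepezil, galantamine and rivastigmine, and
the NMDA-receptor antagonist memantine. Prescribing among them is largely
conventional (donepezil first, memantine for moderate-to-severe disease),
yet patients plausibly differ in which drug slows their cognitive decline
most. `nntoc` implements an individualized-treatment-rule pipeline over
routinely collected longitudinal cognitive scores (MMSE or MoCA, both
integer 0–30 scales, lower = more impaired):

1. encode each patient's visit history (demographics, inter-visit duration,
   score, prescribed drug) into fixed-length, left-zero-padded sequences;
2. train a sequence model to predict the score at the next visit;
3. for each patient, re-run the fitted model once per candidate drug
   ("counterfactual" prediction) and recommend the drug with the highest
   predicted score — the *neural network treatment of choice* (NNToC);
4. split patients into concordant (prescribed drug = NNToC) and discordant
   groups and compare their decline trajectories over the two years after
   treatment initiation.

Real memory-clinic EHR data of this shape is access-restricted, so the
package ships a synthetic cohort generator that reproduces the statistical
structure of such data *and* plants a per-patient ground-truth best drug.
The planted truth turns the whole pipeline into a measurable parameter
recovery problem — something no observational dataset can offer.

## Synthetic cohorts (`nntoc.sim`)

Each patient has sex, ethnicity and marital status (with explicit
"not available" levels at roughly the rates seen in UK memory-clinic
records: ~20 % ethnicity, ~25 % marital status), an age drawn from a
truncated normal on the 59–102 inclusion window (mean 80.5, SD 7.6), a
latent baseline score (default 21.1, SD 5.41 — MMSE-like), and a latent
untreated decline rate (mean 1.5, SD 0.6 points/year).

A record starts at first contact with 0–2 drug-free pre-initiation visits,
then the initiation visit and on-drug follow-ups (2–6 on-drug visits,
log-normal inter-visit intervals with mean 0.55 y — about 3.6 observations
per patient inside a two-year window, matching the case mix the cohort
emulates). Post-initiation scores follow

    score(t) = score(t_init) − (base_decline − effect[drug]) · max(0, t − t_init − plateau) + ε,

clamped to [0, 30] and rounded to integers (both switchable off for limit
tests). The `plateau` term (default 0.5 y) reproduces the 3–6-month
stabilisation seen after starting any of these drugs; ε is Gaussian visit
noise (default SD 1.5, a realistic test–retest error for MMSE).

The pre-initiation visits are not decoration: a patient stays on one drug
for the whole record, so without drug-free steps the prescription features
would be a patient-level constant and the drug input would be statistically
unidentifiable from the rest of the record.

**Planted drug effects.** Every drug shares a base decline-slowing of
0.5 points/year; each patient's *preferred* drug gets `heterogeneity` extra
points/year (default 2.0, i.e. a 2.0 points/year best-versus-rest gap —
consistent with the multi-point two-year group separations reported for
real cohorts; the acceptance suite states this assumed effect size
explicitly wherever it relies on it). The default rule keys the preferred
drug on sex and baseline severity —

| stratum | preferred drug |
|---|---|
| female, milder (score ≥ cohort mean) | donepezil |
| female, more severe | galantamine |
| male, milder | rivastigmine |
| male, more severe | memantine |

— effect modifiers a recommender can in principle see at treatment
initiation, and an echo of the real-world observation that models of this
kind avoid donepezil for men and low scorers and prefer memantine in more
severe disease. An alternative rule (`severity_progression`) keys the
second axis on the *speed* of untreated decline instead of sex; speed is
only expressed through the longitudinal score sequence, which makes that
rule the right probe for sequence-length experiments. A `uniform` rule
(all drugs equal) provides the null. With `heterogeneity = 0` all four
effects are identical and the canonical-order tie-break makes donepezil
the nominal "best" drug everywhere.

Drug assignment defaults to (0.60, 0.15, 0.15, 0.10) over (donepezil,
galantamine, rivastigmine, memantine), independent of covariates; a
`confounded_assignment` switch mixes in a 50 % preference for the
patient's true best drug for sensitivity experiments.

**What the generator does not emulate:** free-text notes, comorbidities and
dementia subtypes, drug switching and discontinuation, visit scheduling
that depends on disease state, floor/ceiling measurement artefacts beyond
hard clamping, and outcome-dependent missingness. Passing tests therefore
demonstrate that the pipeline recovers planted heterogeneity under clean
longitudinal sampling — not that it would do so against the full messiness
of real records.

## Preparation (`nntoc.prep`)

Filters mirror the standard cleanup for this cohort type, in order: age
window 59–102; exclusion of patients on more than one anti-dementia drug;
truncation of follow-up two years after the first prescription; exclusion
of patients left with fewer than two observations. The filters are
idempotent and return an accounting report whose patient-level exclusions
sum exactly to the input/output difference.

Visits are encoded as one-hot blocks — sex (2), ethnicity (5), marital
status (5), prescription incl. "none" (5) — plus age/100, duration since
the previous visit (years) and score/30: 20 entries. "Not available" is a
category of its own; nothing is imputed. A sequence is a window of up to
`window_length` consecutive visits, left-zero-padded, predicting the score
at the visit that follows the window. The target visit's drug (4 slots)
and the time gap to it are appended to the last real step, which is the
hook that makes counterfactual drug substitution well defined. An optional
encoder flag adds a score-missing indicator column (zero-fill + indicator)
for records with missing continuous scores; it is off by default because
the default generator always emits scores and the 20-entry layout is the
documented contract.

Training can either fix one random window per patient (strict mode) or
draw from the per-patient pool of all eligible windows, resampling one
window per patient each epoch. Pool resampling is the default in the
pipeline: it is the natural augmentation of "select one random run" and
uses the whole record over the course of training.

The train/validation split is at patient level; |train| rounds half-up
(3358 patients at 0.60 → 2015/1343).

## Predictors (`nntoc.models`)

The main predictor is a front-end stack of fully connected ReLU layers
(widths 32, 16) acting per step as a feature extractor, feeding a
**two-layer LSTM** (hidden width 32) whose final hidden state maps linearly
to the predicted next-visit score. Loss is mean squared error on the
score/30 scale; MAE in raw points is used for reporting and importance.
Training uses Adam (lr 1e-3, batch 64, decoupled weight decay 1e-4 on
matrices), up to 200 epochs with early stopping on a patient-level 10 %
carve-out (patience 20); all defaults are overridable, and the heavier
study runs in the tests and the acceptance script use 600 epochs /
patience 100. The whole stack runs on a small in-package reverse-mode
autodiff engine over numpy (`nntoc.autodiff`), verified against finite
differences; training is single-threaded and exactly reproducible under a
seed.

Baselines: ridge regression and a random forest on the flattened window
(scikit-learn), and a one-dimensional CNN (kernel width 2 over the visit
axis, 16 channels, mean pooling) on the same autodiff engine, plus a
declared-grid search helper selecting the lowest validation MAE. A
multitask variant carries one output head per scale (MMSE, MoCA); each
sample contributes only its own scale's head to the loss via a hard mask,
so arbitrary values in the absent label leave the loss bit-identical.

**Counterfactual mechanism.** The candidate drug is substituted into the
target-drug slot *and* into the per-step prescription one-hots of the
on-drug history steps. Because a patient's record carries a single drug
throughout, the two feature routes are perfectly collinear in the training
distribution and a fitted model attributes the drug effect arbitrarily
between them; substituting both asks the well-posed patient-level question
("what if this patient had been on drug d") and is insensitive to that
attribution. A model trained with `ablate_drug_input` zeroes all
prescription features and is exactly counterfactually invariant — the
regression guard for silently severed drug inputs.

Identification caveat, worth stating plainly: on purely factual sequences
a model can explain an on-drug score slope either through
covariate-by-drug structure (counterfactually valid) or by simply
continuing the observed slope whatever the drug label says
(counterfactually inert). Both fit the factual data; fitted models mix
them, which attenuates counterfactual spreads. Windows that straddle
initiation (drug-free history, on-drug target) are what anchors the
covariate route — one more reason the pre-initiation visits matter.

## Recommendation and evaluation (`nntoc.recommend`, `nntoc.evalstats`)

`recommend` runs one prediction per drug in the candidate set (all four,
or AChEIs only — memantine can never be recommended in AChEI-only mode)
and takes the argmax with canonical-order tie-break (donepezil,
galantamine, rivastigmine, memantine). Evaluation windows end either at
treatment initiation (the pipeline default: history up to initiation,
target = first on-drug follow-up) or at a uniformly random eligible visit
(`--random-visit`). The headline recovery analyses use the random-visit
arm: with the 0.5-year stabilisation plateau, roughly half of all *first*
follow-ups occur while the four drugs are still genuinely
indistinguishable, so initiation-mode recovery is capped by the data
generating process rather than by the method.

Decline is defined as initiation score minus later score (positive =
worsening). `trajectory_summary` bins time since initiation (default
0.25-y bins over a 2-y horizon), averages within patient before averaging
across patients, stores SD and SE both, records empty bins as missing, and
attaches a per-bin Welch test when there are exactly two groups. The
"two-year decline" endpoint is measured *at* the horizon — the mean score
over visits in (1.5, 2] years — not at whatever last visit a patient has,
which would mix barely-treated early visits into a nominally two-year
contrast.

`welch_t` (Welch–Satterthwaite df) and `chi_square_2x2` (Yates continuity
correction on by default, matching the published worked examples this
package reproduces) are implemented from the textbook formulas with scipy
supplying only the reference distributions; the test suite cross-checks
both against scipy's independent implementations to 1e-10 and against an
exact enumeration-based permutation test on a small sample.

Permutation feature importance shuffles one predictor's full column block
(all one-hot levels; for medication also the counterfactual slot, for
duration also the gap-to-target) jointly across patients, with one
permutation applied consistently to all steps of a sequence. Donor values
are aligned to the receiver's real steps counted back from the window end
and zero padding is left untouched — naively permuting whole padded
windows would write other patients' values onto padding rows and measure
out-of-distribution damage instead of the predictor's contribution (a
constant predictor would then show a large spurious "importance"; under
the aligned shuffle it shows exactly zero). The report is the mean percent
MAE increase over repeats. `recovery_rate` compares recommendations with the simulator's
planted best drugs and reports an exact binomial test against 1/|drug set|.

### Calibration of the recovery null

The exact binomial test treats patients as independent trials. They are
not: all validation patients share one fitted model, so under the
zero-heterogeneity null the per-seed recovery rate is hugely overdispersed
(measured across 20 seeds: mean 0.250, per-seed range 0.00–0.97). The
per-seed binomial p-value is therefore anticonservative *by construction*,
and the type-I property is asserted where it is actually calibrated: across
independent seeds, mean recovery is statistically indistinguishable from
0.25 (one-sample t-test). The per-seed binomial remains available and is
perfectly valid for the alternative-direction claim (recovery above
chance), where correlation only makes it conservative in the directions
that matter here.

## Numerical and design choices

- Canonical drug order everywhere; all argmax ties resolve to the earliest
  drug in it. Scores clamp to [0, 30] at prediction time.
- Round-half-up for the split size; patient-level splits only.
- Seeds: every stochastic operation takes an explicit seed; the pipeline
  derives per-stage child seeds (< 2³¹) from one global seed.
- Early-stopping validation is carved at patient level from the training
  pool, never from the held-out validation patients.
- Degenerate inputs fail loudly: empty filtered cohorts, <2-visit
  patients, unknown categorical levels, non-finite losses (named epoch),
  zero-margin 2×2 tables, degenerate SDs.
- Trajectory dispersion: SD and SE are both computed and stored; figures
  and reports default to SE (group-mean uncertainty), and the choice is
  explicit in the output schema rather than implied.
- The problem sizes in the shipped tests (reference study n = 2000;
  zero-heterogeneity calibration 20 × n = 250; sequence-length study
  10 seeds × 3 windows × n = 500 at noise SD 0.5) were chosen so each
  check has adequate power at the planted effect sizes while the whole
  suite stays comfortably reproducible on a single CPU.

## Known limitations

- The recovery ceiling is intrinsic, not 100 %: patients whose baseline
  score sits near the severity threshold are genuinely ambiguous under the
  planted rule (measured noise-free recovery ≈ 0.85 away from the
  threshold, ≈ 0.5 at it), and targets inside the stabilisation plateau
  carry no drug signal at all.
- Concordance-group comparisons inherit regression-to-the-mean: the noisy
  initiation score enters both the model's inputs and the decline anchor.
  The planted effect dominates at the default settings, but the bias is
  real and documented rather than removed, since the decline definition is
  fixed by the method being reproduced.
- No causal adjustment (propensity scores, IPW) is attempted for
  confounded prescribing; the `confounded_assignment` switch exists to
  demonstrate the distortion, not to correct it.
- Training determinism is guaranteed only single-threaded on one platform;
  across BLAS builds results may differ in the last few ulps.
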