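# Methods

This note documents the models behind `csu_trial`: what the synthetic-cohort
generator assumes, how the analysis components are estimated, the numerical
conventions, and what passing tests do and do not establish.

## Synthetic cohort model

### Diary trajectories

Each patient carries a latent daily disease intensity on the daily-UAS scale
(0–6):

```
y_i(d) = b_i + (E_a + S_a·1[autoimmune_i]) · f(d) + ε_i(d)
f(d)   = (1 − exp(−d/τ)) / (1 − exp(−T/τ)),  d = 1..T;  f ≤ 0 for pre-dose days
```

- `b_i ~ Normal(m0, σ_b)` is the patient's baseline level; `σ_b` is the
  configured baseline UAS7 s.d. divided by 7 (default 7.3/7 per day).
- `E_a` is the arm's latent treatment effect, `S_a` an additive latent shift
  for the autoimmunity class, both reached with the exponential-onset
  profile `f` (time constant τ, default 7 days — effect near-maximal within
  the first weeks, matching the rapid onset effective CSU treatment shows;
  full effect at the last dose day T = 56). After T the effect is held at
  its day-56 level; follow-up weeks are not analyzed.
- `ε_i` is stationary AR(1) day-level noise (default ρ = 0.6, s.d. 1.0 in
  daily-UAS units). Within-patient diary autocorrelation is not published
  anywhere we know of, so ρ is a free configuration parameter; 0.6 makes
  day-to-day scores sticky without freezing weekly sums.

Each of the four session component scores per day (itch and hive, AM and PM)
is generated as `clip(y/2 + η, 0, 3)` followed by **stochastic rounding**
(`floor(x + U)`, U ~ Uniform[0,1)), with independent session noise η
(s.d. 0.35 on the 0–3 scale). Stochastic rounding makes the conditional mean
of the ordinal score equal the clipped latent value exactly, so the
population mean of any weekly score has the closed form

```
E[UAS7] = 14 · E[clip(Normal(m/2, s), 0, 3)]
```

(a doubly-censored normal mean, with `s²` the marginal component variance).
The generator inverts this expression numerically (Brent's method) to find
the latent baseline mean that yields the configured baseline UAS7 and, per
arm, the latent effect that yields the configured week-8 change. The
expected baseline UAS7 and week-8 change therefore match the configuration
by construction, including the floor/ceiling compression the bounded scale
imposes — the property the generator's Monte Carlo calibration tests check.
The marginal week-8 change of an arm with a nonzero autoimmune shift is the
configured change plus prevalence × shift; calibration tests use shift-free
configurations so the target is exact.

The observed baseline UAS7 s.d. is approximately, not exactly, the
configured value: rounding and session noise add a small within-week
component on top of the between-patient spread (≈0.3 points at the default
configuration). We accepted this rather than adding a second calibration
loop for the variance.

### Defaults

The default configuration encodes the study conditions of a four-arm
dose-ranging CSU trial: arm sizes 23/23/24/23, baseline UAS7 27.5 (s.d.
7.3), week-8 changes −11.2 / −11.7 / −17.6 / −20.7, autoimmunity-class
prevalence 0.41, dropout 0.14 over the treatment period (a single
discontinuation day per patient, uniform over days 1–56; no published
hazard shape exists), sporadic post-baseline session missingness 0.03, and
three enrolment countries. The extra latent benefit for the autoimmunity
class at the two lower doses (−4 and −3 points) encodes the qualitative
observation that marker-positive patients respond more strongly at
submaximal doses; no printed magnitude exists, so these are round numbers of
the plausible size, fixed once. The baseline week (the 7 days before the
first dose) is always complete, mirroring the eligibility requirement of
full diary coverage in that window.

### Biomarker forward model

ELISA plates carry a 7-point threefold standard dilution series
(10 … 0.0137 ng/ml — a threefold series needs 7 points to span that printed
range), blanks, a 16-donor healthy panel and per-patient duplicate wells for
both spike conditions. Absorbance follows a four-parameter logistic in
concentration plus a shared 630-nm offset and optional Gaussian noise.
A patient's control-protein-spiked wells read background + true relative
reactivity; antigen-spiked wells read background only, so the quantification
pipeline recovers the true reactivity by subtraction — exactly, when the
absorbance noise is zero (the round-trip tests). BHRA raw amounts encode a
true percentage release against a 120-unit lysate total; the 5-donor healthy
panel has mean ≈2.5%, s.d. ≈0.75%. Class-conditional distributions make the
autoimmunity class BHRA-positive with high probability, ELISA-positive, and
low-IgE (log-normal IgE medians 25 vs 120 IU/ml), reproducing the marker
triad and an overall IgE mean near 136 IU/ml.

### Determinism

All randomness derives from one master seed through fixed
`SeedSequence(seed, spawn_key=(stream, patient_index))` substreams, so
identical (config, seed) give byte-identical serialized cohorts and adding
patients never perturbs existing ones.

## Endpoint scoring conventions

Where the instrument description is silent the package uses:

- one recorded session in a day → that session's sum is the daily score;
  no sessions → missing day;
- a week is valid with ≥ 4 observed days; weekly sums are prorated by
  7/days_observed and rounded to one decimal — applied to the itch and hive
  sums separately, so UAS7 = itch7 + hive7 holds exactly after rounding;
- week w covers study days 7(w−1)+1 … 7w (week 8 ends on the last dose day);
  week 0 is the baseline week;
- "discontinued before the reporting time point" means the dropout day
  precedes the end of the reporting week (dropout_day < 7w); such
  patient-weeks are nonresponders regardless of scores, as are weeks without
  a valid score;
- the itch-score MID is configurable (default 5 points; no published value);
- time-to-MID censors non-achievers at their last validly-scored
  on-treatment week, at the latest week 8 (follow-up excluded).

## MMRM estimation

No maintained Python package fits an MMRM with unstructured covariance, so
the REML estimator is implemented here: β is profiled out of the restricted
likelihood, Σ is parameterized by its Cholesky factor with log-transformed
diagonal (always positive definite), patients are grouped by
observed-visit pattern for vectorized likelihood evaluation, and L-BFGS-B
optimizes the profiled criterion starting from a compound-symmetry estimate
(identity restart on failure). A fit is accepted when the optimizer reports
success, the final gradient is numerically zero (the line search aborts at
iteration zero when the initializer is already optimal, e.g. single-visit
saturated models), or the criterion has plateaued; anything else raises with
the log-likelihood trace. The recorded iterate history is non-decreasing in
REML log-likelihood (line-search guarantee), which the tests assert.

Denominator degrees of freedom use the **Satterthwaite** approximation:
ν = 2v²/Var(v) with v the contrast variance, Var(v) by the delta method
from the observed information of the covariance parameters
(central-difference Hessian, cached per fit). At these sample sizes
Satterthwaite and Kenward–Roger are practically indistinguishable; the dof
method is recorded on every contrast. A fast `residual` option
(n_subjects − n_arms) is provided for simulation studies; under complete
data with a saturated mean structure it is the exact between-subject dof,
which is why the null-simulation type-I-error check uses it.

Design choices: arm-by-visit cell means plus deviation-coded country
contrasts (fixed levels; a single country is dropped with a warning);
baseline is not a covariate (the model adjusts for country, treatment,
visit and their interaction only); no multiplicity adjustment — CIs are
unadjusted 95%. Subgroup fits add a marker stratum to the cells (the
three-way interaction); with one stratum level they reduce exactly to the
plain fit. BOCF's "best" is the most negative change (the direction of
benefit for UAS7).

## Kaplan–Meier conventions

Curves come from the product-limit estimator (lifelines), events before
censorings at tied times. The median is the smallest time with S ≤ 0.5
(inclusive); when the curve sits exactly at 0.5 over a plateau the midpoint
of the plateau is reported — this is what makes half-week medians possible
on a weekly grid. Both the BHRA positivity boundary (value ≥ 10) and the
median rule (S ≤ 0.5) carry relative float guards (~1e-9 … 1e-12) so values
equal to the boundary in exact arithmetic are not misclassified by
ulp-level rounding.

## Design layer

Power treats the evaluable sample as ⌊n(1 − dropout)⌋ per arm and evaluates
the two-sided two-sample comparison by normal approximation (default) or
noncentral t; both exceed 90% under the design assumptions (11-point
difference, s.d. 13, α = 0.10, 30/arm, 10% dropout). The go/no-go rule uses
a flat prior with known s.d.: the posterior of the true effect is
Normal(δ̂, 2σ²/n_interim); predictively, the future estimate adds
2σ²/n_phase3, and the reported probability is the upper tail at the
threshold (> 0.60 go, < 0.25 no-go). Whether the threshold applies to the
future *estimate* or the *true effect* is ambiguous in prose descriptions
of such rules; the predictive (estimate) reading is the default, the
posterior (true-effect) reading is available via `predictive=False`. The
phase-3 threshold and sample size have no published values and are required
arguments. Internally effects are positive-is-better; negate UAS7 changes
on entry. Randomization block size defaults to one ratio-unit (4 for
1:1:1:1), unpublished.

## Problem sizes in the tests

Monte Carlo tests are sized to keep the default suite in the minutes range
while leaving tolerances honest: generator calibration uses 1,000–3,000
simulated patients per arm (3 Monte Carlo s.e. tolerances), the MMRM
type-I-error check uses 1,000 null replicates at 30 patients/arm and 3
visits (tolerance 0.05 ± 0.02), contrast recovery uses 12 replicate trials
at 60/arm, and the power simulation 30,000–100,000 replicates.

## Limitations

- The diary generator produces MCAR session gaps and a single MAR-style
  dropout day; it does not model outcome-dependent dropout, so the
  MAR-robustness property of the MMRM is exercised by a dedicated
  simulation, not by the default cohort.
- Ordinal scores are exchangeable between itch and hive components; real
  diaries show component asymmetry (hive scores run higher).
- The assay forward model has Gaussian absorbance noise and a shared
  background per patient; no plate-position effects, drift, or
  heteroscedastic CV profiles.
- Passing calibration tests shows the analysis chain recovers the
  generator's truth under the generator's assumptions — not that the MMRM
  assumptions hold in any real trial.
- No pharmacokinetics, adverse-event simulation, quality-of-life
  instruments, or angioedema episode endpoints; the UCT appears only as a
  configuration constant.
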