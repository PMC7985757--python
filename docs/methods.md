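# Methods

## The model

`symtraj` implements group-based trajectory modeling (GBTM) for the
Edmonton Symptom Assessment System (ESAS) total symptom distress score
(TSDS) in a longitudinal cancer cohort. The TSDS is the sum of the nine
ESAS item scores (pain, tiredness, drowsiness, nausea, appetite,
dyspnea, depression, anxiety, wellbeing; each 0–10, wellbeing scored
as-is with 0 best), giving a 0–90 scale. Because the raw score is
strongly right-skewed, the modeled outcome is the shifted Box–Cox
transform with λ = 0.25:

    f(x) = ((x + 1)^0.25 − 1) / 0.25,

which maps 0 → 0, 15 → 4, 80 → 8 and the full range onto [0, 8.355].

Each patient *i* belongs to one of *J* latent groups with probability
π_j (multinomial logit; optionally on baseline covariates). Conditional
on group *j*, the transformed score at time *t* (months since
diagnosis) is

    y_it = β_j' · poly(t) + α_j' · w_it + ε_it,   ε_it ~ N(0, σ²),

where poly(t) is a polynomial basis of group-specific order 0–4 in
scaled time, w_it are 0/1 time-varying covariate flags (treatment or
supportive care received in the closed window 0–7 days before the
assessment), and σ is shared across groups. The outcome density follows
the CNORM (censored-normal) convention: a normal density between bounds
(cmin, cmax), with probability mass Φ((cmin−μ)/σ) at y ≤ cmin and
Φ((μ−cmax)/σ) at y ≥ cmax. With bounds outside the observed range —
the default, appropriate when no clustering is seen at the scale limits
— the censored terms are inactive and the model is an ordinary normal
mixture. When the data do pile up at a scale limit (e.g. raw scores
clipped at 90), passing `cnorm_max = f(90)` treats the ceiling as a
censoring bound; the recovery tests demonstrate that this removes the
attenuation of σ that an unbounded fit suffers under ceiling effects.

The marginal log-likelihood is

    ℓ = Σ_i log Σ_j π_j Π_t f_j(y_it),

maximized directly (no EM) by L-BFGS-B with an analytic gradient,
because the censored terms make the M-step non-closed-form anyway and
the full-gradient approach is simpler to make exactly correct (the
gradient is verified against finite differences in the tests, including
with active censoring).

### Numerical choices

- **Time scaling.** Time is divided by 10 before powering (quartic terms
  in raw months overflow conditioning at 72 months: 72⁴ ≈ 2.7·10⁷).
  Coefficients are reported on the scaled axis; the scale is recorded in
  the fit object.
- **Initialization.** A k-means-style split of patients on the
  two-dimensional feature (mean of y in the first half of follow-up,
  mean in the second half). Level-only initialization cannot separate
  groups that differ in direction of change but not average level. The
  first start is deterministic (quantile seeding + 10 Lloyd iterations);
  subsequent starts perturb the cluster centers. Default 10 starts
  (fewer in the scripted analyses where noted); the best local optimum
  is polished at `ftol` 1e-12.
- **Convergence.** Relative log-likelihood tolerance 1e-6 (L-BFGS-B
  `ftol`), max 500 iterations. The per-iteration objective history is
  stored; a test asserts it is non-decreasing within 1e-8.
- **Group labels.** After fitting, groups are relabeled in ascending
  order of time-averaged fitted trajectory level (Group 1 lowest), with
  the per-group polynomial orders permuted along with the parameters.
  Posterior argmax ties resolve to the lowest group index.
- **Standard errors.** Observed information: a central-difference
  Hessian of the analytic gradient at the optimum, inverted (pseudo-
  inverse on singularity). Trajectory confidence bands use the delta
  method on the (β_j, α_j) covariance block; 95% bands are ±1.96·SE.
- **Censoring bounds default.** (observed min − 1, observed max + 1),
  i.e. deliberately inactive.

## Preprocessing rules

Applied in order: (1) TSDS per assessment — sum of the nine items; with
1–4 items missing (≤50%) the score is mean(present) × 9, keeping the
0–90 scale; with ≥5 missing the assessment is excluded. (2) Same-day
duplicates — the assessment with the higher raw TSDS is kept, the
first-listed on ties (raw-after-imputation is used when a duplicate had
imputed items). (3) Patient filters — fewer than three surviving
assessments, all item scores zero on every assessment, or missing
income quintile; removals are logged by reason. (4) Dataset build —
time is (assessment date − diagnosis date)/30.4375 months; only the
first 30 assessments per patient enter the model; the 0–7-day covariate
windows are closed at both ends (day 0 = assessment day and day −7 both
count).

## Model selection and adequacy

BIC follows the Nagin convention, BIC = ℓ − (k/2)·ln N with N the
number of *patients* and k counting (J−1) membership logits per
membership term, Σ_j (order_j + 1) polynomial terms, per-group
covariate effects, and σ. Higher BIC is better, and twice the BIC gap
approximates the log Bayes factor (>10 = strong evidence).

The search grows J from 1 with all groups quartic while the log Bayes
factor against J−1 exceeds 10, then steps polynomial orders down: scan
groups left to right, reduce the first group whose highest-order
coefficient is non-significant (Wald, α = 0.05), refit (warm-started
from the incumbent solution with the dropped coefficient removed, plus
one fresh random start), repeat until stable. Every candidate is
recorded in the ladder.

Adequacy of the selected model is summarized per group by AvePP (mean
posterior among assigned members; threshold 0.7), the odds of correct
classification OCC = [AvePP/(1−AvePP)] / [π/(1−π)] (threshold 5),
|π − P| (estimated probability vs assigned share; should be ≈0), and
membership share (≥5% advisory flag, not auto-rejection). An empty
group reports NaN diagnostics with a note.

## Covariate modeling (three stages)

Stage 1 is the unadjusted structural selection above. Stage 2 regresses
the hard group assignments on each time-fixed baseline covariate with a
multinomial logit and screens on the covariate's overall likelihood-
ratio p-value (the per-term minimum Wald p is wildly anti-conservative
across 5 × k dummy terms). Stage 3 re-estimates the mixture jointly:
screened baseline covariates (if any) enter the membership logits via
`membership_design`, and the four time-varying covariates enter each
group's mean. Both entry points are exposed because either reading of
"joint estimation" (re-estimating membership with covariates vs
conditioning on stage-1 shapes) is defensible.

## Sensitivity analyses

- **Baseline-median split.** Each patient's first assessment's raw TSDS
  is dichotomized at the cohort median (ties to the high side);
  membership in the flat high-burden groups is cross-tabulated against
  it, and a Pearson chi-square (df 1, no continuity correction) is
  reported.
- **Death imputation.** Patients dying in follow-up receive monthly
  pseudo-assessments at the maximum transformed TSDS (f(90) = 8.355)
  from death to the end of follow-up, capped at 30 total assessments;
  the selected structure is refit. Refit groups are matched to base
  groups by patient-assignment overlap (Hungarian assignment on the
  confusion matrix) before trajectories are differenced — without the
  matching step, label switching between the two fits masquerades as
  trajectory shift. Reported: per-group maximum absolute difference of
  mean trajectories on a shared grid.

ED-visit rates per person-month come from an intercept-only Poisson GLM
with log person-month offset (Wald CI on the log scale; at ≥500 events
this agrees with the exact chi-square-inversion interval to a few
percent, which a test checks). Table percentages use half-up rounding
to two decimals. Chi-square tests for group-profile tables merge
adjacent group columns (smallest combined total first) until all
expected counts reach 5, recording the merge map.

## The synthetic cohort generator

No public data exist for this analysis (the study linked provincial
administrative databases), so the generator is a first-class module
emulating the cohort the pipeline expects. Defaults encode the study
conditions:

| quantity | default | basis |
|---|---|---|
| patients | 995 | cohort size |
| realized assessments/patient | ≈16.2 | 16,146 / 995 (pre-truncation target 21, spacing 1.25 mo) |
| group probabilities | (.1149, .0986, .1210, .2463, .2648, .1544) | reported membership % |
| trajectory shapes | 3 changing quartics + flat 4.6 / 5.8 / 7.0 | reported profile: three changing lower groups, three flat higher groups |
| residual SD | 0.65 | calibrated so the six groups meet the reported adequacy criteria (AvePP>0.7, OCC>5, membership>5%) |
| covariate effects | per-group values of the reported adjusted model | reported estimates |
| covariate flag rates | chemo .25–.35, radio .08, home care .12–.15, palliative .10–.28 per visit | plausible visit-level receipt; gradient over groups |
| death hazards / month | (.0166, .0059, .0062, .0147, .0177, .0234) | −ln(1−p₃y)/36 from per-group 3-year mortality |
| duplicates | 3.7% of visit rows | 603 / 16,146 |
| under-3-assessment patients | 20% | 256 / 1,260 pre-filter cohort |
| all-zero patients | 0.5% | 6 / 1,260 |
| missing income | 0.24% | 3 / 1,260 |
| item missingness | 0.5% of cells | baseline per-item Ns ≈ 990–995 of 995 |
| ED visits | 0.12 / person-month | reported rate |

Mechanics: visit gaps are Exponential(mean = spacing) rounded to
0.25-month resolution with the first visit at diagnosis; death
truncates the visit stream and administrative censoring applies at the
follow-up horizon; the latent transformed value is back-transformed to
a raw 0–90 target, rounded, and allocated across the nine items by a
capped multinomial split (so only the sum is meaningful, which is all
the pipeline consumes); a single seeded random stream drives
everything, and artifact injection (duplicates, missing items,
truncated patients, all-zero patients) tags rows in a provenance
column so tests can verify filter behavior.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: item-level correlation structure
beyond the shared sum; informative missingness (visits are missing at
random given death); temporal clustering of ED visits; baseline
covariates are drawn independently of group (consistent with the
study's finding of no significant baseline predictors, but it means the
stage-2 screen is only checked for calibration, not power, on cohort
defaults); and visit timing is memoryless, whereas real assessment
schedules follow treatment cycles.

## Scaling of the scripted analyses

The numbered analyses and the acceptance script run the six-group
design at 450–500 patients and the selection-consistency study at 150
patients × 20 replicates. These sizes keep the full pipeline in the
minutes range on a single CPU while leaving all qualitative conclusions
(structure recovery, adequacy, sensitivity directions) stable across
seeds; they are the package's chosen simulation sizes, and the printed
outputs state the N actually used.

## Known limitations

- No dropout/informative-missingness joint model, no Bayesian
  estimation, no survival sub-model (out of scope by design).
- The order step-down is a deterministic left-to-right heuristic, not
  an exhaustive search over order combinations; at desk-scale N it
  often simplifies quartic generating shapes to lower orders because
  the top coefficients are individually non-significant — the selected
  structure still separates changing from flat groups.
- Standard errors ignore classification uncertainty in two-stage uses
  (assignments treated as known in profile tables and stage-2 screens),
  the standard GBTM practice.
- With fewer than ~8 patients per group the numerical Hessian can be
  near-singular; SEs fall back to a pseudo-inverse and are flagged NaN
  where the diagonal is non-positive.
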