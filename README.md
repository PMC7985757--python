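# symtraj

Group-based trajectory modeling of longitudinal symptom burden in
cancer cohorts.

Patients with metastatic cancer report symptoms repeatedly over their
disease course (here: the nine-item Edmonton Symptom Assessment System,
ESAS, summed to a 0–90 total symptom distress score, TSDS). Average
growth curves hide the clinically important fact that patients follow
*different* burden trajectories — some low and improving, some high and
uncontrolled. `symtraj` identifies those latent subgroups with a
censored-normal finite mixture of polynomial trajectories (GBTM):

- outcome: Box–Cox transformed TSDS, f(x) = ((x+1)^¼ − 1)/¼, modeled as
  y_it = β_j′·poly(t_it) + α_j′·w_it + ε_it, ε ~ N(0, σ²), conditional
  on latent group j (probability π_j, multinomial logit), with CNORM
  probability mass at censoring bounds;
- maximum likelihood by multi-start quasi-Newton with analytic
  gradients; groups relabeled low → high;
- model selection: grow the group count while the log Bayes factor
  2·ΔBIC exceeds 10 (BIC = ℓ − k/2·ln N, higher better), then step
  polynomial orders down while the top coefficient is non-significant;
- adequacy: AvePP > 0.7, odds of correct classification > 5, |π−Ρ| ≈ 0,
  membership ≥ 5%;
- covariate modeling in three stages (baseline screen by multinomial
  logit; time-varying treatment/care flags shifting group means);
- sensitivity analyses (baseline-median split chi-square; maximum-TSDS
  imputation after death with a matched refit);
- ESAS preprocessing (missing-item imputation, same-day dedupe, patient
  filters, first-30 cap) and a synthetic cohort generator emulating the
  administrative data this kind of analysis runs on, including its
  pathologies.

See `docs/methods.md` for the full model description and the generator
calibration.

## Worked example

The numbered scripts under `analysis/` run the full pipeline on a
scaled-down synthetic cohort (500 patients; six groups — three
changing, three flat):

```
$ python analysis/01_simulate_cohort.py
cohort: 500 patients, 6947 raw assessments (13.9/patient)
  deaths within follow-up: 230
  duplicate rows injected: 252
  missing item cells: 297

$ python analysis/02_preprocess.py
retained: 382 patients, 6447 assessments
exclusions by reason:
all_zero                3
missing_income          1
same_day_duplicate    252
under_3               114
```

(16.9 assessments per retained patient; the under-3 and all-zero
patients and the lower-scoring duplicates are removed by the filters.)

```
$ python analysis/03_select_model.py
...
selected: 6 groups, orders 212000, BIC -7277.17
  note: stopped growing at J=7: log Bayes factor -30.28 <= 10

adequacy of the selected model:
 group  avepp      occ  pi_hat  p_assigned  abs_pi_minus_p  membership_pct
     1 0.9877 600.6370  0.1181      0.1178          0.0003         11.7801
     2 0.9856 490.9836  0.1226      0.1230          0.0004         12.3037
     3 0.9420 152.2744  0.0963      0.0916          0.0047          9.1623
     4 0.9623  87.1396  0.2264      0.2277          0.0013         22.7749
     5 0.9841 153.5083  0.2879      0.2906          0.0026         29.0576
     6 0.9938 913.2179  0.1485      0.1492          0.0007         14.9215
```

The ladder's BIC rises monotonically through six groups and drops at
seven; every group passes AvePP > 0.7 and OCC > 5 with |π−Ρ| < 0.005.
At this N the step-down simplifies the three changing groups to
quadratic/linear/quadratic shapes (orders 212000) because the quartic
top coefficients are individually non-significant — the
changing-vs-flat structure is preserved.

```
$ python analysis/04_fit_adjusted.py
stage 2: age_group: LR p = 0.856
stage 2: income_quintile: LR p = 0.329
...
adjusted model: loglik -7059.39, no baseline membership covariates

time-varying covariate effects by group (* p<0.05):
 group  membership_pct            term  estimate     se       z      p sig
     1           11.78    chemotherapy   -0.1355 0.0507 -2.6716 0.0075   *
     1           11.78    radiotherapy    0.6094 0.0982  6.2028 0.0000   *
...
```

No baseline covariate predicts membership (as in the data-generating
design); radiotherapy raises the expected transformed TSDS in every
group, chemotherapy lowers it where significant — the covariate table
is written to `results/adjusted_parameters.csv` and the trajectory
figure to `results/trajectories.png`.

```
$ python analysis/05_sensitivity.py
baseline-median sensitivity: chi2(1, N=382) = 92.74, p = 5.96e-22

death-imputation sensitivity (max |trajectory shift| per group):
 group  max_abs_delta    shape
     1          7.300 changing
     2          2.761 changing
     3          6.771 changing
     4          0.264     flat
     5          0.044     flat
     6          0.018     flat

ED visits per person-month: 0.12 (SE 0.003, 95% CI 0.11-0.12)
```

A first assessment at or above the median TSDS strongly predicts
assignment to a flat high-burden group; imputing maximum TSDS after
death reshapes the changing (low-burden, higher-mortality-impact)
trajectories while leaving the flat high groups essentially unchanged.

A `symtraj` CLI wraps the same steps (`simulate`, `preprocess`, `fit`,
`select`, `report`); the library functions are the primary interface.

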