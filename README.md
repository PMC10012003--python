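# stepcompare

A desk-scale engine for studying **physical-activity social comparison** in
digital environments. It re-creates, as testable library code, the machinery
of a daily-diary platform in which insufficiently active adults track their
steps with a wearable and, once per day, choose a comparison target — another
"user" whose step total sits at a controlled distance above or below their
own previous-day total — then rate their exercise motivation before and after
viewing the target's profile.

The package is aimed at researchers in mHealth / health psychology who want
to prototype comparison-target policies, generate realistic synthetic
intensive-longitudinal datasets, and run the standard within/between-person
analysis pipeline on them.

## What's inside

- **`designs`** — target-set generation for three study designs:
  a fixed 70/90/110/130% option set; daily randomization among
  downward-only (90/80/70/60%), mixed (90/80/110/120%) and upward-only
  (110/120/130/140%) sets; and a three-entry team leaderboard where a
  fabricated user is placed 20% below the lower live total, between the two
  live totals, or 20% above the higher. All displayed totals carry ±2%
  uniform obfuscation noise. Blocked-balanced condition randomization.
- **`telemetry`** — session logs (pre/post motivation on a 1–5 scale, profile
  peeks, final selection, Details-page dwell time, elements viewed) and
  derived per-session measures.
- **`simulate`** — an agent-based cohort simulator: log-normal daily steps
  with person-level heterogeneity, multinomial-logit target selection,
  latent-variable motivation ratings, navigation telemetry with an age
  effect, and MCAR missing days.
- **`prep`** — the cleaning and coding rules: drop Details-page dwell > 6
  minutes and days with < 100 steps; code selections as the target's steps as
  a percentage of the participant's previous-day steps, rounded to the
  nearest 10 (with wide bands above 200%); person-mean centering;
  completeness reporting.
- **`mlm`** — the multilevel layer: empty-model ICCs

  ICC = σ²_between / (σ²_between + σ²_within)

  via the one-way random-effects ANOVA estimator for unbalanced data (REML
  alternative available), random-intercept day-level models
  `y_ij = β₀ + x_ij'β + u_j + e_ij` fit by REML, within/between-person
  decomposition models, linear contrasts over factor levels, and semipartial
  correlation effect sizes *sr*.
- **`fixtures`** — the three studies' published selection-frequency tables as
  packaged CSVs, plus aggregations over them.
- **`cli` / `pipeline`** — a thin command line (`stepcompare simulate |
  generate-targets | analyze | report | fixtures`) over the library, with
  seeded run manifests.

## Worked example

```python
import stepcompare as sc

cohort = sc.simulate_cohort(sc.sim_config(2, seed=42))   # 53 participants x 9 days
report = sc.analyze_cohort(cohort, fit_models=False)
print(f"rows analyzed: {len(report.day_table)}")
print(f"missing participant-days: {report.missing_pct:.1f}%")
print(f"ICC (steps): {report.icc['steps']:.2f}")
up = (report.day_table['selected_direction'] == 'upward').mean()
print(f"upward selections: {100*up:.1f}%")
```

prints

```
rows analyzed: 450
missing participant-days: 0.8%
ICC (steps): 0.35
upward selections: 54.9%
```

450 of the 477 possible participant-days survive simulation-time missingness
and the two cleaning rules; roughly a third of the variance in raw daily
steps is stable between-person difference (the generator is configured for
an ICC of 0.5 on the *log* scale, which compresses on the raw scale); and
upward targets are chosen a bit more often
than downward ones — the signature selection pattern the platform design
elicits (no upward option exists on downward-only days, so the share sits in
the mid-50s rather than at the mixed-day preference level).

The `examples/` directory holds one short narrative script per capability
(target generation, leaderboards, cohort simulation, ICCs, within/between
models, fixture aggregations); each prints its numbers with a line on what
they mean.

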