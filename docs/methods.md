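# Methods

This note documents the models, rules and numerical choices implemented in
`stepcompare`, and what the synthetic-data generator does and does not claim
about real data.

## The platform model

Each participant-day is one session: the participant sees their own
previous-day step total (the *anchor*), an option set of comparison-target
profiles, commits to one profile, and rates exercise motivation (1–5) before
and after viewing it. Three designs are built in:

1. **Fixed set** — four profiles at 110%, 130%, 90% and 70% of the anchor
   every day (two upward, two downward).
2. **Randomized sets** — each day one of three conditions: downward-only
   (90/80/70/60%), mixed (90/80/110/120%), upward-only (110/120/130/140%).
3. **Team leaderboard** — the participant, one live teammate, and one
   fabricated user placed 20% below the lower live total (`fab_below`),
   between the two (`fab_between`), or 20% above the higher (`fab_above`);
   the three-entry board is ranked by steps, descending.

### Obfuscation noise

Every platform-generated step total is multiplied by `1 + u` with
`u ~ Uniform[-h, +h]`, default `h = 0.02`, then rounded half-up to an
integer. The uniform distribution is the simplest symmetric choice on the
stated interval and is what the engine's distributional test checks (KS
against uniform over 10,000 draws). With 20% placement offsets and `h ≤ 0.02`
the fabricated user's total can never cross a live total of at least 100
steps, which is the strict-placement property the tests assert.

### Fabricated "between" placement

A total "between" two live totals is generated at the midpoint, noised, then
clamped to the open interval `(min+1, max-1)` so it remains strictly between
the live totals; when the live totals are equal it degrades to the shared
value. Midpoint-then-clamp is symmetric, reproducible, and respects the
design's description; any interior point would satisfy the letter of the
design, and the choice is recorded here because it is genuinely open.

### Condition randomization

Per participant (per team in the leaderboard design), conditions are
blocked-balanced: each appears `floor(n_days/3)` or `ceil(n_days/3)` times,
remainder assigned at random, order shuffled. Over a 9-day schedule every
condition appears exactly 3 times, so a complete cohort shows exactly equal
marginal thirds — the empirical pattern this mechanism is chosen to
reproduce. An i.i.d.-uniform mode is available (`assignment_mode="iid"`).

### Leaderboard ties

Ties in displayed steps are broken by username ascending. This makes board
construction a pure function of the entry set (invariant to input order),
which the permutation test relies on.

## Session telemetry

A session log records login time, the pre rating, ordered peek events,
the final selection, the count of detail elements viewed, Details-page dwell
seconds, and the post rating. Derived measures: motivation change =
post − pre (range −4..+4); `first_equals_final` is true when the first peek
names the final selection, and vacuously true when the participant committed
without peeking around — the convention that makes the completed-day counts
partition cleanly. Dwell time is interpreted as Details-page time only.
Element counting is distinct-by-default (repeat clicks on one field do not
re-count); a per-click mode exists. Sessions with no final selection are
logged but excluded from the analysis table. Login time is retained but
unused by the default models.

## The synthetic cohort generator

The generator's defaults are the study conditions, fixed once:

| parameter | default | why |
|---|---|---|
| `mean_steps` | 6376 (design 2), 3609 (design 3), 4690 (design 1) | typical steps/day of the emulated cohorts |
| `sigma_day`, `tau_between` | 0.35, 0.35 | log-step ICC = τ²/(τ²+σ²) = 0.5 |
| `p_miss` | 0.20 / 0.01 / 0.049 per design | observed missing-day rates |
| `upward_affinity` | 0.7 | mixed-day upward probability σ(0.7)=0.67, cohort upward share ≈ 0.56 |
| `distance_penalty` | 1.0 | near targets preferred, cancels within same-direction pairs |
| `beta_direction`, `beta_distance` | 0.15, 0.3 | small positive mean motivation change, larger for upward |
| `beta_within` | 0.0 | motivation→steps feedback off unless studied |
| `p_nonwear` | 0.04 | sub-100-step days at the rate the <100 filter removed |
| `p_view_outlier` | 0.005 | >6-minute dwell rows at the removal rate observed |
| `mean_viewing_seconds`, `mean_elements` | 18 s, 9 | typical navigation magnitudes |
| `beta_age_viewing/elements` | 0.03 per year (log scale) | positive age association, built in to be recoverable |

Steps are log-normal (`LogNormal(mu_i, sigma_day)` with
`mu_i ~ Normal(log mean_steps, tau_between)`); a gamma alternative with
matched mean and coefficient of variation is selectable. When feedback is
enabled, `beta_within × (m_post − 3)` is added on the log scale — centering
at the scale midpoint is an arbitrary constant absorbed by the person
intercept, so the within-person slope recovered by person-mean centering is
`beta_within` regardless.

Selection is multinomial logit via Gumbel-max:
`u = upward_affinity·1[upward] − distance_penalty·|scale − 1| + Gumbel`.
Because the candidate distances are symmetric within the mixed condition,
the mixed-day upward-selection probability is exactly `sigmoid(upward_affinity)`.

Motivation ratings discretize a latent Normal (person baseline, SD 1) into
unit-width bins centered on the scale points — equivalently fixed cut-points
at ±0.5 and ±1.5 around the scale midpoint — clipped to 1–5; the post rating
shifts the latent pre by the direction bonus minus the distance penalty plus
Normal(0, 0.5) noise.

Missingness is MCAR. The tracker keeps recording on missed session days, and
the most recent recorded total anchors the next day's offers (with an
optional carry-forward-last-synced flag emulating a sync defect, default
off). An odd-sized leaderboard cohort pairs the last participant with a
simulated non-enrolled partner whose own sessions are not recorded.

**What passing tests do not show:** the generator reproduces marginal
patterns (step scale, selection shares, ICC magnitudes, age association,
missingness) and is MCAR; real selection behavior depends on daily context
the agent model does not represent, missingness in the field is unlikely to
be MCAR, and no circadian or day-of-week structure is modeled. Recovery
results demonstrate correctness of the estimators under the generative
model, not behavioral realism.

## Data preparation

Cleaning removes rows with Details dwell strictly over 360 seconds and rows
with strictly fewer than 100 steps (boundary values retained); the removal
report counts each rule separately, so a row failing both counts under both.
Filters run before category coding and centering.

Scale-category coding: `100 × selected / anchor`, rounded to the nearest 10.
Exact .5 boundaries round away from 100% (95→90, 105→110) so the tie-break
never manufactures lateral selections. Rounded values ≤ 200 keep their own
`NN%` label (the 100% lateral category is retained as its own label);
larger values fall into `200%-999%`, `1000%-1999%`, `>2000%`. Coding is
scale-invariant by construction.

Person-mean centering returns the person mean (between) and the per-row
deviation (within); deviations sum to zero per person exactly and the parts
reconstruct the input exactly.

Completeness = `100 × (expected − observed)/expected` over the
participants × days grid. Missing days are dropped, never imputed.

## Multilevel layer

**ICC.** The ANOVA estimator: `MSW` and `MSB` from the one-way decomposition,
`σ²_b = max(0, (MSB − MSW)/n0)` with `n0 = (N − Σn_i²/N)/(k − 1)`,
`ICC = σ²_b/(σ²_b + MSW)`. On balanced data this is exact against the
closed-form solution; negative between estimates truncate at zero. The REML
mode (intercept-only mixed model) agrees within 0.02 on balanced data.

**Day-level models.** Random intercept per participant, REML (statsmodels
MixedLM). Categorical predictors are dummy-coded against their first sorted
level. Inference uses the residual-df approximation `df = N − rank(X)` with
two-sided t tests — the convention matching the subscripted test statistics
the pipeline reports; Satterthwaite df are deliberately not implemented.
Rank-deficient fixed designs raise an error naming the collinear columns
(identified by greedy rank inclusion in column order).

**Within/between models** enter the predictor's person mean and within
deviation as separate fixed effects; a predictor constant within every
person has its within term dropped with a warning.

**Contrasts** are linear combinations of one factor's level coefficients
(reference level ≡ 0) with variance `w'Vw` from the fixed-effect covariance;
weights must sum to zero.

**Semipartial r** is the correlation between the outcome and the residual of
the focal predictor after OLS on the other terms. For mixed models this is
an interpretation rather than a canonical definition; it is computed at the
centering level at which the focal term enters (e.g. the within-person
deviation for a within effect). Zero residual variance raises an error.

**Direction dichotomy.** For two-level direction analyses, upward means a
coded category above 100% and downward below; exact-100% rows are excluded
from two-level contrasts, while the share-at-or-above-100% aggregation over
the packaged tables is computed inclusively (that is the accounting under
which the team-design upward share reproduces its printed value).

## Numerical and testing choices

- Displayed steps round half-up to integers; rating discretization is
  floor(x+0.5) clipped to 1–5.
- All randomness flows through `numpy.random.Generator`; a cohort is a pure
  function of its config and master seed (byte-identical reruns, which the
  manifest checksums make auditable).
- Simulation-heavy checks run at 200 persons × 9 days with 100 replications
  for CI coverage and 500 smaller replications (40 × 6) for the type-I error
  rate; the ICC-recovery figure is the mean over 5 cohorts at 200 × 9, since
  a single cohort's ICC estimate has sampling SD ≈ 0.03.
- Degenerate inputs: a zero-step anchor yields all-zero lateral offers and
  an undefined scale percentage (error); equal live totals collapse the
  between placement; an all-singleton grouping has no within variance
  (error).

## Known limitations

- The team design's live totals come from simulated teammates; no real
  multi-user concurrency exists.
- `elements_viewed` is generated as a Poisson count rather than from
  field-level click streams; the distinct-counting helper exists for real
  telemetry.
- Random-intercept-only covariance: no autocorrelated residuals or random
  slopes.
- The semipartial-r definition for mixed models is one defensible choice
  among several; values should be compared only within this package.
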