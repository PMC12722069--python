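# Methods

This note documents the models, the kinship machinery, the synthetic-data
generator and the numerical choices behind `kinnet`.  It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Survey data model

Three tables describe a multi-reporter household survey (column
dictionaries in `kinnet/survey_io.py`): participants (demographics, 1–10
self-rated health and effort, two 4-item 9-point cultural-orientation
scales, four diet items), alters (2–10 important people per reporter with
relation label, sex, approximate age, perceived 1–10 health/effort), and
dyadic ratings (five 0–9 agreement items per rated pair; interaction,
closeness and eating are symmetric, the two health-importance items are
directed).  Perceived health/effort may be missing; missingness propagates
and each model applies its own listwise deletion.

Participants carry a `relation_to_index` label ("ego" for the index adult).
It anchors kinship composition and is known at recruitment, since index
adults invite specific family members.

Ages are banded (<19, 19–39, 40–59, 60+) by a single function used
everywhere; band midpoints stand in for missing years where a numeric age
is required.  Diet frequency uses seven ordinal levels (none, 1–3/week,
4–6/week, 1/day, 2/day, 3/day, 4+/day) — the minimal labelling consistent
with all four dichotomization thresholds.

## Kinship canonicalization

The canonical vocabulary is closed: ego, father, mother, sibling,
grandparent, aunt_uncle, godparent, godchild, cousin, child, niece_nephew,
grandchild, spouse_partner, parent/sibling/child-in-law, friend, other.
Generation offsets are fixed per term; collateral kin outside the named
slots map to the named term of their generation class (a granduncle is
carried as `grandparent`), because downstream classification needs only the
offset.  Godparents sit in the parents' generation, reflecting their
close-family role in the study population.

Composition (reporter's relation ∘ reported label) is a shipped CSV table
(`resources/composition.csv`, 185 rows) over the vocabulary cross-product,
with sex constraints where the candidate depends on the alter's sex.  The
table was written by hand from pedigree arithmetic; a property test
verifies offset additivity (offset(candidate) = offset(reporter) +
offset(reported)) for every row, and a closure test verifies every
vocabulary pair yields a non-empty candidate set ({other} for pairs outside
the table, never an exception).

Ambiguity resolution runs in two passes: unique compositions (plus surveyed
participants) build a context of resolved nodes, then each ambiguous
candidate set is settled by (1) a manual override row, standing in for the
study team re-contacting participants; (2) a cross-reporter match — a
unique candidate whose label matches a context node of compatible sex and
age within ±5 years (configurable; the tolerance is a design choice, no
rule being stated for the original procedure); (3) otherwise the node stays
`other`, excluded from generational classification but never dropped.

## Fusion

Singleton kin slots (father, mother, ego, the index's spouse) merge
unconditionally; multi-instance slots (siblings, grandparents, …) merge
only when sex is compatible and ages agree within the same ±5-year
tolerance, so two brothers survive as distinct nodes.  Friends and
unresolved labels merge across reporters only on exact
case/whitespace-normalized label equality — no other cross-reporter friend
identity information exists.  Surveyed participants' self-reports override
others' perceptions of them; perceived attributes of merged alters are
averaged, as are all edge ratings (directed importance is re-oriented to a
canonical node ordering before averaging).  Node attributes are averaged
across reporters, the same convention as edge ratings.

Tie classification precedence is spouse/partner > friend > generational.
Spouse detection is label-driven via couple slots: (father, mother),
(ego, spouse_partner), (sibling, sibling_in_law), (child, child_in_law),
and opposite-sex same-label pairs for grandparents and parents-in-law.
Opposite-sex aunt/uncle pairs are classified intragenerational: without
family-side information a married aunt-uncle couple cannot be told apart
from two blood-related aunt/uncle siblings, and the blood reading is the
conservative one.  Any tie with a friend endpoint is a friend tie; any tie
with an unresolved endpoint is `other`.  Each fused tie expands to exactly
two directed records (source → target with the source's importance in the
target's health as outcome).

## Dyadic importance model

`DyadImportanceModel` fits a linear mixed model to the 0–9 directed
importance outcome.  The 0–9 rating is treated as continuous, matching the
unit-scale coefficients such studies report.  Three nested fixed-effect
specifications: (1) interaction frequency + closeness + tie category
(friend reference; intergenerational split by whether the target is in an
older or younger generation) + source and target age band, sex, health,
effort; (2) adds eating frequency; (3) restricts to surveyed source nodes
and adds the individualism/collectivism median-split flags.  A
`surveyed_only` switch restricts to dyads with both endpoints surveyed
(sensitivity analysis).

Random structure: household intercept plus *crossed* node intercepts.
"A random effect per node" is ambiguous between separate source/target
effects and one shared effect per node; both are implemented
(`node_effect_mode="crossed"` default, `"shared"` behind the switch) via an
explicit variance-component design (one indicator column per node within
each household), and neither is presented as the original study's certainty.

Estimation is REML through statsmodels MixedLM (lbfgs, fallback to the
default optimizer).  **Boundary handling:** the REML surface is flat where
a variance component is truly zero, and the optimizer either stalls or
stops at a spurious small value.  A component estimated below
`boundary_tol` (default 0.05) × residual variance is treated as a boundary
zero and removed, refitting; with every random term gone the fit is exactly
ordinary least squares.  This makes the degenerate limit exact (zero
generator variances → OLS to 1e-3, verified) without disturbing
well-identified fits, whose components sit far above the threshold.
Non-convergence with no boundary component is reported as a flagged result,
never an exception.

## Network averages and the diet model

For each surveyed participant, network averages are computed over three
scopes: all other network members; family members excluding the
participant's spouse/partner; friends only.  Health and effort use each
member's best value (self-report if surveyed, mean perception otherwise);
eating-together averages the participant's fused edge ratings with scope
members.  A scope with zero members yields no row, so participants without
friends simply drop out of the friends-scope model.

`DietNetworkModel` regresses one dichotomized diet flag (vegetables
≥2×/day; fruit ≥1×/day — the laxer threshold keeps the outcome from being
nearly all-negative; fast food none vs any; snacks ≤3×/week) on the three
scope averages plus participant age band, sex, race, income (modal
reference categories), BMI, self-rated health and effort.  Estimation is
GEE logistic with household clusters and an exchangeable working
correlation (the estimating-equation approach names no structure;
exchangeable is the natural within-household choice).  Standard errors use
the Mancl–DeRouen bias-reduced sandwich covariance: with a few dozen
clusters the plain robust covariance is anti-conservative (the package's
null simulations show ~8% type-I error for the plain sandwich vs ~5–6%
bias-reduced).  Odds ratios are per 1 rating point; predictors are not
standardized.  Scale scores are median-split with ties going to the
"not high" group (strict >), configurable.  BMI is carried as an opaque
covariate.  Cronbach's alpha for the two scales is reported as a
diagnostic, not a gate.

Fits are separate per scope.  Separation and degenerate covariances are
detected via absurd or undefined standard errors and flagged; all-one
outcomes and single-household data raise sample-size errors.

## Synthetic-data generator

`GeneratorConfig` defaults define the study conditions: 36 households, a
21–35-year-old index adult, 1–3 co-surveyed members drawn from
{mother, father, sibling, grandmother, spouse} with weights favouring two,
a kin roster (parents always; sibling, paternal grandmother, maternal aunt,
paternal uncle, cousin, spouse with fixed probabilities), 57% female, and
1–2 private friends per reporter.  Ages follow fixed pedigree offsets
(father = index + 28–32, mother = father − 7, grandmother = father + 26,
uncle = father − 8, aunt = mother − 8, sibling = index + 6, cousin =
index − 11) chosen so that sex+age matching disambiguates every
cross-reporter ambiguity the roster can produce; the spousal 7-year gap in
particular lets a degraded "spouse" label resolve against the correct
parent.  Each reporter rates all family pairs, all self–friend and
own-friend pairs, and 30% of friend × family pairs, calibrating fused
networks to ≈10 nodes and ≈26–28 edges and a tie-category mix near the
observed 456/228/69/392 pattern.

Ratings are discretized truncated normals on 0–9 with category means
(spouse 7.2, intergenerational 5.3, intragenerational 4.5, friend 2.0,
other 3.0), reporter noise sd 0.8, and an opposite-sex eating bonus
(default 1.0) that induces negative sex assortativity.  Directed importance
comes from the truth model: configured coefficients (defaults at the
magnitudes such studies report — closeness 0.38, eating 0.43, spouse 0.89,
intergenerational 0.62/0.36) × mid-scale-centered ratings, plus category
effects, crossed node intercepts (sd 0.5), a household intercept (sd 0.3)
and residual noise (sd 1.5), rounded and clipped to 0–9.  Centering on the
scale midpoint (4.5) rather than per category keeps the *adjusted* category
coefficients equal to the configured truth.  Scale items share a
per-person latent trait (latent sd 1.3, item noise sd 1.1, mean 6.9),
giving alpha ≈ 0.8 and score medians centred on 28 — individual cohorts
scatter ±1 around it, as any finite sample must.  Diet flags are drawn from
a logistic truth model on the participant's own-circle averages (so diet
generation does not presuppose fusion), with base rates 28/25/33/22% and
the configured log-odds; ordinal diet levels are then drawn consistently
with each flag.

`inject_ambiguity` degrades a configurable fraction of sex-pinned spouse
labels ("husband" → "spouse" with the sex field cleared), widening the
candidate set, and emits a key of expected resolutions for testing the
resolution machinery end-to-end.

Two direct simulators (`simulate_dyad_records`, `simulate_diet_data`)
produce model-ready tables straight from the truth models, so
parameter-recovery studies at hundreds of replicates stay cheap.  The
dyad simulator centres ratings per category and anchors the linear
predictor at the scale midpoint so 0/9 truncation is rare and symmetric
(~0.3% per tail); residual truncation leaves ≈1% downward attenuation,
visible in the recovery suite's mean bias and well inside its 10% bound.

**What the generator does not emulate:** free-text label noise beyond
qualifiers and initials, reporter disagreement about who exists (alters are
never phantom), informative missingness, non-pedigree households, and
population demographic marginals beyond the configured categories.  Passing
tests therefore certify the pipeline's logic and the estimators'
calibration under the assumed data-generating process, not robustness to
messy real-world survey text.

## Problem sizes in the test and acceptance runs

Recovery suites use 100 replicates at 200 households (dyadic model,
closeness truth 0.45) and 100 replicates at 300 households (diet model,
family-effort odds-ratio truth 0.5); null calibration uses 500 replicates
at 300 households.  The end-to-end smoke and the acceptance script run the
full pipeline at the 36-household study scale.  These sizes give binomial
noise of ~2–3 percentage points on coverage estimates while keeping a full
run in single-digit minutes on one core.

## Known limitations

- The 0–9 importance outcome is modelled linearly; ordinal models are out
  of scope.
- Kin merging keys on canonical relation + sex/age compatibility; two
  same-sex siblings closer than 5 years apart in age would merge.  Real
  deployments should supply overrides for such households.
- Friend identity across reporters is exact-label only.
- Assortativity with fewer than two distinct attribute values, or zero
  total weight, is undefined (NaN) and excluded from cohort means with a
  logged count.
- No multiple imputation; all models delete listwise and report n.
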