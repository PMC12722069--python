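# Input column dictionary

All three tables are UTF-8 CSV with a header row.  Ids are opaque strings.

## participants.csv

| column | type | description |
|---|---|---|
| participant_id | str | unique across the cohort |
| household_id | str | household the participant belongs to |
| is_index | bool | exactly one per household: the 21–35-year-old index adult |
| relation_to_index | str | raw relation label of this participant to the index adult ("ego" for the index; e.g. "mother", "grandmother") |
| age | float, optional | age in years |
| age_band | str | one of `<19`, `19-39`, `40-59`, `60+` |
| sex | str | `m` / `f` |
| race | str | category |
| income | str | ordinal category |
| housing | str | category (e.g. HDB room count, private) |
| bmi | float, optional | kg/m² |
| marital_status | str | category |
| self_health | int 1–10 | self-rated health (1 poor … 10 excellent) |
| self_effort | int 1–10 | self-rated effort put into a healthy lifestyle |
| hi_1 … hi_4 | int 1–9 | horizontal-individualism items |
| vc_1 … vc_4 | int 1–9 | vertical-collectivism items |
| diet_vegetables, diet_fruits, diet_snacks, diet_fast_food | int 0–6 | ordinal frequency: 0 none, 1 1–3/week, 2 4–6/week, 3 1/day, 4 2/day, 5 3/day, 6 4+/day |

Household invariants: exactly one `is_index` participant and 1–3 others.

## alters.csv

| column | type | description |
|---|---|---|
| reporter_id | str | participant naming this alter |
| alter_label | str | free-text relation label or pseudonym ("mother", "oldest brother", "auntie AZ"); unique per reporter |
| relation_class | str | `family` / `friend` / `other` |
| sex | str, optional | `m` / `f` |
| age_approx | float, optional | approximate age in years |
| perceived_health | int 1–10, optional | reporter's perception |
| perceived_effort | int 1–10, optional | reporter's perception |

Each reporter names 2–10 alters.

## ratings.csv

| column | type | description |
|---|---|---|
| reporter_id | str | participant providing the rating |
| person_a, person_b | str | a participant_id, or one of this reporter's alter labels; a ≠ b |
| interact_freq | int 0–9 | frequent interaction (symmetric) |
| closeness | int 0–9 | close emotional relationship (symmetric) |
| eat_freq | int 0–9 | frequently eat together (symmetric) |
| importance_a_in_b | int 0–9 | a plays an important role in b's health (directed) |
| importance_b_in_a | int 0–9 | b plays an important role in a's health (directed) |

One row per unordered pair per reporter.

## overrides.csv (optional)

| column | description |
|---|---|
| household_id | household the override applies to |
| reporter_id | reporter whose alter is being resolved |
| alter_label | the label as given |
| resolved_label | canonical term to assign (e.g. `father`) |

Overrides stand in for the study team contacting participants to settle an
ambiguous relation, and take precedence over cross-reporter matching.
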