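# Methods

This note documents the models and procedures implemented in `wardflow`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic feed does and does not emulate.

## Plans, steps and decisions

A plan is a directed graph of named steps with one start step and at least
one terminal step. A non-terminal step runs: gather input → validate →
algorithm → actions → decision → advance. Decisions are total by
construction and checked statically (`check_plan`): a band selector over a
score algorithm must cover every achievable integer score; a label selector
over a rule algorithm must cover every rule label plus the default.
Terminal steps carry no decision.

Hourly-assessment pathways are cyclic (assess → monitor → assess); the exit
is the *discharge message*, which jumps any journey to the plan's
designated `discharge_step`. For structural analysis this jump is treated
as an implicit edge from every non-terminal step, which is what makes the
"a terminal is reachable from every step" check meaningful for looping
plans.

Within one clock tick a journey executes each step at most once and stops
when the next step has already run this tick. That yields exactly one full
assessment cycle per hour while letting pass-through steps (monitoring, CRP
stratification) execute in the same instant as the assessment they follow.

## Record validation and data availability

Fields are typed (`number`, `integer`, `boolean`, `text`, `datetime`,
`category`) with optional closed ranges, defaults, and units. Validation
coerces text renderings ("8.1", "true", ISO datetimes), substitutes
defaults for absent optional fields and raises on missing required fields —
the signal that pauses a journey. Validation is idempotent, and collation
of multiple sources is last-wins in declared source order (the paper-silent
collision rule, chosen to be deterministic and declarable).

An observation is *available* at time t if it is the most recent value with
timestamp ≤ t and no staler than the field's `stale_after` window. Labs and
vitals default to a 24-hour look-back; demographics never go stale.
Datetimes are timezone-naive local hospital time — replay only needs
ordering.

## CURB65 and severity banding

One point each for confusion; urea > 7 mmol/L; respiratory rate ≥ 30/min;
systolic < 90 mmHg or diastolic ≤ 60 mmHg; age ≥ 65 years. Bands: Low 0–1,
Moderate 2, High 3–5. The cut-offs follow the standard published score and
are keyword-overridable in `curb65_algorithm`. Confusion is a pre-recorded
boolean (no mental-test-score computation). The blood-pressure factor is a
single factor with two OR-ed predicates, so hypotension never contributes
two points.

## Engine modes and their equivalence

Replay mode preloads a store and walks each admission hour by hour from
admission to discharge (ticks at admission + k hours, k ≥ 0, strictly
before the discharge instant), then finalises at discharge. Stream mode
consumes messages in timestamp order and fires the same per-journey hourly
ticks lazily between arrivals, with messages at a given instant delivered
before the tick at that instant. Because availability is defined by
observation timestamps (not arrival), the two orchestrations produce
identical per-journey logs on identical data; the suite asserts this at
cohort scale. Journey logs are grouped per admission (id order) so the
property is byte-level.

Pausing: a tick that cannot assemble a step's required input pauses the
journey; it resumes at the next tick only if some observation carries a
timestamp inside the paused interval. A discharge arriving while paused
finalises the journey with an `incomplete` marker rather than erroring.
Algorithm failures mark only the affected journey `errored` (per-journey
isolation). Duplicate admission messages are idempotent; observations for
unknown admissions are queued by default (configurable rejection).

## The simulated feed

The generator emulates the *record/field structure and message timing* of a
hospital feed: admission (demographics + ICD-10 codes), 8-hourly lab
(urea, CRP) and vital (RR, BP, confusion) panels, an optional flagged
imaging stub, and a discharge message.

Severity ground truth is enforced constructively, not by rejection: per CAP
admission a target band is drawn from `severity_mix`, a target score within
the band is chosen, the age factor is fixed by sampling age on the
appropriate side of 65, and the remaining factors trigger only inside a
contiguous peak window of 2–4 whole hours; all other hours score exactly
the age factor. Hourly replay therefore recovers the target band for every
CAP admission — the closed-loop property that anchors the tests. Defaults:
45% of CAP admissions reviewed; severity mix 0.30/0.35/0.35
(Low/Moderate/High — CAP cohorts needing review skew moderate/severe);
log-normal length of stay with 72 h mean, clipped to 24–240 h; per-band
mortality 2%/10%/25% (within the published 2–30% severity-dependent range);
20% of reviews lack a comparable numeric score. CAP prevalence
(`cap_fraction`) defaults to 0.3: the plan ignores non-CAP admissions at
triage, so cohorts are deliberately CAP-enriched relative to a whole
hospital.

The simulated reviewer errs with probability `reviewer_error`:
Moderate/High are under-scored one band, Low is over-scored to Moderate.
Every erroneous review therefore disagrees with the engine, so the
pipeline's measured disagreement fraction is an unbiased estimate of the
error rate — the recovery property tested at n = 1,000 within three
binomial standard errors. (Pure one-directional under-scoring would leave
Low reviews unperturbable and the rate unrecoverable.)

What the feed does **not** emulate: physiological time-series structure
beyond threshold crossings, free-text reports, correlated comorbidity,
coding noise, or inter-hospital transfer. Passing tests show the pipeline's
*mechanics* are correct on data whose truth is known by construction; they
say nothing about clinical performance on real admissions.

## Evaluation pipeline

CAP identification: primary-position ICD-10 code with prefix in J12–J18
(configurable). Review linkage: equal patient id and the review's recorded
admission datetime within the admission interval ± 24 h (configurable);
one-to-one, earliest review wins, multi-admission matches kept on the first
with a logged warning. The comparison is the reviewer's single manual band
versus the engine's *maximum* hourly band — deliberately not time-aligned
to the review instant; timing mismatch is a documented source of
discordance in this design, not a defect. The cross-tab asserts its own
arithmetic on every construction (cell sum = compared pairs; reviewed +
unreviewed = CAP total).

## Demonstration mortality model

An XGBoost classifier (60 trees, depth 3, learning rate 0.2, single
thread) over six illustrative per-admission aggregates: age, worst urea,
worst respiratory rate, lowest systolic pressure, any confusion, peak CRP.
Labels come from the simulator's per-band mortality, so achievable AUC is
modest (~0.6) by design — the model exists to exercise encoding,
thresholding (positive class at probability ≥ 0.5, boundary inclusive),
metadata caching, serialization and explanation, not to be clinically
meaningful. "Predictive power" in the metric panel is implemented as
positive predictive value. Metadata is computed on a 25% held-out split and
cached in the artefact so panels render without the model.

## Local explainer

For a record x, sample n perturbations (Gaussian noise scaled by
per-feature training dispersions for numeric features; uniform {0,1}
resampling for booleans), weight by exp(−d²/w²) with d the standardised
distance and kernel width w = 0.75·√(n_features) by convention, and fit a
ridge-regularised (α = 1) linear surrogate to the model's probabilities.
Contributions are the surrogate's raw-unit coefficients: deterministic
given the seed, near-zero for constant models, and inversely equivariant
to feature rescaling for linear models (all tested). Default n = 2,000;
n below the feature count is rejected.

## Serialization and plan documents

Algorithm artefacts are single zip archives: manifest (format version,
kind, schema version), schema JSON, parameter JSON, cached metadata JSON,
and an opaque joblib model blob for classifiers. Loading cross-checks the
manifest's schema version against the embedded schema and any
caller-expected version by exact string match — the guard against scoring
data through an algorithm built for a different schema. Plans themselves
are declarable in one YAML document (schemas, sources, declarative
score/logical algorithms, decisions, actions, state names); predictive
algorithms are referenced by artefact path; transforms resolve through a
caller-supplied registry.

## Numerical and scale choices

Problem sizes in the test and acceptance runs — 1,000-admission cohorts for
the closed-loop and reviewer-recovery properties, 150 for mode equivalence,
100 for byte-level determinism, 600 for model training — were chosen as the
smallest sizes at which the stochastic tolerances (three binomial standard
errors) are meaningful while a full run stays comfortably interactive.
Hourly ticks are exact hours from each admission instant; ties at identical
timestamps resolve message-before-tick, then field precedence by collation
order. Severity maxima use the ordering Low < Moderate < High.

## Known limitations

- No HL7/FHIR parsing; inputs are delimited text, SQLite, or JSON messages.
- No authentication, distributed execution, HTTP API, or dashboard; the
  renderers emit static Mermaid/HTML/PNG artefacts.
- Missing-data handling is defaults-plus-pause; no imputation.
- The published hospital-scale counts motivating this design derive from
  data that is not distributable; the pipeline reproduces the *structure*
  of that analysis on synthetic cohorts with known truth.
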