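# wardflow

Data-driven clinical decision support as declarative, replayable workflows —
applied end-to-end to in-hospital triage of community-acquired pneumonia
(CAP).

## The problem

Hospital teams that triage acute admissions (here: a specialist pneumonia
nurse service) score disease severity by hand from scattered data — bloods,
vitals, confusion assessments — and inevitably miss or under-score patients
under clinical pressure. `wardflow` encodes the triage pathway as a *plan*:
a directed graph of determinative *steps*, each combining a schema-validated
data input, an algorithm (clinical risk score, ordered if/then rules, or an
embedded binary classifier), a *decision* routing the result to the next
step, and event-driven actions that record state or emit outcome messages.
An engine executes plans either by replaying stored admissions hour by hour
(retrospective evaluation) or by consuming a near-real-time message feed
(service mode) — the two modes produce identical journey logs on identical
data.

The package is for health-informatics engineers and quality-improvement
analysts who want to build, test and retrospectively evaluate such pathways
against synthetic or extracted hospital data.

## The core calculation

CAP severity uses the CURB65 score: one point for each of

    C  mental confusion
    U  blood urea > 7 mmol/L
    R  respiratory rate >= 30 /min
    B  systolic BP < 90 mmHg or diastolic BP <= 60 mmHg
    65 age >= 65 years

banded per NHS guidance into **Low** (0–1), **Moderate** (2), **High**
(3–5). The engine computes the score and band for every hour of every CAP
admission; the retrospective comparison links each admission's single manual
review (by anonymised patient id + admission-datetime window) to the
engine's *maximum* band over the stay and tallies the reviewer-band ×
engine-band pairs into a 3×3 cross-tab with agreement and under-scoring
summaries.

Around this sit: a simulated-admissions feed whose observations are sampled
conditional on a target severity band (so hourly replay provably recovers
the ground truth), a demonstration gradient-boosted mortality classifier
with cached performance metadata (AUC, sensitivity, specificity, accuracy,
PPV), a perturbation-based local explainer (ridge-regularised weighted
linear surrogate), and pure renderers producing Mermaid journey diagrams
and HTML panels.

## Worked example

Score one patient-hour:

```python
>>> from wardflow import curb65_score, stratify_severity
>>> r = curb65_score(confusion=False, urea=9.1, resp_rate=32,
...                  systolic_bp=118, diastolic_bp=76, age=78)
>>> r.value, stratify_severity(r.value)
(3, 'High')
```

The breakdown lists each factor (urea, respiratory rate and age are
satisfied; confusion and blood pressure are not), so the rendered panel can
show *why* the patient is High severity.

Simulate a cohort, replay it, and run the severity comparison from the
shell:

```sh
$ wardflow simulate --n 200 --seed 1 --out demo
wrote 5301 messages for 200 admissions (52 CAP, 26 reviewed) to demo
$ wardflow evaluate --store demo/messages.ndjson --reviews demo/reviews.csv --out demo_eval
Admissions: 200 total, 52 CAP
Reviewed: 26 (50.0% of CAP), 24 with a comparable manual score
Severity agreement: 24 (100.0% of compared pairs)
Engine High but reviewer Low/Moderate: 0 (0.0%)
Reviewer above engine: 0
Not reviewed: 26 (50.0% of CAP); moderate/high among them: 16

Reviewer band (rows) x engine band (columns):
engine    Low  Moderate  High
reviewer
Low         5         0     0
Moderate    0         7     0
High        0         0    12
```

With the default error-free simulated reviewer the cross-tab is exactly
diagonal (100% agreement); 2 of the 26 reviews carry no comparable manual
score and are reported in the reviewed/without-score split. Setting
`--reviewer-error 0.3` perturbs 30% of manual bands and the measured
disagreement fraction recovers that rate. `wardflow run-replay`, `wardflow
serve` and `wardflow report` replay a store, process a live stream, and
render journey diagrams/breakdowns respectively.

## Layout

- `src/wardflow/schema.py`, `sources.py`, `plan.py` — data model: fields,
  schemas, validation, collation, plans, structural checking
- `algorithms.py`, `curb65.py`, `metadata.py`, `explain.py`, `serialize.py`
  — the three algorithm modalities, CURB65 + banding, cached metrics,
  local explanations, portable artefacts
- `engine.py`, `store.py` — clock/journey execution, replay and stream
  modes, ndjson/CSV/SQLite stores
- `simulate.py`, `model.py` — the simulated-admissions feed and the
  demonstration mortality classifier
- `evaluation.py` — CAP identification, review linkage, severity cross-tab
- `reporting.py`, `config.py`, `cli.py` — renderers, YAML plan documents,
  command-line interface

See `docs/methods.md` for the underlying model, parameter choices and
limitations.
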