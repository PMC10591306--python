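"""The community-acquired pneumonia (CAP) management plan.

Journey shape: a triage step routes admissions by primary ICD-10 code
(J12–J18 = CAP); CAP admissions enter an hourly loop — CURB65 scoring with
severity banding, a severity-specific monitoring step, CRP stratification
and (optionally) an embedded mortality classifier — until the discharge
message finalises the journey at the ``discharged`` terminal step.
"""

from __future__ import annotations

from .algorithms import LogicalAlgorithm, Predicate, PredictiveAlgorithm, Rule
from .curb65 import curb65_algorithm, curb65_schema, severity_decision
from .plan import Action, Decision, EmitOutcome, Plan, Selector, SetState, Step
from .schema import DataField, DataSchema
from .sources import DataSource

#: Primary-position ICD-10 prefixes counted as CAP (configurable).
CAP_ICD_PREFIXES = ("J12", "J13", "J14", "J15", "J16", "J17", "J18")


def admission_schema() -> DataSchema:
    return DataSchema(
        name="admission",
        version="1",
        fields=(
            DataField("patient_id", "text"),
            DataField("age", "number", unit="years", required=True, allowed_range=(0, 130)),
            DataField("sex", "category", allowed_range=("F", "M")),
            DataField("primary_diagnosis", "text", required=True),
            DataField("secondary_diagnoses", "text"),
        ),
    )


def lab_schema() -> DataSchema:
    return DataSchema(
        name="lab",
        version="1",
        fields=(
            DataField("urea", "number", unit="mmol/L", allowed_range=(0, 100)),
            DataField("crp", "number", unit="mg/L", allowed_range=(0, 800)),
        ),
    )


def vital_schema() -> DataSchema:
    return DataSchema(
        name="vital",
        version="1",
        fields=(
            DataField("respiratory_rate", "integer", unit="breaths/min", allowed_range=(0, 80)),
            DataField("systolic_bp", "number", unit="mmHg", allowed_range=(30, 300)),
            DataField("diastolic_bp", "number", unit="mmHg", allowed_range=(10, 200)),
            DataField("confusion", "boolean"),
        ),
    )


def discharge_schema() -> DataSchema:
    return DataSchema(
        name="discharge",
        version="1",
        fields=(
            DataField("disposition", "category", allowed_range=("home", "deceased", "transfer")),
            DataField("died", "boolean"),
        ),
    )


def imaging_schema() -> DataSchema:
    return DataSchema(
        name="imaging_report",
        version="1",
        fields=(DataField("report_text", "text"), DataField("flagged", "boolean")),
    )


def crp_schema(stale_after: float | None = 24.0) -> DataSchema:
    return DataSchema(
        name="crp_input",
        version="1",
        fields=(
            DataField("crp", "number", unit="mg/L", required=True,
                      allowed_range=(0, 800), stale_after=stale_after),
        ),
    )


def mortality_schema(stale_after: float | None = 24.0) -> DataSchema:
    """Input schema of the demonstration mortality classifier."""
    return DataSchema(
        name="mortality_input",
        version="1",
        fields=(
            DataField("age", "number", unit="years", required=True, allowed_range=(0, 130)),
            DataField("urea", "number", unit="mmol/L", required=True,
                      allowed_range=(0, 100), stale_after=stale_after),
            DataField("respiratory_rate", "integer", unit="breaths/min", required=True,
                      allowed_range=(0, 80), stale_after=stale_after),
            DataField("systolic_bp", "number", unit="mmHg", required=True,
                      allowed_range=(30, 300), stale_after=stale_after),
            DataField("confusion", "boolean", required=True, stale_after=stale_after),
            DataField("crp", "number", unit="mg/L", required=True,
                      allowed_range=(0, 800), stale_after=stale_after),
        ),
    )


def cap_check_algorithm(cap_prefixes=CAP_ICD_PREFIXES) -> LogicalAlgorithm:
    """Route by primary diagnosis code: CAP prefix match vs everything else."""
    return LogicalAlgorithm(
        name="cap_check",
        schema=admission_schema(),
        rules=(Rule(Predicate("primary_diagnosis", "prefix_in", tuple(cap_prefixes)), "cap"),),
        default_label="not_cap",
    )


def crp_stratify_algorithm(high: float = 100.0, raised: float = 20.0) -> LogicalAlgorithm:
    """Stratify C-reactive protein: >=high 'high', >=raised 'raised', else 'normal'."""
    return LogicalAlgorithm(
        name="crp_stratify",
        schema=crp_schema(),
        rules=(
            Rule(Predicate("crp", "ge", high), "high"),
            Rule(Predicate("crp", "ge", raised), "raised"),
        ),
        default_label="normal",
    )


def cap_message_schemas() -> dict[str, DataSchema]:
    return {
        "admission": admission_schema(),
        "lab": lab_schema(),
        "vital": vital_schema(),
        "discharge": discharge_schema(),
        "imaging_report": imaging_schema(),
    }


def build_cap_plan(
    mortality: PredictiveAlgorithm | None = None,
    cap_prefixes=CAP_ICD_PREFIXES,
    lookback_hours: float = 24.0,
    **curb65_kwargs,
) -> Plan:
    """Assemble the CAP plan; ``mortality`` embeds a trained classifier step."""
    assess_source = DataSource("curb65_input", curb65_schema(stale_after=lookback_hours))
    triage_source = DataSource("admission", admission_schema())
    crp_source = DataSource("crp_input", crp_schema(stale_after=lookback_hours))

    monitor_next = "check_crp"
    after_crp = "predict_mortality" if mortality is not None else "assess"

    steps = {
        "triage": Step(
            name="triage",
            input=triage_source,
            algorithm=cap_check_algorithm(cap_prefixes),
            decision=Decision(
                options={"cap": "assess", "not_cap": "not_cap"},
                selector=Selector(kind="result_label"),
            ),
        ),
        "assess": Step(
            name="assess",
            input=assess_source,
            algorithm=curb65_algorithm(schema=curb65_schema(stale_after=lookback_hours), **curb65_kwargs),
            decision=severity_decision(
                {"Low": "monitor_low", "Moderate": "monitor_moderate", "High": "monitor_high"}
            ),
            actions=(
                Action("on_decision_made", SetState("severity", source="decision")),
                Action("on_decision_made", SetState("curb65", source="value")),
                Action("on_decision_actioned", EmitOutcome()),
            ),
        ),
        "monitor_low": Step(
            name="monitor_low",
            decision=Decision({"continue": monitor_next}, Selector("constant", label="continue")),
        ),
        "monitor_moderate": Step(
            name="monitor_moderate",
            decision=Decision({"continue": monitor_next}, Selector("constant", label="continue")),
        ),
        "monitor_high": Step(
            name="monitor_high",
            decision=Decision({"continue": monitor_next}, Selector("constant", label="continue")),
        ),
        "check_crp": Step(
            name="check_crp",
            input=crp_source,
            algorithm=crp_stratify_algorithm(),
            decision=Decision(
                options={"high": after_crp, "raised": after_crp, "normal": after_crp},
                selector=Selector(kind="result_label"),
            ),
            actions=(Action("on_decision_made", SetState("crp_band", source="decision")),),
        ),
        "not_cap": Step(name="not_cap", terminal=True),
        "discharged": Step(name="discharged", terminal=True),
    }
    states = ["severity", "curb65", "crp_band"]
    if mortality is not None:
        steps["predict_mortality"] = Step(
            name="predict_mortality",
            input=DataSource("mortality_input", mortality.schema),
            algorithm=mortality,
            decision=Decision(
                options={mortality.positive_label: "assess", mortality.negative_label: "assess"},
                selector=Selector(kind="result_label"),
            ),
            actions=(Action("on_decision_made", SetState("mortality_risk", source="value")),),
        )
        states.append("mortality_risk")

    return Plan(
        name="cap-management",
        steps=steps,
        start="triage",
        states=tuple(states),
        discharge_step="discharged",
    )
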