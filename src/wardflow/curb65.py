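"""CURB65 pneumonia severity scoring and NHS severity banding.

CURB65 awards one point for each of: mental Confusion; blood Urea above
7 mmol/L; Respiratory rate at or above 30 breaths/min; low Blood pressure
(systolic below 90 mmHg or diastolic at or below 60 mmHg); and age at or
over 65 years. The 0–5 score stratifies to a severity band:
Low = 0–1, Moderate = 2, High = 3–5.

Thresholds are overridable via :func:`curb65_algorithm` keyword arguments.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .algorithms import AlgorithmResult, Predicate, RiskFactor, ScoreAlgorithm, run_score
from .errors import InvalidValue, NoSeverityRecorded
from .plan import Decision, Selector
from .schema import DataField, DataSchema

SEVERITY_BANDS = ("Low", "Moderate", "High")

#: Inclusive score intervals for each band.
SEVERITY_BREAKPOINTS = ((0, 1, "Low"), (2, 2, "Moderate"), (3, 5, "High"))


def curb65_schema(stale_after: float | None = 24.0) -> DataSchema:
    """Input schema for CURB65: vitals/labs go stale, age does not."""
    return DataSchema(
        name="curb65_input",
        version="1",
        fields=(
            DataField("confusion", "boolean", required=True, stale_after=stale_after),
            DataField("urea", "number", unit="mmol/L", required=True,
                      allowed_range=(0, 100), stale_after=stale_after),
            DataField("respiratory_rate", "integer", unit="breaths/min", required=True,
                      allowed_range=(0, 80), stale_after=stale_after),
            DataField("systolic_bp", "number", unit="mmHg", required=True,
                      allowed_range=(30, 300), stale_after=stale_after),
            DataField("diastolic_bp", "number", unit="mmHg", required=True,
                      allowed_range=(10, 200), stale_after=stale_after),
            DataField("age", "number", unit="years", required=True, allowed_range=(0, 130)),
        ),
    )


def curb65_algorithm(
    urea_threshold: float = 7.0,
    resp_rate_threshold: float = 30,
    systolic_threshold: float = 90,
    diastolic_threshold: float = 60,
    age_threshold: float = 65,
    schema: DataSchema | None = None,
) -> ScoreAlgorithm:
    """Build the CURB65 score algorithm with standard (overridable) cut-offs:
    urea > 7 mmol/L; RR >= 30; SBP < 90 or DBP <= 60; age >= 65."""
    return ScoreAlgorithm(
        name="curb65",
        schema=schema or curb65_schema(),
        factors=(
            RiskFactor("confusion", (Predicate("confusion", "is_true"),)),
            RiskFactor("urea", (Predicate("urea", "gt", urea_threshold),)),
            RiskFactor("respiratory_rate", (Predicate("respiratory_rate", "ge", resp_rate_threshold),)),
            RiskFactor(
                "blood_pressure",
                (
                    Predicate("systolic_bp", "lt", systolic_threshold),
                    Predicate("diastolic_bp", "le", diastolic_threshold),
                ),
            ),
            RiskFactor("age", (Predicate("age", "ge", age_threshold),)),
        ),
    )


_DEFAULT_ALGO = None


def curb65_score(
    confusion: bool,
    urea: float,
    resp_rate: float,
    systolic_bp: float,
    diastolic_bp: float,
    age: float,
) -> AlgorithmResult:
    """Score one patient-hour; returns the 0–5 score with factor breakdown."""
    global _DEFAULT_ALGO
    if _DEFAULT_ALGO is None:
        _DEFAULT_ALGO = curb65_algorithm()
    return run_score(
        _DEFAULT_ALGO,
        {
            "confusion": confusion,
            "urea": urea,
            "respiratory_rate": resp_rate,
            "systolic_bp": systolic_bp,
            "diastolic_bp": diastolic_bp,
            "age": age,
        },
    )


def stratify_severity(score: int) -> str:
    """Band a CURB65 score: 0–1 Low, 2 Moderate, 3–5 High."""
    if isinstance(score, bool) or score != int(score):
        raise InvalidValue("curb65", f"score {score!r} is not an integer")
    score = int(score)
    for lo, hi, band in SEVERITY_BREAKPOINTS:
        if lo <= score <= hi:
            return band
    raise InvalidValue("curb65", f"score {score} outside 0–5")


def band_index(band: str) -> int:
    try:
        return SEVERITY_BANDS.index(band)
    except ValueError:
        raise InvalidValue("severity", f"unknown band {band!r}") from None


def max_band(bands: Iterable[str]) -> str:
    """Maximum severity band under the ordering Low < Moderate < High."""
    bands = list(bands)
    if not bands:
        raise NoSeverityRecorded("no severity bands supplied")
    return SEVERITY_BANDS[max(band_index(b) for b in bands)]


def severity_decision(options: Mapping[str, str]) -> Decision:
    """Decision routing a CURB65 result by severity band.

    ``options`` maps each band label (Low/Moderate/High) to a next-step name.
    """
    return Decision(
        options=dict(options),
        selector=Selector(kind="band", breakpoints=SEVERITY_BREAKPOINTS),
    )
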