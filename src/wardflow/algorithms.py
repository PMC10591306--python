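"""Algorithm modalities: clinical risk scores, ordered rules, classifiers.

Three kinds of algorithm can sit inside a plan step:

* :class:`ScoreAlgorithm` — a weighted count of satisfied risk-factor
  predicates (e.g. CURB65);
* :class:`LogicalAlgorithm` — ordered if/then comparisons yielding a label;
* :class:`PredictiveAlgorithm` — a trained binary classifier behind a
  schema-aware feature encoder, thresholded into two outcome labels.

All of them return an :class:`AlgorithmResult` carrying the value, a
per-factor/per-feature breakdown, and a rendering context.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field as dc_field
from typing import Any, Mapping, Sequence

import numpy as np

from .errors import InvalidValue, MissingField, SchemaMismatch
from .schema import DataSchema, validate_record

_BINARY_OPS = {
    "gt": operator.gt,
    "ge": operator.ge,
    "lt": operator.lt,
    "le": operator.le,
    "eq": operator.eq,
    "ne": operator.ne,
}


@dataclass
class AlgorithmResult:
    """Outcome of running an algorithm on one record."""

    value: Any
    breakdown: list[dict] = dc_field(default_factory=list)
    context: dict = dc_field(default_factory=dict)


@dataclass(frozen=True)
class Predicate:
    """A single comparison of a schema field against a constant.

    Supported operators: ``gt ge lt le eq ne`` (field vs ``value``),
    ``is_true`` (boolean field), ``in`` (membership in ``value``) and
    ``prefix_in`` (string field starts with any prefix in ``value`` —
    used for ICD-10 code-set membership).
    """

    field: str
    op: str
    value: Any = None

    def __post_init__(self):
        if self.op not in _BINARY_OPS and self.op not in ("is_true", "in", "prefix_in"):
            raise InvalidValue(self.field, f"unknown predicate operator {self.op!r}")

    def holds(self, record: Mapping[str, Any]) -> bool:
        if self.field not in record:
            raise MissingField(self.field)
        v = record[self.field]
        if self.op == "is_true":
            return bool(v)
        if self.op == "in":
            return v in self.value
        if self.op == "prefix_in":
            return any(str(v).startswith(str(p)) for p in self.value)
        return bool(_BINARY_OPS[self.op](v, self.value))

    def describe(self) -> str:
        if self.op == "is_true":
            return f"{self.field}"
        sym = {"gt": ">", "ge": ">=", "lt": "<", "le": "<=", "eq": "==", "ne": "!="}.get(self.op, self.op)
        return f"{self.field} {sym} {self.value}"

    def to_dict(self) -> dict:
        d: dict[str, Any] = {"field": self.field, "op": self.op}
        if self.value is not None:
            d["value"] = list(self.value) if isinstance(self.value, (tuple, frozenset, set)) else self.value
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "Predicate":
        value = d.get("value")
        if isinstance(value, list):
            value = tuple(value)
        return cls(field=d["field"], op=d["op"], value=value)


@dataclass(frozen=True)
class RiskFactor:
    """A named, weighted risk factor; satisfied when *any* predicate holds."""

    name: str
    predicates: tuple[Predicate, ...]
    weight: int = 1

    def __post_init__(self):
        object.__setattr__(self, "predicates", tuple(self.predicates))
        if not self.predicates:
            raise InvalidValue(self.name, "risk factor requires at least one predicate")
        if self.weight < 0:
            raise InvalidValue(self.name, "weight must be non-negative")

    def satisfied(self, record: Mapping[str, Any]) -> bool:
        return any(p.holds(record) for p in self.predicates)

    def describe(self) -> str:
        return " or ".join(p.describe() for p in self.predicates)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "weight": self.weight,
            "predicates": [p.to_dict() for p in self.predicates],
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RiskFactor":
        return cls(
            name=d["name"],
            weight=d.get("weight", 1),
            predicates=tuple(Predicate.from_dict(p) for p in d["predicates"]),
        )


@dataclass(frozen=True)
class ScoreAlgorithm:
    """Weighted risk-factor count; the maximum achievable score is the sum of
    weights and equals the upper bound of ``output_range``."""

    name: str
    schema: DataSchema
    factors: tuple[RiskFactor, ...]
    output_range: tuple[int, int] = None  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "factors", tuple(self.factors))
        max_score = sum(f.weight for f in self.factors)
        if self.output_range is None:
            object.__setattr__(self, "output_range", (0, max_score))
        elif self.output_range[1] != max_score or self.output_range[0] != 0:
            raise InvalidValue(
                self.name,
                f"output_range {self.output_range} inconsistent with factor weights (max {max_score})",
            )


@dataclass(frozen=True)
class Rule:
    """One ordered if/then comparison mapping a predicate to a label."""

    predicate: Predicate
    label: str

    def to_dict(self) -> dict:
        return {"predicate": self.predicate.to_dict(), "label": self.label}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "Rule":
        return cls(predicate=Predicate.from_dict(d["predicate"]), label=d["label"])


@dataclass(frozen=True)
class LogicalAlgorithm:
    """Ordered if/then rules; the first matching rule's label wins, falling
    back to ``default_label``."""

    name: str
    schema: DataSchema
    rules: tuple[Rule, ...]
    default_label: str = "default"

    def __post_init__(self):
        object.__setattr__(self, "rules", tuple(self.rules))

    @property
    def labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for r in self.rules:
            if r.label not in seen:
                seen.append(r.label)
        if self.default_label not in seen:
            seen.append(self.default_label)
        return tuple(seen)


@dataclass(frozen=True)
class FeatureEncoder:
    """Maps a validated record to a numeric feature vector, in declared order.

    ``scales`` are per-feature dispersion estimates (e.g. training-set
    standard deviations) used by the local explainer's perturbations.
    """

    features: tuple[str, ...]
    scales: tuple[float, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "features", tuple(self.features))
        if self.scales is not None:
            if len(self.scales) != len(self.features):
                raise SchemaMismatch("encoder scales length differs from feature count")
            object.__setattr__(self, "scales", tuple(float(s) for s in self.scales))

    @property
    def n_features(self) -> int:
        return len(self.features)

    def encode(self, record: Mapping[str, Any]) -> np.ndarray:
        values = []
        for name in self.features:
            if name not in record:
                raise MissingField(name)
            v = record[name]
            values.append(float(v) if not isinstance(v, bool) else float(int(v)))
        return np.asarray(values, dtype=float)

    def to_dict(self) -> dict:
        d: dict[str, Any] = {"features": list(self.features)}
        if self.scales is not None:
            d["scales"] = list(self.scales)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "FeatureEncoder":
        scales = d.get("scales")
        return cls(features=tuple(d["features"]), scales=tuple(scales) if scales else None)


@dataclass
class PredictiveAlgorithm:
    """A serialized binary classifier with encoder, threshold and metadata.

    ``model`` is any object exposing ``predict_proba`` over a 2-D array with
    the positive (mortality) class in column 1. A probability at or above
    ``threshold`` maps to ``positive_label``.
    """

    name: str
    schema: DataSchema
    encoder: FeatureEncoder
    model: Any
    threshold: float = 0.5
    metadata: Any = None  # ModelMetadata, kept loose to avoid import cycle
    positive_label: str = "LikelyMortality"
    negative_label: str = "LikelySurvival"

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise InvalidValue(self.name, f"threshold {self.threshold} outside (0, 1)")

    @property
    def labels(self) -> tuple[str, str]:
        return (self.negative_label, self.positive_label)

    def check_dimensions(self) -> None:
        n_in = getattr(self.model, "n_features_in_", None)
        if n_in is not None and int(n_in) != self.encoder.n_features:
            raise SchemaMismatch(
                f"encoder emits {self.encoder.n_features} features, model expects {int(n_in)}"
            )

    def predict_proba_row(self, x: np.ndarray) -> float:
        return float(self.model.predict_proba(x.reshape(1, -1))[0, 1])


def run_score(algo: ScoreAlgorithm, record: Mapping[str, Any]) -> AlgorithmResult:
    """Run a score algorithm: validate, evaluate every factor, sum weights."""
    vr = validate_record(algo.schema, record)
    breakdown = []
    total = 0
    for f in algo.factors:
        sat = f.satisfied(vr)
        points = f.weight if sat else 0
        total += points
        breakdown.append(
            {
                "factor": f.name,
                "criterion": f.describe(),
                "satisfied": sat,
                "weight": f.weight,
                "points": points,
            }
        )
    return AlgorithmResult(
        value=total,
        breakdown=breakdown,
        context={"kind": "score", "algorithm": algo.name, "max_score": algo.output_range[1]},
    )


def run_logical(algo: LogicalAlgorithm, record: Mapping[str, Any]) -> AlgorithmResult:
    """Run ordered if/then rules; first match wins, else the default label."""
    vr = validate_record(algo.schema, record)
    label = algo.default_label
    breakdown = []
    matched = False
    for r in algo.rules:
        hit = (not matched) and r.predicate.holds(vr)
        breakdown.append({"rule": r.predicate.describe(), "label": r.label, "matched": hit})
        if hit:
            label = r.label
            matched = True
    return AlgorithmResult(
        value=label,
        breakdown=breakdown,
        context={"kind": "logical", "algorithm": algo.name, "label": label},
    )


def run_predictive(algo: PredictiveAlgorithm, record: Mapping[str, Any]) -> AlgorithmResult:
    """Run the classifier: validate, encode, score, threshold into a label."""
    vr = validate_record(algo.schema, record)
    algo.check_dimensions()
    x = algo.encoder.encode(vr)
    prob = algo.predict_proba_row(x)
    label = algo.positive_label if prob >= algo.threshold else algo.negative_label
    breakdown = [
        {"feature": name, "value": float(v)} for name, v in zip(algo.encoder.features, x)
    ]
    return AlgorithmResult(
        value=prob,
        breakdown=breakdown,
        context={
            "kind": "predictive",
            "algorithm": algo.name,
            "label": label,
            "threshold": algo.threshold,
            "probabilities": {algo.positive_label: prob, algo.negative_label: 1.0 - prob},
        },
    )


def run_algorithm(algo: Any, record: Mapping[str, Any]) -> AlgorithmResult:
    """Dispatch on algorithm modality."""
    if isinstance(algo, ScoreAlgorithm):
        return run_score(algo, record)
    if isinstance(algo, LogicalAlgorithm):
        return run_logical(algo, record)
    if isinstance(algo, PredictiveAlgorithm):
        return run_predictive(algo, record)
    raise InvalidValue("algorithm", f"unsupported algorithm type {type(algo).__name__}")
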