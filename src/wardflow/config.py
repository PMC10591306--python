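"""Plan configuration documents.

A plan can be declared in a single YAML document — schemas, sources,
algorithms, steps with decisions and actions, state names — so evaluation
and service modes share one definition. Score and logical algorithms are
fully declarative; predictive algorithms are referenced by the path of a
serialized artefact (see :mod:`wardflow.serialize`). Named transforms are
resolved through a caller-supplied registry.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Callable, Mapping

import yaml

from .algorithms import LogicalAlgorithm, RiskFactor, Rule, ScoreAlgorithm
from .errors import InvalidValue
from .plan import Action, Decision, EmitOutcome, Plan, Selector, SetState, Step
from .schema import DataSchema
from .serialize import load_algorithm
from .sources import DataSource, Transform


def _selector_from_dict(d: Mapping[str, Any]) -> Selector:
    kind = d["kind"]
    if kind == "band":
        return Selector(kind="band", breakpoints=tuple((int(lo), int(hi), str(lb)) for lo, hi, lb in d["breakpoints"]))
    if kind == "constant":
        return Selector(kind="constant", label=d["label"])
    if kind == "result_label":
        return Selector(kind="result_label")
    raise InvalidValue("selector", f"selector kind {kind!r} not declarable in config")


def _selector_to_dict(s: Selector) -> dict:
    if s.kind == "band":
        return {"kind": "band", "breakpoints": [list(bp) for bp in s.breakpoints]}
    if s.kind == "constant":
        return {"kind": "constant", "label": s.label}
    if s.kind == "result_label":
        return {"kind": "result_label"}
    raise InvalidValue("selector", "custom selectors are not serializable")


def _action_from_dict(d: Mapping[str, Any]) -> Action:
    effect = d["effect"]
    if effect["type"] == "set_state":
        eff = SetState(
            state=effect["state"],
            source=effect.get("source", "value"),
            constant=effect.get("constant"),
        )
    elif effect["type"] == "emit_outcome":
        eff = EmitOutcome(kind=effect.get("kind", "outcome"))
    else:
        raise InvalidValue("action", f"unknown effect type {effect['type']!r}")
    return Action(trigger=d["trigger"], effect=eff)


def _action_to_dict(a: Action) -> dict:
    if isinstance(a.effect, SetState):
        eff: dict[str, Any] = {"type": "set_state", "state": a.effect.state, "source": a.effect.source}
        if a.effect.constant is not None:
            eff["constant"] = a.effect.constant
    else:
        eff = {"type": "emit_outcome", "kind": a.effect.kind}
    return {"trigger": a.trigger, "effect": eff}


def plan_from_dict(
    doc: Mapping[str, Any],
    transform_registry: Mapping[str, Callable[[dict], dict]] | None = None,
    artefact_root: str | Path = ".",
) -> Plan:
    """Build a plan from a configuration tree (see :func:`plan_to_dict`)."""
    registry = transform_registry or {}
    schemas = {name: DataSchema.from_dict({"name": name, **sd}) for name, sd in doc.get("schemas", {}).items()}

    def _resolve_transforms(names):
        out = []
        for n in names:
            if n not in registry:
                raise InvalidValue(n, "transform not found in registry")
            out.append(Transform(n, registry[n]))
        return tuple(out)

    sources: dict[str, DataSource] = {}
    for name, sd in doc.get("sources", {}).items():
        sources[name] = DataSource(
            name=name,
            schema=schemas[sd["schema"]],
            transforms=_resolve_transforms(sd.get("transforms", [])),
            constituents=tuple(sources[c] for c in sd.get("constituents", [])),
        )

    algorithms: dict[str, Any] = {}
    for name, ad in doc.get("algorithms", {}).items():
        atype = ad["type"]
        if atype == "score":
            algorithms[name] = ScoreAlgorithm(
                name=name,
                schema=schemas[ad["schema"]],
                factors=tuple(RiskFactor.from_dict(f) for f in ad["factors"]),
            )
        elif atype == "logical":
            algorithms[name] = LogicalAlgorithm(
                name=name,
                schema=schemas[ad["schema"]],
                rules=tuple(Rule.from_dict(r) for r in ad["rules"]),
                default_label=ad.get("default_label", "default"),
            )
        elif atype == "predictive":
            algorithms[name] = load_algorithm(
                Path(artefact_root) / ad["artefact"],
                expected_schema_version=ad.get("schema_version"),
            )
        else:
            raise InvalidValue(name, f"unknown algorithm type {atype!r}")

    steps: dict[str, Step] = {}
    for name, sd in doc["steps"].items():
        decision = None
        if "decision" in sd:
            decision = Decision(
                options=dict(sd["decision"]["options"]),
                selector=_selector_from_dict(sd["decision"]["selector"]),
            )
        steps[name] = Step(
            name=name,
            input=sources[sd["input"]] if sd.get("input") else None,
            algorithm=algorithms[sd["algorithm"]] if sd.get("algorithm") else None,
            decision=decision,
            actions=tuple(_action_from_dict(a) for a in sd.get("actions", [])),
            terminal=sd.get("terminal", False),
        )

    return Plan(
        name=doc["name"],
        steps=steps,
        start=doc["start"],
        states=tuple(doc.get("states", [])),
        discharge_step=doc.get("discharge_step"),
    )


def plan_to_dict(plan: Plan) -> dict:
    """Serialize a plan (score/logical algorithms only) to a config tree."""
    schemas: dict[str, dict] = {}
    sources: dict[str, dict] = {}
    algorithms: dict[str, dict] = {}

    def _register_schema(schema: DataSchema) -> str:
        d = schema.to_dict()
        name = d.pop("name")
        schemas[name] = d
        return name

    steps: dict[str, dict] = {}
    for step in plan.steps.values():
        sd: dict[str, Any] = {}
        if step.input is not None:
            src = step.input
            sources[src.name] = {
                "schema": _register_schema(src.schema),
                "transforms": [t.name for t in src.transforms],
            }
            sd["input"] = src.name
        if step.algorithm is not None:
            algo = step.algorithm
            if isinstance(algo, ScoreAlgorithm):
                algorithms[algo.name] = {
                    "type": "score",
                    "schema": _register_schema(algo.schema),
                    "factors": [f.to_dict() for f in algo.factors],
                }
            elif isinstance(algo, LogicalAlgorithm):
                algorithms[algo.name] = {
                    "type": "logical",
                    "schema": _register_schema(algo.schema),
                    "rules": [r.to_dict() for r in algo.rules],
                    "default_label": algo.default_label,
                }
            else:
                raise InvalidValue(
                    algo.name, "predictive algorithms serialize via artefacts, not plan config"
                )
            sd["algorithm"] = algo.name
        if step.decision is not None:
            sd["decision"] = {
                "options": dict(step.decision.options),
                "selector": _selector_to_dict(step.decision.selector),
            }
        if step.actions:
            sd["actions"] = [_action_to_dict(a) for a in step.actions]
        if step.terminal:
            sd["terminal"] = True
        steps[step.name] = sd

    return {
        "name": plan.name,
        "start": plan.start,
        "states": list(plan.states),
        "discharge_step": plan.discharge_step,
        "schemas": schemas,
        "sources": sources,
        "algorithms": algorithms,
        "steps": steps,
    }


def plan_from_yaml(path: str | Path, **kwargs) -> Plan:
    with Path(path).open() as fh:
        return plan_from_dict(yaml.safe_load(fh), **kwargs)


def plan_to_yaml(plan: Plan, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        yaml.safe_dump(plan_to_dict(plan), fh, sort_keys=True)
    return path
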