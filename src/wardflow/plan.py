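"""Declarative workflow plans: steps, decisions, actions, structural checks.

A :class:`Plan` is a directed graph of named :class:`Step` objects. Each
non-terminal step couples a data input, an algorithm, a :class:`Decision`
that maps the algorithm's result onto a successor step, and event-driven
:class:`Action` hooks. :func:`check_plan` reports structural faults
(unreachable steps, dangling decision targets, non-total selectors, dead
ends) without raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Any, Callable, Mapping

import networkx as nx

from .algorithms import (
    AlgorithmResult,
    LogicalAlgorithm,
    PredictiveAlgorithm,
    ScoreAlgorithm,
)
from .errors import InvalidValue
from .sources import DataSource

TRIGGERS = ("on_data", "on_result", "on_decision_made", "on_decision_actioned")


@dataclass(frozen=True)
class Selector:
    """Total rule mapping an :class:`AlgorithmResult` to one option label.

    Kinds:

    * ``band`` — integer result binned by inclusive ``(lo, hi, label)``
      breakpoints (risk-score banding);
    * ``result_label`` — the result's own label (logical / predictive
      algorithms) used directly as the option label;
    * ``constant`` — always ``label`` (pass-through steps);
    * ``custom`` — arbitrary ``func(result) -> label`` (not serializable).
    """

    kind: str
    breakpoints: tuple[tuple[int, int, str], ...] = ()
    label: str = ""
    func: Callable[[AlgorithmResult], str] | None = None

    def __post_init__(self):
        if self.kind not in ("band", "result_label", "constant", "custom"):
            raise InvalidValue("selector", f"unknown selector kind {self.kind!r}")
        object.__setattr__(self, "breakpoints", tuple(tuple(bp) for bp in self.breakpoints))

    def select(self, result: AlgorithmResult | None) -> str:
        if self.kind == "constant":
            return self.label
        if result is None:
            raise InvalidValue("selector", "non-constant selector requires a result")
        if self.kind == "band":
            v = result.value
            if isinstance(v, bool) or v != int(v):
                raise InvalidValue("selector", f"band selector requires an integer, got {v!r}")
            for lo, hi, label in self.breakpoints:
                if lo <= int(v) <= hi:
                    return label
            raise InvalidValue("selector", f"value {v} outside all bands")
        if self.kind == "result_label":
            return str(result.context.get("label", result.value))
        return self.func(result)  # custom

    def labels(self) -> tuple[str, ...]:
        if self.kind == "band":
            out: list[str] = []
            for _, _, label in self.breakpoints:
                if label not in out:
                    out.append(label)
            return tuple(out)
        if self.kind == "constant":
            return (self.label,)
        return ()


@dataclass(frozen=True)
class Decision:
    """Non-empty map from option label to next-step name plus a selector."""

    options: Mapping[str, str]
    selector: Selector

    def __post_init__(self):
        object.__setattr__(self, "options", dict(self.options))
        if not self.options:
            raise InvalidValue("decision", "decision requires at least one option")

    def select(self, result: AlgorithmResult | None) -> str:
        label = self.selector.select(result)
        if label not in self.options:
            raise InvalidValue("decision", f"selected label {label!r} not among options")
        return label

    def next_step(self, label: str) -> str:
        return self.options[label]


@dataclass(frozen=True)
class SetState:
    """Write a state value on the owning journey.

    ``source`` selects what is written: ``value`` (result value),
    ``decision`` (chosen option label), or ``constant``.
    """

    state: str
    source: str = "value"
    constant: Any = None

    def __post_init__(self):
        if self.source not in ("value", "decision", "constant"):
            raise InvalidValue(self.state, f"unknown state source {self.source!r}")


@dataclass(frozen=True)
class EmitOutcome:
    """Send an outbound outcome message carrying the step's result."""

    kind: str = "outcome"


@dataclass(frozen=True)
class Action:
    """An effect fired at a trigger point within step execution.

    ``on_decision_made`` effects run after the decision label is selected and
    *before* the journey advances to the successor step.
    """

    trigger: str
    effect: SetState | EmitOutcome

    def __post_init__(self):
        if self.trigger not in TRIGGERS:
            raise InvalidValue("action", f"unknown trigger {self.trigger!r}")


@dataclass(frozen=True)
class Step:
    """A determinative unit: data input + algorithm + decision + actions.

    Terminal steps carry no decision; non-terminal steps must carry one.
    A ``None`` algorithm yields a ``None`` result (pass-through steps).
    """

    name: str
    input: DataSource | None = None
    algorithm: Any = None
    decision: Decision | None = None
    actions: tuple[Action, ...] = ()
    terminal: bool = False

    def __post_init__(self):
        object.__setattr__(self, "actions", tuple(self.actions))


@dataclass(frozen=True)
class Fault:
    """One structural fault found by :func:`check_plan`."""

    kind: str
    subject: str
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.kind}: {self.subject}" + (f" ({self.detail})" if self.detail else "")


@dataclass(frozen=True)
class Plan:
    """Named container of steps with a designated start and state variables.

    ``discharge_step`` names the terminal step every journey jumps to when a
    discharge message arrives; for dead-end analysis it acts as an implicit
    successor of every non-terminal step, because hourly-assessment loops
    (assess/monitor cycles) only ever exit through it.
    """

    name: str
    steps: Mapping[str, Step]
    start: str
    states: tuple[str, ...] = ()
    discharge_step: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "steps", dict(self.steps))
        object.__setattr__(self, "states", tuple(self.states))
        for key, step in self.steps.items():
            if key != step.name:
                raise InvalidValue(key, f"step registered under {key!r} is named {step.name!r}")

    def graph(self, include_discharge_edges: bool = False) -> nx.DiGraph:
        """Decision-edge graph; optionally add implicit discharge edges."""
        g = nx.DiGraph()
        g.add_nodes_from(self.steps)
        for step in self.steps.values():
            if step.decision is not None:
                for label, target in step.decision.options.items():
                    if target in self.steps:
                        g.add_edge(step.name, target, label=label)
            if include_discharge_edges and not step.terminal and self.discharge_step in self.steps:
                g.add_edge(step.name, self.discharge_step, label="(discharge)")
        return g


def _selector_faults(step: Step) -> list[Fault]:
    """Check selector totality against the step's algorithm output range."""
    faults: list[Fault] = []
    dec, algo = step.decision, step.algorithm
    sel = dec.selector
    for label in sel.labels():
        if label not in dec.options:
            faults.append(Fault("non-total-selector", step.name, f"label {label!r} has no option"))
    if sel.kind == "band" and isinstance(algo, ScoreAlgorithm):
        lo, hi = algo.output_range
        covered = {
            v for bp_lo, bp_hi, _ in sel.breakpoints for v in range(bp_lo, bp_hi + 1)
        }
        missing = sorted(set(range(lo, hi + 1)) - covered)
        if missing:
            faults.append(
                Fault("non-total-selector", step.name, f"scores {missing} map to no band")
            )
    elif sel.kind == "result_label" and isinstance(algo, LogicalAlgorithm):
        for label in algo.labels:
            if label not in dec.options:
                faults.append(
                    Fault("non-total-selector", step.name, f"rule label {label!r} has no option")
                )
    elif sel.kind == "result_label" and isinstance(algo, PredictiveAlgorithm):
        for label in algo.labels:
            if label not in dec.options:
                faults.append(
                    Fault("non-total-selector", step.name, f"class label {label!r} has no option")
                )
    return faults


def check_plan(plan: Plan) -> list[Fault]:
    """Return all structural faults of ``plan`` (empty list = valid).

    Checks: start exists; decision targets exist; terminal steps carry no
    decision and non-terminal steps carry one; every step is reachable from
    start; a terminal step is reachable from every step (counting the
    implicit discharge edge); selectors are total over their algorithm's
    output range; actions reference declared state variables.
    """
    faults: list[Fault] = []
    if plan.start not in plan.steps:
        faults.append(Fault("missing-start", plan.start))
        return faults

    for step in plan.steps.values():
        if step.terminal and step.decision is not None:
            faults.append(Fault("terminal-has-decision", step.name))
        if not step.terminal and step.decision is None:
            faults.append(Fault("no-decision", step.name, "non-terminal step cannot advance"))
        if step.decision is not None:
            for label, target in step.decision.options.items():
                if target not in plan.steps:
                    faults.append(Fault("dangling-target", target, f"from {step.name}[{label}]"))
            faults.extend(_selector_faults(step))
        for action in step.actions:
            if isinstance(action.effect, SetState) and action.effect.state not in plan.states:
                faults.append(
                    Fault("unknown-state", action.effect.state, f"written by {step.name}")
                )

    # the implicit discharge edge counts for reachability and dead-end
    # analysis: any non-terminal step can be exited by a discharge message
    g_dis = plan.graph(include_discharge_edges=True)
    reachable = {plan.start} | nx.descendants(g_dis, plan.start)
    for name in plan.steps:
        if name not in reachable:
            faults.append(Fault("unreachable", name))

    terminals = {s.name for s in plan.steps.values() if s.terminal}
    for name in sorted(reachable):
        if name in terminals:
            continue
        if not (({name} | nx.descendants(g_dis, name)) & terminals):
            faults.append(Fault("dead-end", name, "no terminal step reachable"))
    return faults
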