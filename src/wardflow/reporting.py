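"""Rendered decision-support artefacts.

All renderers are pure functions of their inputs: identical inputs produce
byte-identical documents. Journey diagrams are emitted as Mermaid-dialect
flowchart text; tabular artefacts as plain HTML via string templates.
:class:`RenderContext` memoises one rendering so cached artefacts can be
served without recomputation (and, for model panels, without the model).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Any, Callable, Mapping

from .algorithms import AlgorithmResult
from .engine import Journey
from .errors import InconsistentJourney, MissingMetric, NoBreakdown
from .metadata import ModelMetadata
from .plan import Plan


@dataclass
class RenderContext:
    """Lazily rendered, cached document."""

    subject: Any
    format: str
    _render: Callable[[], str] = None  # type: ignore[assignment]
    cached: bool = False
    _payload: str | None = None

    def get(self) -> str:
        if not self.cached:
            self._payload = self._render()
            self.cached = True
        return self._payload


def _check_journey(journey: Journey, plan: Plan) -> None:
    for visit in journey.visited:
        if visit.step not in plan.steps:
            raise InconsistentJourney(f"step {visit.step!r} not in plan {plan.name!r}")
    for a, b in zip(journey.visited, journey.visited[1:]):
        step = plan.steps[a.step]
        targets = set(step.decision.options.values()) if step.decision else set()
        if plan.discharge_step:
            targets.add(plan.discharge_step)
        if b.step not in targets and b.step != a.step:
            raise InconsistentJourney(f"no edge {a.step!r} -> {b.step!r} in plan")


def render_journey(
    journey: Journey,
    plan: Plan,
    direct_route_only: bool = False,
    show_sources: bool = False,
) -> str:
    """Flowchart markup (Mermaid dialect) of the journey within its plan.

    Visited steps are highlighted; traversed edges are annotated with the
    decision label. ``direct_route_only`` drops unvisited steps;
    ``show_sources`` adds each step's data source as a dashed satellite node.
    """
    _check_journey(journey, plan)
    visited_steps = [v.step for v in journey.visited]
    visited_set = set(visited_steps) or {plan.start}
    taken_edges: dict[tuple[str, str], str] = {}
    for a, b in zip(journey.visited, journey.visited[1:]):
        taken_edges.setdefault((a.step, b.step), a.decision or "")

    lines = ["flowchart TD"]
    shown = visited_set if direct_route_only else set(plan.steps)
    for name in sorted(shown):
        step = plan.steps.get(name)
        shape = f"{name}([{name}])" if step is not None and step.terminal else f"{name}[{name}]"
        lines.append(f"    {shape}")
        if show_sources and step is not None and step.input is not None:
            lines.append(f"    {name}_src[({step.input.name})]")
            lines.append(f"    {name}_src -.-> {name}")
    for name in sorted(shown):
        step = plan.steps.get(name)
        if step is None or step.decision is None:
            continue
        for label, target in sorted(step.decision.options.items()):
            if target not in shown:
                continue
            if (name, target) in taken_edges:
                continue  # drawn below with its decision annotation
            lines.append(f"    {name} -->|{label}| {target}")
    for (a, b), label in sorted(taken_edges.items()):
        annotation = f"|{label}|" if label else ""
        lines.append(f"    {a} =={annotation}==> {b}")
    lines.append("    classDef visited fill:#cde6cd,stroke:#2f6f2f,stroke-width:2px;")
    if visited_set:
        lines.append("    class " + ",".join(sorted(visited_set)) + " visited;")
    return "\n".join(lines) + "\n"


_TABLE_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title></head>
<body>
<h2>{title}</h2>
<table border="1" cellspacing="0" cellpadding="4">
<tr>{header}</tr>
{rows}
</table>
{footer}
</body></html>
"""


def _table(title: str, header: list[str], rows: list[list[str]], footer: str = "") -> str:
    head = "".join(f"<th>{h}</th>" for h in header)
    body = "\n".join("<tr>" + "".join(f"<td>{c}</td>" for c in row) + "</tr>" for row in rows)
    return _TABLE_TEMPLATE.format(title=title, header=head, rows=body, footer=footer)


def render_factor_breakdown(result: AlgorithmResult) -> str:
    """HTML listing each risk factor, its criterion, satisfied flag and points."""
    if result.context.get("kind") != "score" or not result.breakdown:
        raise NoBreakdown("result carries no per-factor score breakdown")
    total = sum(item["points"] for item in result.breakdown)
    if total != result.value:
        raise NoBreakdown(f"breakdown points {total} do not sum to value {result.value}")
    rows = [
        [item["factor"], item["criterion"], "yes" if item["satisfied"] else "no", str(item["points"])]
        for item in result.breakdown
    ]
    footer = (
        f"<p>Total: <b>{result.value}</b> of {result.context.get('max_score', '?')}</p>"
    )
    return _table(
        f"Risk factor breakdown — {result.context.get('algorithm', '')}",
        ["Factor", "Criterion", "Satisfied", "Points"],
        rows,
        footer,
    )


def render_prediction(result: AlgorithmResult, explanation: Mapping[str, float]) -> str:
    """HTML with both class probabilities and signed feature contributions
    ordered by decreasing magnitude."""
    probs = result.context.get("probabilities", {})
    prob_rows = [[label, f"{p:.3f}"] for label, p in sorted(probs.items(), key=lambda kv: -kv[1])]
    contribs = sorted(explanation.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    contrib_rows = [[name, f"{value:+.4f}"] for name, value in contribs]
    head = "".join(f"<th>{h}</th>" for h in ["Class", "Probability"])
    prob_html = "\n".join(
        "<tr>" + "".join(f"<td>{c}</td>" for c in row) + "</tr>" for row in prob_rows
    )
    footer = (
        "<h3>Local explanation</h3>"
        "<table border=\"1\" cellspacing=\"0\" cellpadding=\"4\">"
        "<tr><th>Feature</th><th>Contribution</th></tr>"
        + "".join("<tr>" + "".join(f"<td>{c}</td>" for c in row) + "</tr>" for row in contrib_rows)
        + "</table>"
        f"<p>Predicted: <b>{result.context.get('label', '')}</b> "
        f"(threshold {result.context.get('threshold', '')})</p>"
    )
    return _TABLE_TEMPLATE.format(
        title=f"Prediction — {result.context.get('algorithm', '')}",
        header=head,
        rows=prob_html,
        footer=footer,
    )


def render_model_panel(metadata: ModelMetadata) -> str:
    """HTML panel of the five performance indicators, 3-decimal formatted.

    Needs only cached metadata — never the model itself.
    """
    if metadata is None:
        raise MissingMetric("no model metadata available")
    rows = []
    display = {
        "auc": "Area under the curve",
        "sensitivity": "Sensitivity",
        "specificity": "Specificity",
        "accuracy": "Accuracy",
        "positive_predictive_value": "Predictive power (PPV)",
    }
    for attr, label in display.items():
        value = getattr(metadata, attr, None)
        if value is None:
            raise MissingMetric(attr)
        rows.append([label, f"{value:.3f}"])
    footer = f"<p>Computed on: {metadata.computed_on or 'n/a'}</p>"
    return _table("Model performance", ["Indicator", "Value"], rows, footer)


def plot_prediction(result: AlgorithmResult, path) -> None:
    """Optional raster export of the class-probability bars (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    probs = result.context.get("probabilities", {})
    labels = sorted(probs, key=lambda k: -probs[k])
    fig, ax = plt.subplots(figsize=(4, 2.2))
    ax.barh(labels, [probs[k] for k in labels], color=["#b03a2e", "#2e86c1"][: len(labels)])
    ax.set_xlim(0, 1)
    ax.set_xlabel("probability")
    fig.tight_layout()
    fig.savefig(path, metadata={})
    plt.close(fig)
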