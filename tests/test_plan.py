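"""Plan structure checking against a brute-force reachability oracle."""

import pytest

from wardflow.algorithms import LogicalAlgorithm, Predicate, Rule
from wardflow.plan import Decision, Plan, Selector, Step, check_plan
from wardflow.schema import DataField, DataSchema


def passthrough(name, target):
    return Step(name=name, decision=Decision({"go": target}, Selector("constant", label="go")))


def linear_plan():
    return Plan(
        name="linear",
        steps={
            "a": passthrough("a", "b"),
            "b": passthrough("b", "end"),
            "end": Step(name="end", terminal=True),
        },
        start="a",
    )


def bfs_reachable(plan, origin):
    """Independent brute-force reachability over decision edges."""
    seen, frontier = {origin}, [origin]
    while frontier:
        node = frontier.pop()
        step = plan.steps.get(node)
        if step is None or step.decision is None:
            continue
        for target in step.decision.options.values():
            if target in plan.steps and target not in seen:
                seen.add(target)
                frontier.append(target)
    return seen


class TestCheckPlan:
    def test_linear_plan_is_valid(self):
        assert check_plan(linear_plan()) == []

    def test_dangling_decision_target(self):
        plan = Plan(
            name="p",
            steps={
                "a": passthrough("a", "ghost"),
                "end": Step(name="end", terminal=True),
            },
            start="a",
        )
        faults = check_plan(plan)
        assert any(f.kind == "dangling-target" and f.subject == "ghost" for f in faults)

    def test_unreachable_step_matches_bfs_oracle(self):
        plan = Plan(
            name="p",
            steps={
                "a": passthrough("a", "end"),
                "b": passthrough("b", "end"),  # not reachable from start
                "end": Step(name="end", terminal=True),
            },
            start="a",
        )
        faults = check_plan(plan)
        flagged = {f.subject for f in faults if f.kind == "unreachable"}
        assert flagged == set(plan.steps) - bfs_reachable(plan, "a") == {"b"}

    def test_terminal_with_decision_and_missing_start(self):
        bad_terminal = Plan(
            name="p",
            steps={
                "a": Step(
                    name="a",
                    terminal=True,
                    decision=Decision({"go": "a"}, Selector("constant", label="go")),
                )
            },
            start="a",
        )
        assert any(f.kind == "terminal-has-decision" for f in check_plan(bad_terminal))
        no_start = Plan(name="p", steps={"end": Step(name="end", terminal=True)}, start="zzz")
        assert [f.kind for f in check_plan(no_start)] == ["missing-start"]

    def test_dead_end_cycle_without_discharge_step(self):
        plan = Plan(
            name="p",
            steps={
                "a": passthrough("a", "b"),
                "b": passthrough("b", "a"),
            },
            start="a",
        )
        dead = {f.subject for f in check_plan(plan) if f.kind == "dead-end"}
        assert dead == {"a", "b"}

    def test_discharge_step_rescues_assessment_cycles(self):
        plan = Plan(
            name="p",
            steps={
                "a": passthrough("a", "b"),
                "b": passthrough("b", "a"),
                "out": Step(name="out", terminal=True),
            },
            start="a",
            discharge_step="out",
        )
        assert check_plan(plan) == []

    def test_non_total_selector_over_logical_labels(self):
        schema = DataSchema("s", (DataField("crp", "number", required=True),))
        algo = LogicalAlgorithm(
            "crp", schema, rules=(Rule(Predicate("crp", "ge", 100), "high"),), default_label="normal"
        )
        plan = Plan(
            name="p",
            steps={
                "a": Step(
                    name="a",
                    algorithm=algo,
                    decision=Decision({"high": "end"}, Selector("result_label")),
                ),
                "end": Step(name="end", terminal=True),
            },
            start="a",
        )
        faults = check_plan(plan)
        assert any(f.kind == "non-total-selector" and "normal" in f.detail for f in faults)

    def test_unknown_state_write_flagged(self):
        from wardflow.plan import Action, SetState

        plan = Plan(
            name="p",
            steps={
                "a": Step(
                    name="a",
                    decision=Decision({"go": "end"}, Selector("constant", label="go")),
                    actions=(Action("on_decision_made", SetState("mystery")),),
                ),
                "end": Step(name="end", terminal=True),
            },
            start="a",
        )
        assert any(f.kind == "unknown-state" for f in check_plan(plan))

    def test_cap_plan_reachability_matches_oracle(self, cap_plan):
        assert check_plan(cap_plan) == []
        # every step is reachable once the implicit discharge edge is counted
        reachable = bfs_reachable(cap_plan, cap_plan.start) | {cap_plan.discharge_step}
        assert reachable == set(cap_plan.steps)


class TestSelector:
    def test_band_selector_requires_integer(self):
        from wardflow.algorithms import AlgorithmResult
        from wardflow.errors import InvalidValue

        sel = Selector("band", breakpoints=((0, 1, "Low"), (2, 5, "High")))
        assert sel.select(AlgorithmResult(value=1)) == "Low"
        with pytest.raises(InvalidValue):
            sel.select(AlgorithmResult(value=1.5))
        with pytest.raises(InvalidValue):
            sel.select(AlgorithmResult(value=9))

    def test_decision_rejects_label_outside_options(self):
        from wardflow.algorithms import AlgorithmResult
        from wardflow.errors import InvalidValue

        dec = Decision({"Low": "x"}, Selector("band", breakpoints=((0, 5, "Other"),)))
        with pytest.raises(InvalidValue):
            dec.select(AlgorithmResult(value=3))
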