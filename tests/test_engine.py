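"""Engine execution: ticks, pause/resume, discharge, isolation, replay."""

from datetime import datetime, timedelta

import pytest

from wardflow.capplan import build_cap_plan, cap_message_schemas
from wardflow.engine import Engine, Message
from wardflow.store import ReplayStore

T0 = datetime(2022, 4, 1, 8, 0)


def make_engine(**kwargs):
    return Engine(build_cap_plan(), message_schemas=cap_message_schemas(), **kwargs)


def admission_msg(adm="A1", age=70.0, code="J18.1", at=T0):
    return Message(
        "admission",
        adm,
        at,
        {"patient_id": "P1", "age": age, "sex": "F", "primary_diagnosis": code},
    )


def obs_msgs(adm="A1", at=T0, urea=5.0, rr=16, sbp=120.0, dbp=80.0, conf=False, crp=10.0):
    return [
        Message("lab", adm, at, {"urea": urea, "crp": crp}),
        Message("vital", adm, at, {"respiratory_rate": rr, "systolic_bp": sbp, "diastolic_bp": dbp, "confusion": conf}),
    ]


class TestTick:
    def test_full_inputs_advance_through_assessment(self):
        eng = make_engine()
        eng.handle_message(admission_msg())
        for m in obs_msgs():
            eng.handle_message(m)
        eng.tick(T0)
        j = eng.journeys["A1"]
        visited = [v.step for v in j.visited]
        assert visited[:2] == ["triage", "assess"]
        # age 70 -> 1 point, nothing else: Low
        assert j.latest_state("curb65") == 1
        assert j.latest_state("severity") == "Low"
        assert j.current == "assess"  # hourly loop parked for the next tick

    def test_missing_lab_pauses_journey(self):
        eng = make_engine()
        eng.handle_message(admission_msg())
        # vitals only: urea is required by the assessment schema
        eng.handle_message(obs_msgs()[1])
        eng.tick(T0)
        assert eng.journeys["A1"].status == "paused"

    def test_lab_message_resumes_paused_journey(self):
        eng = make_engine()
        eng.handle_message(admission_msg())
        eng.handle_message(obs_msgs()[1])
        eng.tick(T0)
        assert eng.journeys["A1"].status == "paused"
        eng.handle_message(obs_msgs(at=T0 + timedelta(minutes=30))[0])
        eng.tick(T0 + timedelta(hours=1))
        j = eng.journeys["A1"]
        assert j.status == "active"
        assert j.latest_state("severity") == "Low"

    def test_non_cap_admission_terminates_at_triage(self):
        eng = make_engine()
        eng.handle_message(admission_msg(code="I21.0"))
        eng.tick(T0)
        j = eng.journeys["A1"]
        assert j.status == "complete"
        assert [v.step for v in j.visited] == ["triage", "not_cap"]

    def test_stale_observations_pause_the_journey(self):
        eng = make_engine()
        eng.handle_message(admission_msg())
        for m in obs_msgs():
            eng.handle_message(m)
        eng.tick(T0)
        eng.tick(T0 + timedelta(hours=25))  # beyond the 24 h look-back
        assert eng.journeys["A1"].status == "paused"


class TestMessages:
    def test_admission_opens_journey_at_start(self):
        eng = make_engine()
        ack = eng.handle_message(admission_msg())
        assert ack["status"] == "ok"
        assert eng.journeys["A1"].current == "triage"

    def test_duplicate_admission_is_idempotent(self):
        eng = make_engine()
        eng.handle_message(admission_msg())
        eng.handle_message(admission_msg())
        assert len(eng.journeys) == 1

    def test_discharge_completes_active_journey(self):
        eng = make_engine()
        eng.handle_message(admission_msg())
        for m in obs_msgs():
            eng.handle_message(m)
        eng.tick(T0)
        eng.handle_message(Message("discharge", "A1", T0 + timedelta(hours=5), {"disposition": "home", "died": False}))
        j = eng.journeys["A1"]
        assert j.status == "complete"
        assert j.visited[-1].step == "discharged"
        assert not j.incomplete

    def test_discharge_of_paused_journey_marks_incomplete(self):
        eng = make_engine()
        eng.handle_message(admission_msg())
        eng.tick(T0)  # no observations at all -> assess pauses? triage has data
        eng.handle_message(Message("discharge", "A1", T0 + timedelta(hours=2), {"disposition": "home", "died": False}))
        j = eng.journeys["A1"]
        assert j.status == "complete"
        assert j.incomplete

    def test_unknown_admission_observation_queued_then_applied(self):
        eng = make_engine()
        acks = [eng.handle_message(m) for m in obs_msgs()]
        assert all(a["status"] == "queued" for a in acks)
        eng.handle_message(admission_msg())
        eng.tick(T0)
        assert eng.journeys["A1"].latest_state("severity") == "Low"

    def test_unknown_admission_rejected_when_configured(self):
        eng = make_engine(queue_unknown=False)
        assert eng.handle_message(obs_msgs()[0])["status"] == "rejected"


class TestActionsAndIsolation:
    def test_state_written_before_advancing(self):
        """The severity state history matches the decision labels of the
        assess visits one-to-one, with identical timestamps."""
        eng = make_engine()
        eng.handle_message(admission_msg(age=80.0))
        for m in obs_msgs(urea=9.0):
            eng.handle_message(m)
        eng.tick(T0)
        eng.tick(T0 + timedelta(hours=1))
        j = eng.journeys["A1"]
        assess_visits = [v for v in j.visited if v.step == "assess"]
        history = j.state_history("severity")
        assert len(assess_visits) == len(history) == 2
        for visit, (ts, value) in zip(assess_visits, history):
            assert visit.time == ts
            assert visit.decision == value == "Moderate"

    def test_outcome_action_feeds_outbox(self):
        eng = make_engine()
        eng.handle_message(admission_msg())
        for m in obs_msgs():
            eng.handle_message(m)
        eng.tick(T0)
        assert len(eng.outbox) == 1
        out = eng.outbox[0]
        assert out.kind == "outcome" and out.payload["step"] == "assess"

    def test_algorithm_failure_is_isolated_per_journey(self):
        plan = build_cap_plan()
        broken = plan.steps["assess"]
        object.__setattr__(broken, "algorithm", object())  # unsupported algorithm type
        eng = Engine(plan, message_schemas=cap_message_schemas())
        eng.handle_message(admission_msg("A1"))
        eng.handle_message(admission_msg("A2", code="I21.0", at=T0))
        for m in obs_msgs("A1"):
            eng.handle_message(m)
        eng.tick(T0)
        assert eng.journeys["A1"].status == "errored"
        assert eng.journeys["A2"].status == "complete"

    def test_transitions_only_use_declared_options(self, replayed_engine, cap_plan):
        for j in replayed_engine.journeys.values():
            for v in j.visited:
                if v.decision is not None:
                    assert v.decision in cap_plan.steps[v.step].decision.options


class TestReplay:
    def worsening_store(self):
        """Hand-built timeline: urea climbs from normal to severely high."""
        msgs = [admission_msg(age=70.0)]
        for hour, (urea, rr, conf) in enumerate(
            [(5.0, 16, False)] * 3 + [(9.0, 16, False)] * 3 + [(9.0, 34, True)] * 3
        ):
            msgs += obs_msgs(at=T0 + timedelta(hours=hour), urea=urea, rr=rr, conf=conf)
        msgs.append(
            Message("discharge", "A1", T0 + timedelta(hours=9), {"disposition": "home", "died": False})
        )
        return ReplayStore.from_messages(msgs), msgs

    def test_worsening_urea_walks_low_to_high(self):
        store, _ = self.worsening_store()
        eng = make_engine()
        eng.run_replay(store)
        bands = [v for _, v in eng.journeys["A1"].state_history("severity")]
        assert bands == ["Low"] * 3 + ["Moderate"] * 3 + ["High"] * 3
        scores = [v for _, v in eng.journeys["A1"].state_history("curb65")]
        assert scores == [1, 1, 1, 2, 2, 2, 4, 4, 4]

    def test_replay_is_deterministic(self):
        store, _ = self.worsening_store()
        runs = []
        for _ in range(2):
            eng = make_engine()
            eng.run_replay(store)
            runs.append(eng.journey_logs())
        assert runs[0] == runs[1]

    def test_replay_equals_stream_on_hand_timeline(self):
        store, msgs = self.worsening_store()
        e1, e2 = make_engine(), make_engine()
        e1.run_replay(store)
        e2.run_stream(msgs)
        assert e1.journey_logs() == e2.journey_logs()

    def test_empty_store_yields_no_journeys(self):
        import pandas as pd

        store = ReplayStore(
            admissions=pd.DataFrame(columns=["admission_id", "admitted_at", "discharged_at"]),
            observations=pd.DataFrame(columns=["admission_id", "timestamp", "kind", "field", "value"]),
        )
        eng = make_engine()
        eng.run_replay(store)
        assert eng.journeys == {}
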