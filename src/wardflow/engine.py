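"""Plan execution over time: hourly replay and message-driven progression.

The engine keeps one :class:`Journey` per admission and a per-admission
time-series store of observed field values. At each clock tick a journey's
current step gathers the freshest data available at that instant, runs its
algorithm, fires actions, and follows its decision — looping through
immediate successor steps until a step would repeat within the same tick
(hourly-assessment cycles), data is missing (the journey pauses), or a
terminal step is reached.

Two orchestration modes produce identical per-journey logs on identical
data: :meth:`Engine.run_replay` walks a preloaded store hour by hour within
each admission, while :meth:`Engine.run_stream` consumes ordered messages
and interleaves the same hourly ticks between arrivals (static-replay vs
near-real-time duality).
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

from .errors import InvalidValue, MissingField
from .plan import Action, EmitOutcome, Plan, SetState, Step, check_plan
from .algorithms import AlgorithmResult, run_algorithm
from .schema import DataSchema, validate_record

MESSAGE_KINDS = ("admission", "discharge", "lab", "vital", "imaging_report", "outcome")


@dataclass(frozen=True)
class Message:
    """One timestamped record about an admission, as exchanged with a broker."""

    kind: str
    admission_id: str
    timestamp: datetime
    payload: Mapping[str, Any] = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in MESSAGE_KINDS:
            raise InvalidValue("kind", f"unknown message kind {self.kind!r}")
        object.__setattr__(self, "payload", dict(self.payload))

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "admission_id": self.admission_id,
            "timestamp": self.timestamp.isoformat(),
            "payload": {
                k: (v.isoformat() if isinstance(v, datetime) else v)
                for k, v in self.payload.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "Message":
        return cls(
            kind=d["kind"],
            admission_id=d["admission_id"],
            timestamp=datetime.fromisoformat(d["timestamp"]),
            payload=dict(d.get("payload", {})),
        )


@dataclass
class Clock:
    """Temporal progression: fixed hourly increments in replay, message-driven
    advancement in live mode. Time never decreases within a journey."""

    mode: str = "replay"
    step: timedelta = timedelta(hours=1)
    current_time: datetime | None = None


@dataclass
class Visit:
    """One visited step of a journey."""

    step: str
    time: datetime
    result: AlgorithmResult | None = None
    decision: str | None = None


@dataclass
class Journey:
    """Ordered record of one admission's progress through a plan."""

    admission_id: str
    current: str
    admitted_at: datetime
    visited: list[Visit] = dc_field(default_factory=list)
    states: dict[str, list[tuple[datetime, Any]]] = dc_field(default_factory=dict)
    status: str = "active"  # active | paused | complete | errored
    next_tick: datetime | None = None
    paused_since: datetime | None = None
    finished_at: datetime | None = None
    incomplete: bool = False
    log: list[dict] = dc_field(default_factory=list)

    def state_history(self, name: str) -> list[tuple[datetime, Any]]:
        return self.states.get(name, [])

    def latest_state(self, name: str, default: Any = None) -> Any:
        hist = self.states.get(name)
        return hist[-1][1] if hist else default


class Engine:
    """Executes a checked plan over admissions data.

    Parameters
    ----------
    plan
        A plan passing :func:`~wardflow.plan.check_plan`.
    message_schemas
        Optional per-kind payload schemas; payloads are validated/coerced on
        arrival when a schema is registered for their kind.
    queue_unknown
        Whether observation messages arriving before their admission message
        are queued (default) or rejected.
    """

    def __init__(
        self,
        plan: Plan,
        message_schemas: Mapping[str, DataSchema] | None = None,
        clock: Clock | None = None,
        queue_unknown: bool = True,
    ):
        faults = check_plan(plan)
        if faults:
            raise InvalidValue(plan.name, "plan has structural faults: " + "; ".join(map(str, faults)))
        self.plan = plan
        self.message_schemas = dict(message_schemas or {})
        self.clock = clock or Clock()
        self.queue_unknown = queue_unknown
        self.journeys: dict[str, Journey] = {}
        # per admission: field -> ([timestamps], [values]); appends are in
        # timestamp order because messages are processed chronologically
        self._data: dict[str, dict[str, tuple[list[datetime], list[Any]]]] = {}
        self._data_ts: dict[str, list[datetime]] = {}
        self._pending: dict[str, list[Message]] = {}
        self.outbox: list[Message] = []

    # ------------------------------------------------------------------ data

    def _store_payload(self, admission_id: str, timestamp: datetime, payload: Mapping[str, Any]):
        fields = self._data.setdefault(admission_id, {})
        for name, value in payload.items():
            ts_list, val_list = fields.setdefault(name, ([], []))
            idx = bisect.bisect_right(ts_list, timestamp)
            ts_list.insert(idx, timestamp)
            val_list.insert(idx, value)
        all_ts = self._data_ts.setdefault(admission_id, [])
        bisect.insort(all_ts, timestamp)

    def _latest(self, admission_id: str, field: str, at: datetime):
        series = self._data.get(admission_id, {}).get(field)
        if not series:
            return None, None
        ts_list, val_list = series
        idx = bisect.bisect_right(ts_list, at) - 1
        if idx < 0:
            return None, None
        return val_list[idx], ts_list[idx]

    def _has_data_between(self, admission_id: str, after: datetime, upto: datetime) -> bool:
        all_ts = self._data_ts.get(admission_id, [])
        idx = bisect.bisect_right(all_ts, after)
        return idx < len(all_ts) and all_ts[idx] <= upto

    def gather(self, step: Step, admission_id: str, at: datetime) -> dict[str, Any] | None:
        """Assemble the step's input record from data available at ``at``.

        Availability = most recent value with timestamp <= ``at`` that is not
        staler than the field's ``stale_after`` window. Raises
        :class:`MissingField` when a required field has no fresh value.
        Returns ``None`` for steps without a data input.
        """
        if step.input is None:
            return None
        raw: dict[str, Any] = {}
        for f in step.input.schema.fields:
            value, ts = self._latest(admission_id, f.name, at)
            if value is None:
                continue
            if f.stale_after is not None and at - ts > timedelta(hours=f.stale_after):
                continue
            raw[f.name] = value
        raw = step.input.apply_transforms(raw)
        return validate_record(step.input.schema, raw)

    # ----------------------------------------------------------------- steps

    def _fire_actions(
        self,
        journey: Journey,
        step: Step,
        trigger: str,
        at: datetime,
        result: AlgorithmResult | None,
        decision: str | None,
    ):
        for action in step.actions:
            if action.trigger != trigger:
                continue
            effect = action.effect
            if isinstance(effect, SetState):
                if effect.source == "value":
                    value = result.value if result is not None else None
                elif effect.source == "decision":
                    value = decision
                else:
                    value = effect.constant
                journey.states.setdefault(effect.state, []).append((at, value))
            elif isinstance(effect, EmitOutcome):
                self.outbox.append(
                    Message(
                        kind="outcome",
                        admission_id=journey.admission_id,
                        timestamp=at,
                        payload={
                            "step": step.name,
                            "value": result.value if result is not None else None,
                            "decision": decision,
                        },
                    )
                )

    def _log(self, journey: Journey, at: datetime, step: str, **extra):
        entry = {"admission_id": journey.admission_id, "time": at.isoformat(), "step": step}
        entry.update(extra)
        journey.log.append(entry)

    def _tick_journey(self, journey: Journey, at: datetime):
        """Run one clock instant for one journey (isolation: exceptions other
        than missing data mark the journey errored without propagating)."""
        if journey.status == "paused":
            if not self._has_data_between(journey.admission_id, journey.paused_since, at):
                return
            journey.status = "active"
            journey.paused_since = None
            self._log(journey, at, journey.current, event="resumed")
        if journey.status != "active":
            return
        executed: set[str] = set()
        while journey.status == "active":
            step = self.plan.steps[journey.current]
            if step.terminal:
                self._complete(journey, at, step.name, append_visit=False)
                break
            if step.name in executed:
                break
            executed.add(step.name)
            try:
                record = self.gather(step, journey.admission_id, at)
            except MissingField as exc:
                journey.status = "paused"
                journey.paused_since = at
                self._log(journey, at, step.name, event="paused", missing=exc.name)
                break
            try:
                self._fire_actions(journey, step, "on_data", at, None, None)
                result = run_algorithm(step.algorithm, record) if step.algorithm is not None else None
                self._fire_actions(journey, step, "on_result", at, result, None)
                label = step.decision.select(result)
                # state writes fire before the journey advances
                self._fire_actions(journey, step, "on_decision_made", at, result, label)
                journey.visited.append(Visit(step.name, at, result, label))
                self._log(
                    journey,
                    at,
                    step.name,
                    event="decision",
                    value=result.value if result is not None else None,
                    decision=label,
                )
                self._fire_actions(journey, step, "on_decision_actioned", at, result, label)
                journey.current = step.decision.next_step(label)
            except Exception as exc:  # noqa: BLE001 - journey isolation contract
                journey.status = "errored"
                self._log(journey, at, step.name, event="errored", error=str(exc))
                break
            nxt = self.plan.steps[journey.current]
            if nxt.terminal:
                self._complete(journey, at, nxt.name)
                break

    def _complete(self, journey: Journey, at: datetime, terminal: str, append_visit: bool = True):
        if append_visit:
            journey.visited.append(Visit(terminal, at, None, None))
        journey.current = terminal
        journey.status = "complete"
        journey.finished_at = at
        self._log(journey, at, terminal, event="complete", incomplete=journey.incomplete)

    # -------------------------------------------------------------- messages

    def _admit(self, admission_id: str, at: datetime, payload: Mapping[str, Any]) -> Journey:
        if admission_id in self.journeys:
            return self.journeys[admission_id]  # duplicate admissions are idempotent
        journey = Journey(
            admission_id=admission_id, current=self.plan.start, admitted_at=at, next_tick=at
        )
        self.journeys[admission_id] = journey
        self._store_payload(admission_id, at, payload)
        self._log(journey, at, self.plan.start, event="admitted")
        for msg in self._pending.pop(admission_id, []):
            self._store_payload(admission_id, msg.timestamp, msg.payload)
        return journey

    def _finalise(self, journey: Journey, at: datetime):
        if journey.status == "complete":
            return
        if journey.status in ("paused", "errored"):
            journey.incomplete = True
        target = self.plan.discharge_step or journey.current
        self._complete(journey, at, target)

    def handle_message(self, msg: Message) -> dict:
        """Ingest one message; returns an acknowledgment with any transitions.

        Admissions open journeys; labs/vitals/imaging store observations and
        let paused journeys resume at their next tick; discharges finalise the
        journey at the plan's discharge step (paused journeys finalise with an
        ``incomplete`` marker).
        """
        schema = self.message_schemas.get(msg.kind)
        payload = validate_record(schema, msg.payload) if schema is not None else dict(msg.payload)
        self.clock.current_time = msg.timestamp

        if msg.kind == "admission":
            journey = self._admit(msg.admission_id, msg.timestamp, payload)
            return {"status": "ok", "journey": journey.admission_id, "transitions": []}

        journey = self.journeys.get(msg.admission_id)
        if journey is None:
            if not self.queue_unknown:
                return {"status": "rejected", "reason": "unknown admission", "transitions": []}
            self._pending.setdefault(msg.admission_id, []).append(
                Message(msg.kind, msg.admission_id, msg.timestamp, payload)
            )
            return {"status": "queued", "transitions": []}

        self._store_payload(msg.admission_id, msg.timestamp, payload)
        transitions: list[dict] = []
        if msg.kind == "discharge":
            n_before = len(journey.log)
            self._finalise(journey, msg.timestamp)
            transitions = journey.log[n_before:]
        return {"status": "ok", "transitions": transitions}

    # ----------------------------------------------------------- orchestration

    def tick(self, now: datetime) -> list[dict]:
        """Advance every admitted journey to clock time ``now``; returns the
        log entries produced at this instant."""
        produced: list[dict] = []
        for admission_id in sorted(self.journeys):
            journey = self.journeys[admission_id]
            if journey.status not in ("active", "paused") or journey.admitted_at > now:
                continue
            n_before = len(journey.log)
            self._tick_journey(journey, now)
            produced.extend(journey.log[n_before:])
        self.clock.current_time = now
        return produced

    def _advance_journeys(self, until: datetime, inclusive: bool = False):
        for admission_id in sorted(self.journeys):
            journey = self.journeys[admission_id]
            while journey.status in ("active", "paused") and (
                journey.next_tick < until or (inclusive and journey.next_tick <= until)
            ):
                self._tick_journey(journey, journey.next_tick)
                journey.next_tick += self.clock.step

    def run_stream(self, messages: Iterable[Message]) -> dict[str, Journey]:
        """Near-real-time mode: consume ordered messages, ticking each journey
        hourly (from its admission instant) between arrivals."""
        self.clock.mode = "live"
        horizon = None
        for msg in sorted(messages, key=lambda m: m.timestamp):
            self._advance_journeys(msg.timestamp)
            self.handle_message(msg)
            horizon = msg.timestamp
        if horizon is not None:
            self._advance_journeys(horizon, inclusive=True)
        return self.journeys

    def run_replay(self, store) -> dict[str, Journey]:
        """Static-replay mode: preload a store and walk each admission hour by
        hour from admission to discharge, finalising at the discharge instant.

        Deterministic: identical stores yield identical journey logs, and the
        logs equal those of :meth:`run_stream` on the store's message stream.
        """
        self.clock.mode = "replay"
        admissions, observations = store.admissions, store.observations
        obs_by_adm: dict[str, list] = {}
        if len(observations):
            for admission_id, grp in observations.groupby("admission_id", sort=False):
                obs_by_adm[admission_id] = list(
                    zip(grp["timestamp"].tolist(), grp["field"].tolist(), grp["value"].tolist())
                )
        order = admissions.sort_values(["admitted_at", "admission_id"])
        for row in order.itertuples(index=False):
            admitted = _as_datetime(row.admitted_at)
            discharged = _as_datetime(row.discharged_at)
            row_map = row._asdict()
            payload = {
                k: v
                for k, v in row_map.items()
                if k not in ("admission_id", "admitted_at", "discharged_at", "died", "disposition")
                and v == v
            }
            journey = self._admit(row.admission_id, admitted, payload)
            # discharge-time facts become visible only at the discharge instant
            discharge_payload = {
                k: row_map[k] for k in ("died", "disposition") if k in row_map and row_map[k] == row_map[k]
            }
            if discharge_payload:
                self._store_payload(row.admission_id, discharged, discharge_payload)
            for ts, fieldname, value in obs_by_adm.get(row.admission_id, []):
                self._store_payload(row.admission_id, _as_datetime(ts), {fieldname: value})
            t = admitted
            while journey.status in ("active", "paused") and t < discharged:
                self.clock.current_time = t
                self._tick_journey(journey, t)
                t += self.clock.step
            self._finalise(journey, discharged)
        return self.journeys

    # ------------------------------------------------------------------- logs

    def journey_logs(self) -> dict[str, list[dict]]:
        """Per-admission transition logs, keyed and ordered by admission id."""
        return {aid: list(self.journeys[aid].log) for aid in sorted(self.journeys)}

    def write_journey_logs(self, path: str | Path) -> Path:
        """Write logs as JSON lines, one transition per line, grouped by
        admission in id order (byte-identical for identical runs)."""
        path = Path(path)
        with path.open("w") as fh:
            for aid in sorted(self.journeys):
                for entry in self.journeys[aid].log:
                    fh.write(json.dumps(entry, sort_keys=True, default=str) + "\n")
        return path


def _as_datetime(value) -> datetime:
    if isinstance(value, datetime):
        return value
    if hasattr(value, "to_pydatetime"):
        return value.to_pydatetime()
    return datetime.fromisoformat(str(value))
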