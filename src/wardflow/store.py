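"""Replay stores and message streams.

A :class:`ReplayStore` holds an admissions table plus a long-format
observations table (admission_id, timestamp, kind, field, value) and
round-trips between three physical representations: newline-delimited JSON
message streams, delimited text files, and SQLite databases.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .engine import Message

#: stable ordering of message kinds at identical timestamps
_KIND_ORDER = {"admission": 0, "imaging_report": 1, "lab": 2, "vital": 3, "outcome": 4, "discharge": 5}

ADMISSION_COLUMNS = [
    "admission_id",
    "patient_id",
    "age",
    "sex",
    "primary_diagnosis",
    "secondary_diagnoses",
    "admitted_at",
    "discharged_at",
    "disposition",
    "died",
]


def sort_messages(messages: Iterable[Message]) -> list[Message]:
    return sorted(
        messages, key=lambda m: (m.timestamp, _KIND_ORDER.get(m.kind, 9), m.admission_id)
    )


def write_messages(path: str | Path, messages: Sequence[Message]) -> Path:
    """Write a newline-delimited JSON message stream (deterministic bytes)."""
    path = Path(path)
    with path.open("w") as fh:
        for msg in messages:
            fh.write(json.dumps(msg.to_dict(), sort_keys=True) + "\n")
    return path


def read_messages(path: str | Path) -> list[Message]:
    out = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(Message.from_dict(json.loads(line)))
    return out


@dataclass
class ReplayStore:
    admissions: pd.DataFrame
    observations: pd.DataFrame

    @classmethod
    def from_messages(cls, messages: Iterable[Message]) -> "ReplayStore":
        """Fold a message stream into admission rows + long-format observations."""
        adm_rows: dict[str, dict] = {}
        obs_rows: list[dict] = []
        for msg in sort_messages(messages):
            if msg.kind == "admission":
                row = {"admission_id": msg.admission_id, "admitted_at": msg.timestamp}
                row.update(msg.payload)
                adm_rows.setdefault(msg.admission_id, {}).update(row)
            elif msg.kind == "discharge":
                row = adm_rows.setdefault(msg.admission_id, {"admission_id": msg.admission_id})
                row["discharged_at"] = msg.timestamp
                row.update(msg.payload)
            else:
                for field, value in msg.payload.items():
                    obs_rows.append(
                        {
                            "admission_id": msg.admission_id,
                            "timestamp": msg.timestamp,
                            "kind": msg.kind,
                            "field": field,
                            "value": value,
                        }
                    )
        admissions = pd.DataFrame(list(adm_rows.values()))
        for col in ADMISSION_COLUMNS:
            if col not in admissions.columns:
                admissions[col] = float("nan")
        admissions = admissions[ADMISSION_COLUMNS]
        observations = pd.DataFrame(
            obs_rows, columns=["admission_id", "timestamp", "kind", "field", "value"]
        )
        return cls(admissions=admissions, observations=observations)

    def to_messages(self) -> list[Message]:
        """Re-emit the store as an ordered message stream."""
        messages: list[Message] = []
        for row in self.admissions.itertuples(index=False):
            row_map = {k: v for k, v in row._asdict().items() if v is not pd.NA and v == v}
            adm_payload = {
                k: v
                for k, v in row_map.items()
                if k not in ("admission_id", "admitted_at", "discharged_at", "disposition", "died")
            }
            messages.append(
                Message("admission", row.admission_id, _ts(row.admitted_at), adm_payload)
            )
            if "discharged_at" in row_map:
                dis_payload = {k: row_map[k] for k in ("disposition", "died") if k in row_map}
                messages.append(
                    Message("discharge", row.admission_id, _ts(row.discharged_at), dis_payload)
                )
        if len(self.observations):
            grouped = self.observations.groupby(
                ["admission_id", "timestamp", "kind"], sort=False
            )
            for (admission_id, timestamp, kind), grp in grouped:
                payload = dict(zip(grp["field"], grp["value"]))
                messages.append(Message(kind, admission_id, _ts(timestamp), payload))
        return sort_messages(messages)

    # ------------------------------------------------------------- text files

    def to_csv_dir(self, directory: str | Path, delimiter: str = ",") -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.admissions.to_csv(directory / "admissions.csv", index=False, sep=delimiter)
        self.observations.to_csv(directory / "observations.csv", index=False, sep=delimiter)
        return directory

    @classmethod
    def from_csv_dir(cls, directory: str | Path, delimiter: str = ",") -> "ReplayStore":
        directory = Path(directory)
        admissions = pd.read_csv(
            directory / "admissions.csv", sep=delimiter, parse_dates=["admitted_at", "discharged_at"]
        )
        observations = pd.read_csv(directory / "observations.csv", sep=delimiter, parse_dates=["timestamp"])
        return cls(admissions=admissions, observations=observations)

    # ----------------------------------------------------------------- sqlite

    def to_sqlite(self, path: str | Path) -> Path:
        path = Path(path)
        with sqlite3.connect(path) as conn:
            adm = self.admissions.copy()
            obs = self.observations.copy()
            for col in ("admitted_at", "discharged_at"):
                adm[col] = adm[col].map(lambda v: _ts(v).isoformat() if v == v else None)
            obs["timestamp"] = obs["timestamp"].map(lambda v: _ts(v).isoformat())
            obs["value"] = obs["value"].map(str)
            adm.to_sql("admissions", conn, index=False, if_exists="replace")
            obs.to_sql("observations", conn, index=False, if_exists="replace")
        return path

    @classmethod
    def from_sqlite(cls, path: str | Path) -> "ReplayStore":
        with sqlite3.connect(Path(path)) as conn:
            admissions = pd.read_sql("select * from admissions", conn)
            observations = pd.read_sql("select * from observations", conn)
        for col in ("admitted_at", "discharged_at"):
            admissions[col] = pd.to_datetime(admissions[col])
        observations["timestamp"] = pd.to_datetime(observations["timestamp"])
        return cls(admissions=admissions, observations=observations)


def load_store(path: str | Path) -> ReplayStore:
    """Load a store from a directory of CSVs, a SQLite file, or an ndjson
    message stream, dispatching on the path."""
    path = Path(path)
    if path.is_dir():
        return ReplayStore.from_csv_dir(path)
    if path.suffix in (".sqlite", ".db", ".sqlite3"):
        return ReplayStore.from_sqlite(path)
    return ReplayStore.from_messages(read_messages(path))


def _ts(value) -> datetime:
    if isinstance(value, datetime):
        return value
    if hasattr(value, "to_pydatetime"):
        return value.to_pydatetime()
    return datetime.fromisoformat(str(value))
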