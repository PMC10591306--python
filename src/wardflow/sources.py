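"""Data sources: named record providers with transforms and collation.

A :class:`DataSource` couples a schema with an ordered list of record-level
transforms and, optionally, constituent child sources whose records are
merged ("collated") into one. Field-name collisions resolve by declaration
order: the *last* source wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable, Mapping, Sequence

from .schema import DataSchema, union_schema, validate_record


@dataclass(frozen=True)
class Transform:
    """A named record-level transform (record in, record out)."""

    name: str
    func: Callable[[dict], dict]

    def __call__(self, record: dict) -> dict:
        return self.func(record)


@dataclass(frozen=True)
class DataSource:
    name: str
    schema: DataSchema
    transforms: tuple[Transform, ...] = ()
    constituents: tuple["DataSource", ...] = ()

    def apply_transforms(self, record: Mapping[str, Any]) -> dict[str, Any]:
        out = dict(record)
        for t in self.transforms:
            out = t(out)
        return out


def merge_records(records: Sequence[Mapping[str, Any]]) -> dict[str, Any]:
    """Merge records in order; later records override earlier on collisions."""
    merged: dict[str, Any] = {}
    for rec in records:
        merged.update(rec)
    return merged


def collate(
    sources: Sequence[DataSource],
    records: Mapping[str, Mapping[str, Any]],
    schema: DataSchema | None = None,
) -> dict[str, Any]:
    """Collate per-source records into one validated record.

    Each source's record (looked up by source name; missing entries count as
    empty) is passed through that source's transforms, then the results are
    merged in declared source order — last source wins on field collisions —
    and validated against ``schema`` (default: the field-wise union of the
    sources' schemas).
    """
    parts = [src.apply_transforms(records.get(src.name, {})) for src in sources]
    merged = merge_records(parts)
    target = schema if schema is not None else union_schema([s.schema for s in sources])
    return validate_record(target, merged)


def collate_source(source: DataSource, records: Mapping[str, Mapping[str, Any]]) -> dict[str, Any]:
    """Collate a composite source's constituents against the parent schema."""
    return collate(source.constituents, records, schema=source.schema)
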