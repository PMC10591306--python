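"""Data schemas: typed field declarations and record validation.

A :class:`DataSchema` is an ordered collection of :class:`DataField`
declarations. :func:`validate_record` coerces a flat record to the declared
kinds, substitutes defaults for absent optional fields and enforces ranges.
Validation is idempotent: validating an already-validated record returns an
equal record.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from datetime import datetime
from typing import Any, Iterable, Mapping

from .errors import InvalidValue, MissingField

KINDS = ("number", "integer", "boolean", "text", "datetime", "category")

_TRUE = {"true", "t", "yes", "y", "1"}
_FALSE = {"false", "f", "no", "n", "0"}


def _coerce(name: str, kind: str, value: Any, allowed: Any) -> Any:
    """Coerce ``value`` to ``kind``; raise InvalidValue on failure."""
    try:
        if kind == "number":
            if isinstance(value, bool):
                raise ValueError("boolean is not a number")
            out: Any = float(value)
        elif kind == "integer":
            if isinstance(value, bool):
                raise ValueError("boolean is not an integer")
            f = float(value)
            if f != int(f):
                raise ValueError("not an integral value")
            out = int(f)
        elif kind == "boolean":
            if isinstance(value, bool):
                out = value
            elif isinstance(value, (int, float)) and value in (0, 1):
                out = bool(value)
            elif isinstance(value, str) and value.strip().lower() in _TRUE:
                out = True
            elif isinstance(value, str) and value.strip().lower() in _FALSE:
                out = False
            else:
                raise ValueError(f"not a recognised boolean: {value!r}")
        elif kind == "text":
            out = str(value)
        elif kind == "datetime":
            if isinstance(value, datetime):
                out = value
            elif hasattr(value, "to_pydatetime"):  # pandas.Timestamp
                out = value.to_pydatetime()
            elif isinstance(value, str):
                out = datetime.fromisoformat(value)
            else:
                raise ValueError(f"not a datetime: {value!r}")
        elif kind == "category":
            out = str(value)
        else:  # pragma: no cover - guarded by DataField.__post_init__
            raise ValueError(f"unknown kind {kind!r}")
    except InvalidValue:
        raise
    except (TypeError, ValueError) as exc:
        raise InvalidValue(name, str(exc)) from None

    if allowed is not None:
        if kind == "category":
            if out not in allowed:
                raise InvalidValue(name, f"{out!r} not in categories {sorted(allowed)}")
        else:
            lo, hi = allowed
            if lo is not None and out < lo:
                raise InvalidValue(name, f"{out!r} below minimum {lo!r}")
            if hi is not None and out > hi:
                raise InvalidValue(name, f"{out!r} above maximum {hi!r}")
    return out


@dataclass(frozen=True)
class DataField:
    """One typed field of a schema.

    ``allowed_range`` is a closed ``(lo, hi)`` interval for ordered kinds or a
    set of labels for ``category``. ``stale_after`` (hours) bounds how old an
    observation may be when the engine assembles a record at a point in time;
    ``None`` means the value never goes stale (demographics).
    """

    name: str
    kind: str = "number"
    unit: str = ""
    required: bool = False
    default: Any = None
    allowed_range: Any = None
    stale_after: float | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise InvalidValue(self.name, f"unknown kind {self.kind!r}")
        if self.required and self.default is not None:
            raise InvalidValue(self.name, "required and default are mutually exclusive")
        if self.kind == "category" and self.allowed_range is not None:
            object.__setattr__(self, "allowed_range", frozenset(self.allowed_range))
        elif self.allowed_range is not None:
            lo, hi = self.allowed_range
            object.__setattr__(self, "allowed_range", (lo, hi))
        if self.default is not None:
            object.__setattr__(
                self, "default", _coerce(self.name, self.kind, self.default, self.allowed_range)
            )

    def coerce(self, value: Any) -> Any:
        return _coerce(self.name, self.kind, value, self.allowed_range)

    def to_dict(self) -> dict:
        d: dict[str, Any] = {"name": self.name, "kind": self.kind}
        if self.unit:
            d["unit"] = self.unit
        if self.required:
            d["required"] = True
        if self.default is not None:
            d["default"] = self.default.isoformat() if isinstance(self.default, datetime) else self.default
        if self.allowed_range is not None:
            if self.kind == "category":
                d["categories"] = sorted(self.allowed_range)
            else:
                d["range"] = list(self.allowed_range)
        if self.stale_after is not None:
            d["stale_after"] = self.stale_after
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DataField":
        allowed = d.get("categories")
        if allowed is None and "range" in d:
            allowed = tuple(d["range"])
        return cls(
            name=d["name"],
            kind=d.get("kind", "number"),
            unit=d.get("unit", ""),
            required=d.get("required", False),
            default=d.get("default"),
            allowed_range=allowed,
            stale_after=d.get("stale_after"),
        )


@dataclass(frozen=True)
class DataSchema:
    """Named, versioned, ordered collection of fields."""

    name: str
    fields: tuple[DataField, ...]
    version: str = "1"

    def __post_init__(self):
        object.__setattr__(self, "fields", tuple(self.fields))
        if not self.fields:
            raise InvalidValue(self.name, "schema requires at least one field")
        names = [f.name for f in self.fields]
        if len(set(names)) != len(names):
            raise InvalidValue(self.name, f"duplicate field names in {names}")

    @property
    def field_map(self) -> dict[str, DataField]:
        return {f.name: f for f in self.fields}

    @property
    def field_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.fields)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "version": self.version,
            "fields": [f.to_dict() for f in self.fields],
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DataSchema":
        return cls(
            name=d["name"],
            version=d.get("version", "1"),
            fields=tuple(DataField.from_dict(fd) for fd in d["fields"]),
        )


def validate_record(schema: DataSchema, record: Mapping[str, Any]) -> dict[str, Any]:
    """Validate and coerce ``record`` against ``schema``.

    Returns a new record containing exactly the schema's fields (in schema
    order): coerced values where present, defaults where absent and declared,
    nothing where absent and optional. ``None`` counts as absent.

    Raises
    ------
    MissingField
        A required field is absent.
    InvalidValue
        A value cannot be coerced or violates its allowed range.
    """
    out: dict[str, Any] = {}
    for f in schema.fields:
        value = record.get(f.name)
        if value is not None:
            out[f.name] = f.coerce(value)
        elif f.required:
            raise MissingField(f.name)
        elif f.default is not None:
            out[f.name] = f.default
    return out


def union_schema(schemas: Iterable[DataSchema], name: str = "collated") -> DataSchema:
    """Field-wise union of schemas; later declarations win on name collision."""
    merged: dict[str, DataField] = {}
    for s in schemas:
        for f in s.fields:
            merged[f.name] = f
    return DataSchema(name=name, fields=tuple(merged.values()), version="collated")
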