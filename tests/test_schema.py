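"""Record validation: coercion, defaults, ranges, idempotence, collation."""

from datetime import datetime

import pytest
from hypothesis import given, settings, strategies as st

from wardflow.errors import InvalidValue, MissingField
from wardflow.schema import DataField, DataSchema, validate_record, union_schema
from wardflow.sources import DataSource, Transform, collate


def schema_of(*fields):
    return DataSchema(name="t", fields=tuple(fields))


class TestValidateRecord:
    def test_numeric_text_is_coerced(self):
        s = schema_of(DataField("urea", "number", required=True))
        assert validate_record(s, {"urea": "8.1"}) == {"urea": 8.1}

    def test_default_substituted_when_missing(self):
        s = schema_of(DataField("crp", "number", default=0))
        assert validate_record(s, {}) == {"crp": 0.0}

    def test_range_violation_rejected(self):
        s = schema_of(DataField("rr", "integer", allowed_range=(0, 80)))
        with pytest.raises(InvalidValue) as err:
            validate_record(s, {"rr": 999})
        assert err.value.name == "rr"

    def test_missing_required_field(self):
        s = schema_of(DataField("urea", "number", required=True))
        with pytest.raises(MissingField):
            validate_record(s, {})

    @pytest.mark.parametrize(
        "kind,raw,expected",
        [
            ("integer", "8", 8),
            ("boolean", "true", True),
            ("boolean", 0, False),
            ("text", 42, "42"),
            ("datetime", "2022-04-01T03:00:00", datetime(2022, 4, 1, 3)),
            ("category", "High", "High"),
        ],
    )
    def test_kind_coercions(self, kind, raw, expected):
        allowed = ("Low", "Moderate", "High") if kind == "category" else None
        s = schema_of(DataField("x", kind, allowed_range=allowed))
        assert validate_record(s, {"x": raw}) == {"x": expected}

    @pytest.mark.parametrize(
        "kind,raw", [("number", "abc"), ("integer", "8.5"), ("boolean", "maybe"), ("datetime", 7)]
    )
    def test_uncoercible_values_rejected(self, kind, raw):
        s = schema_of(DataField("x", kind))
        with pytest.raises(InvalidValue):
            validate_record(s, {"x": raw})

    def test_category_outside_set_rejected(self):
        s = schema_of(DataField("band", "category", allowed_range=("Low", "High")))
        with pytest.raises(InvalidValue):
            validate_record(s, {"band": "Extreme"})

    def test_none_counts_as_absent(self):
        s = schema_of(DataField("crp", "number", default=3))
        assert validate_record(s, {"crp": None}) == {"crp": 3.0}

    @given(
        urea=st.floats(0, 50, allow_nan=False),
        rr=st.integers(0, 80),
        conf=st.booleans(),
    )
    @settings(max_examples=50, derandomize=True)
    def test_validation_is_idempotent(self, urea, rr, conf):
        s = schema_of(
            DataField("urea", "number"),
            DataField("rr", "integer"),
            DataField("conf", "boolean"),
            DataField("note", "text", default="none"),
        )
        once = validate_record(s, {"urea": urea, "rr": rr, "conf": conf})
        assert validate_record(s, once) == once


class TestDataField:
    def test_required_and_default_are_exclusive(self):
        with pytest.raises(InvalidValue):
            DataField("x", "number", required=True, default=1)

    def test_default_must_satisfy_range(self):
        with pytest.raises(InvalidValue):
            DataField("x", "integer", default=99, allowed_range=(0, 10))

    def test_schema_rejects_duplicate_names(self):
        with pytest.raises(InvalidValue):
            DataSchema("s", (DataField("a"), DataField("a")))

    def test_schema_requires_a_field(self):
        with pytest.raises(InvalidValue):
            DataSchema("s", ())


class TestCollate:
    def make_sources(self):
        sa = DataSource("demo", schema_of(DataField("age", "number")))
        sb = DataSource("labs", schema_of(DataField("urea", "number")))
        return sa, sb

    def test_disjoint_merge(self):
        sa, sb = self.make_sources()
        out = collate([sa, sb], {"demo": {"age": 70}, "labs": {"urea": 8}})
        assert out == {"age": 70.0, "urea": 8.0}

    def test_last_source_wins_and_order_matters(self):
        s1 = DataSource("a", schema_of(DataField("urea", "number")))
        s2 = DataSource("b", schema_of(DataField("urea", "number")))
        records = {"a": {"urea": 5}, "b": {"urea": 8}}
        assert collate([s1, s2], records)["urea"] == 8.0
        assert collate([s2, s1], records)["urea"] == 5.0

    def test_all_required_schema_with_empty_records(self):
        sa = DataSource("a", schema_of(DataField("age", "number", required=True)))
        sb = DataSource("b", schema_of(DataField("urea", "number", required=True)))
        with pytest.raises(MissingField):
            collate([sa, sb], {"a": {}, "b": {}})

    def test_transforms_apply_in_declared_order(self):
        double = Transform("double", lambda r: {**r, "x": r["x"] * 2})
        plus_one = Transform("plus_one", lambda r: {**r, "x": r["x"] + 1})
        src = DataSource("t", schema_of(DataField("x", "number")), transforms=(double, plus_one))
        assert collate([src], {"t": {"x": 3}})["x"] == 7.0

    @given(
        a=st.dictionaries(st.sampled_from(["p", "q"]), st.floats(0, 9, allow_nan=False), max_size=2),
        b=st.dictionaries(st.sampled_from(["r", "s"]), st.floats(0, 9, allow_nan=False), max_size=2),
        c=st.dictionaries(st.sampled_from(["t", "u"]), st.floats(0, 9, allow_nan=False), max_size=2),
    )
    @settings(max_examples=40, derandomize=True)
    def test_collate_associative_on_disjoint_fields(self, a, b, c):
        fields = {n: DataField(n, "number") for n in "pqrstu"}

        def src(name, rec):
            used = tuple(fields[k] for k in rec) or (fields[name[0]],)
            return DataSource(name, DataSchema(name, used))

        sa, sb, sc = src("pa", a), src("rb", b), src("tc", c)
        records = {"pa": a, "rb": b, "tc": c}
        schema = union_schema([sa.schema, sb.schema, sc.schema])
        left = collate([sa, sb, sc], records, schema=schema)
        inner = collate([sa, sb], records, schema=union_schema([sa.schema, sb.schema]))
        merged = collate(
            [DataSource("ab", union_schema([sa.schema, sb.schema])), sc],
            {"ab": inner, "tc": c},
            schema=schema,
        )
        assert left == merged
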