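"""Algorithm serialization: one portable zip artefact per algorithm.

The archive contains ``manifest.json`` (format version, kind, name, schema
version), ``schema.json``, ``params.json`` (factors / rules / encoder /
threshold), ``metadata.json`` where cached, and for predictive algorithms an
opaque ``model.bin`` (joblib). Loading verifies the format version and that
the manifest's schema version matches the embedded schema; a mismatch
raises :class:`~wardflow.errors.SchemaMismatch`.
"""

from __future__ import annotations

import io
import json
import zipfile
from pathlib import Path
from typing import Any

import joblib

from .algorithms import (
    FeatureEncoder,
    LogicalAlgorithm,
    PredictiveAlgorithm,
    RiskFactor,
    Rule,
    ScoreAlgorithm,
)
from .errors import SchemaMismatch
from .metadata import ModelMetadata
from .schema import DataSchema

FORMAT_VERSION = "1"


def _kind(algo: Any) -> str:
    if isinstance(algo, ScoreAlgorithm):
        return "score"
    if isinstance(algo, LogicalAlgorithm):
        return "logical"
    if isinstance(algo, PredictiveAlgorithm):
        return "predictive"
    raise SchemaMismatch(f"cannot serialize algorithm of type {type(algo).__name__}")


def _params(algo: Any) -> dict:
    if isinstance(algo, ScoreAlgorithm):
        return {"factors": [f.to_dict() for f in algo.factors]}
    if isinstance(algo, LogicalAlgorithm):
        return {
            "rules": [r.to_dict() for r in algo.rules],
            "default_label": algo.default_label,
        }
    return {
        "encoder": algo.encoder.to_dict(),
        "threshold": algo.threshold,
        "positive_label": algo.positive_label,
        "negative_label": algo.negative_label,
    }


def save_algorithm(algo: Any, path: str | Path) -> Path:
    """Write ``algo`` to a portable zip artefact at ``path``."""
    path = Path(path)
    manifest = {
        "format_version": FORMAT_VERSION,
        "kind": _kind(algo),
        "name": algo.name,
        "schema_version": algo.schema.version,
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as z:
        z.writestr("manifest.json", json.dumps(manifest, sort_keys=True, indent=1))
        z.writestr("schema.json", json.dumps(algo.schema.to_dict(), sort_keys=True, indent=1))
        z.writestr("params.json", json.dumps(_params(algo), sort_keys=True, indent=1))
        if isinstance(algo, PredictiveAlgorithm):
            buf = io.BytesIO()
            joblib.dump(algo.model, buf)
            z.writestr("model.bin", buf.getvalue())
            if algo.metadata is not None:
                z.writestr(
                    "metadata.json", json.dumps(algo.metadata.to_dict(), sort_keys=True, indent=1)
                )
    return path


def load_algorithm(path: str | Path, expected_schema_version: str | None = None) -> Any:
    """Load an algorithm artefact, verifying format and schema versions.

    ``expected_schema_version``, when given, must match the artefact's schema
    version exactly (exact string comparison) — this is the guard against
    running data through an algorithm built for a different schema.
    """
    with zipfile.ZipFile(Path(path)) as z:
        manifest = json.loads(z.read("manifest.json"))
        if manifest.get("format_version") != FORMAT_VERSION:
            raise SchemaMismatch(
                f"unsupported artefact format version {manifest.get('format_version')!r}"
            )
        schema = DataSchema.from_dict(json.loads(z.read("schema.json")))
        if manifest.get("schema_version") != schema.version:
            raise SchemaMismatch(
                f"manifest schema version {manifest.get('schema_version')!r} "
                f"does not match embedded schema version {schema.version!r}"
            )
        if expected_schema_version is not None and schema.version != expected_schema_version:
            raise SchemaMismatch(
                f"artefact schema version {schema.version!r}, expected {expected_schema_version!r}"
            )
        params = json.loads(z.read("params.json"))
        kind = manifest["kind"]
        if kind == "score":
            return ScoreAlgorithm(
                name=manifest["name"],
                schema=schema,
                factors=tuple(RiskFactor.from_dict(f) for f in params["factors"]),
            )
        if kind == "logical":
            return LogicalAlgorithm(
                name=manifest["name"],
                schema=schema,
                rules=tuple(Rule.from_dict(r) for r in params["rules"]),
                default_label=params["default_label"],
            )
        if kind == "predictive":
            model = joblib.load(io.BytesIO(z.read("model.bin")))
            metadata = None
            if "metadata.json" in z.namelist():
                metadata = ModelMetadata.from_dict(json.loads(z.read("metadata.json")))
            return PredictiveAlgorithm(
                name=manifest["name"],
                schema=schema,
                encoder=FeatureEncoder.from_dict(params["encoder"]),
                model=model,
                threshold=params["threshold"],
                metadata=metadata,
                positive_label=params["positive_label"],
                negative_label=params["negative_label"],
            )
        raise SchemaMismatch(f"unknown algorithm kind {kind!r}")
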