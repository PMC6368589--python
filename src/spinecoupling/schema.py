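"""Minimal structural validation of the pipeline report.

The committed schema (``report_schema.json``) pins the report's top-level
structure so downstream consumers can rely on it. The validator supports
the subset of JSON-schema keywords the report needs: ``type`` (including
unions), ``properties`` + ``required`` for objects, and ``items`` for
arrays. Unknown extra keys are permitted.
"""

from __future__ import annotations

import json
from importlib import resources

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "boolean": bool,
    "null": type(None),
}


def _type_ok(value, typename: str) -> bool:
    if typename == "number":
        return isinstance(value, (int, float)) and not isinstance(value, bool)
    if typename == "integer":
        return isinstance(value, int) and not isinstance(value, bool)
    return isinstance(value, _TYPES[typename])


def validate_schema(obj, schema: dict, path: str = "$") -> None:
    """Raise ValueError at the first structural mismatch."""
    typ = schema.get("type")
    if typ is not None:
        types = typ if isinstance(typ, list) else [typ]
        if not any(_type_ok(obj, t) for t in types):
            raise ValueError(
                f"{path}: expected {types}, got {type(obj).__name__} ({obj!r:.80})"
            )
        if obj is None:
            return
    if isinstance(obj, dict):
        for key in schema.get("required", []):
            if key not in obj:
                raise ValueError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                validate_schema(obj[key], sub, f"{path}.{key}")
    if isinstance(obj, list) and "items" in schema:
        for i, item in enumerate(obj):
            validate_schema(item, schema["items"], f"{path}[{i}]")


def load_report_schema() -> dict:
    text = (
        resources.files("spinecoupling").joinpath("report_schema.json").read_text()
    )
    return json.loads(text)


def validate_report(report: dict) -> None:
    """Validate a pipeline report against the committed schema."""
    validate_schema(report, load_report_schema())
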