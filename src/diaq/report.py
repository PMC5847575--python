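"""Assembly of per-stage outputs into a QC dossier.

``render_report`` turns whatever stage outputs exist into a machine-readable
JSON summary (sections ``rt``, ``filter``, ``normalize``, ``correct``,
``cv``, ``batch``, ``counts``) and a plain-text markdown dossier.  Missing
stages render as "not run"; rendering is deterministic.
"""

from __future__ import annotations

import json
import math
from typing import Any

SECTIONS = ("rt", "filter", "normalize", "correct", "cv", "batch", "counts")

#: minimal schema: section -> {field: type tag ("number" | "int" | "str" | "any")}
REPORT_SCHEMA: dict[str, str] = {"version": "1"}


def _finite_or_null(value):
    if isinstance(value, float) and not math.isfinite(value):
        return None
    return value


def _clean(obj: Any) -> Any:
    """Recursively coerce numerics to finite-or-null plain Python values."""
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if hasattr(obj, "item"):                 # numpy scalar
        obj = obj.item()
    if isinstance(obj, float):
        return _finite_or_null(obj)
    if isinstance(obj, (int, str, bool)) or obj is None:
        return obj
    return str(obj)


def validate_summary(summary: dict) -> None:
    """Check the shipped schema: known sections, numerics finite or null."""
    for key in summary:
        if key not in SECTIONS and key != "schema_version":
            raise ValueError(f"unknown report section {key!r}")

    def walk(node):
        if isinstance(node, dict):
            for v in node.values():
                walk(v)
        elif isinstance(node, list):
            for v in node:
                walk(v)
        elif isinstance(node, float) and not math.isfinite(node):
            raise ValueError("non-finite numeric in report")

    walk(summary)


def render_report(stage_outputs: dict[str, Any]) -> tuple[dict, str]:
    """Render stage outputs into (JSON-ready summary, markdown dossier)."""
    if not any(v is not None for v in stage_outputs.values()):
        raise ValueError("no stage output present")
    summary: dict[str, Any] = {"schema_version": REPORT_SCHEMA["version"]}
    for section in SECTIONS:
        value = stage_outputs.get(section)
        summary[section] = _clean(value) if value is not None else None
    validate_summary(summary)

    lines = ["# QC dossier", ""]
    titles = {
        "rt": "Retention-time stability",
        "filter": "Q-value filtering",
        "normalize": "Injection normalization",
        "correct": "Batch correction",
        "cv": "Precision (CV)",
        "batch": "Batch diagnostics",
        "counts": "Stage feature counts",
    }
    for section in SECTIONS:
        lines.append(f"## {titles[section]}")
        value = summary[section]
        if value is None:
            lines.append("not run")
        else:
            lines.append("```json")
            lines.append(json.dumps(value, indent=2, sort_keys=True))
            lines.append("```")
        lines.append("")
    return summary, "\n".join(lines)


def write_report(summary: dict, dossier: str, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "qc_report.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (out / "qc_report.md").write_text(dossier + "\n")
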