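"""Serialization, schema validation, and report rendering.

Reports interchange as JSON documents with an explicit
``schema_version`` so the schema can migrate (e.g. to a future TNM
revision) without breaking readers.  Parsing is strict by default —
unknown fields and any type-invariant violation are rejected with
JSON-pointer paths — and writing is deterministic (stable key order,
sorted descriptor lists, one-decimal diameters) so documents diff
cleanly.  Reader-study tables interchange as CSV.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import IO, Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, ValidationError

from . import engine
from .evaluation import VALID_METHODS, ReaderRecord
from .findings import StructuredReport, TNMClassification

__all__ = [
    "SCHEMA_VERSION",
    "ReportDocument",
    "DerivedBlock",
    "SchemaError",
    "read_report",
    "write_report",
    "read_reader_study",
    "write_reader_study",
    "render_report_text",
]

SCHEMA_VERSION = "1.0"

PathOrStream = Union[str, Path, IO[str]]


class SchemaError(ValueError):
    """A report document violated the schema; ``violations`` lists every
    problem as (json_pointer, message)."""

    def __init__(self, violations: Sequence[tuple[str, str]]):
        self.violations = list(violations)
        msg = "; ".join(f"{ptr}: {m}" for ptr, m in self.violations)
        super().__init__(f"invalid report document: {msg}")


class DerivedBlock(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)
    tnm: str
    uicc_stage: str
    engine_version: str


class ReportDocument(BaseModel):
    """Envelope for one structured report, optionally carrying the
    engine-derived TNM/stage block (always reproducible from the report)."""

    model_config = ConfigDict(extra="forbid", frozen=True)
    schema_version: str
    report: StructuredReport
    derived: Optional[DerivedBlock] = None


def _pointer(loc: tuple) -> str:
    return "/" + "/".join(str(p) for p in loc)


def read_report(source: PathOrStream, strict: bool = True) -> StructuredReport:
    """Read and validate a report document (JSON).

    In strict mode unknown fields are schema violations; with
    ``strict=False`` they are dropped with a warning.  All violations
    are collected and reported at once via :class:`SchemaError`.
    """
    if hasattr(source, "read"):
        raw = source.read()
    else:
        raw = Path(source).read_text(encoding="utf-8")
    try:
        payload = json.loads(raw)
    except json.JSONDecodeError as e:
        raise SchemaError([("/", f"not valid JSON: {e}")]) from None
    if not strict:
        payload = _strip_unknown(payload)
    try:
        doc = ReportDocument.model_validate(payload)
    except ValidationError as e:
        raise SchemaError([(_pointer(err["loc"]), err["msg"]) for err in e.errors()]) from None
    if doc.derived is not None:
        derived = _derive(doc.report)
        if (doc.derived.tnm, doc.derived.uicc_stage) != (derived.tnm, derived.uicc_stage):
            raise SchemaError(
                [("/derived", f"derived block {doc.derived.tnm!r}/{doc.derived.uicc_stage!r} "
                              f"is not reproducible from the report ({derived.tnm!r}/{derived.uicc_stage!r})")]
            )
    return doc.report


def _strip_unknown(payload):
    """Lenient mode: drop unknown top-level and report-level keys, warning once each."""
    if not isinstance(payload, dict):
        return payload
    known_top = {"schema_version", "report", "derived"}
    known_report = set(StructuredReport.model_fields)
    out = {}
    for k, v in payload.items():
        if k not in known_top:
            warnings.warn(f"ignoring unknown document field {k!r}", stacklevel=3)
            continue
        out[k] = v
    rep = out.get("report")
    if isinstance(rep, dict):
        cleaned = {}
        for k, v in rep.items():
            if k not in known_report:
                warnings.warn(f"ignoring unknown report field {k!r}", stacklevel=3)
                continue
            cleaned[k] = v
        out["report"] = cleaned
    return out


def _derive(report: StructuredReport) -> DerivedBlock:
    c = engine.classify_report(report)
    return DerivedBlock(
        tnm=engine.format_tnm(c),
        uicc_stage=engine.uicc_stage(c).value,
        engine_version=engine.ENGINE_VERSION,
    )


def write_report(
    report: StructuredReport,
    target: Optional[PathOrStream] = None,
    derived: bool = False,
) -> str:
    """Serialize a report to its JSON document (returned; also written
    to ``target`` when given).  Output is byte-stable across runs."""
    doc = ReportDocument(
        schema_version=SCHEMA_VERSION,
        report=report,
        derived=_derive(report) if derived else None,
    )
    payload = doc.model_dump(mode="json", exclude_none=True)
    text = json.dumps(payload, indent=2, ensure_ascii=False) + "\n"
    if target is not None:
        if hasattr(target, "write"):
            target.write(text)
        else:
            Path(target).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# Reader-study CSV

_STUDY_COLUMNS = ["reader_id", "case_id", "method", "reported_code", "reference_code"]


def read_reader_study(source: PathOrStream) -> list[ReaderRecord]:
    """Read a reader-study CSV into typed records.

    Malformed reported codes are kept verbatim (validity is scored
    downstream); an unknown method, missing columns, or duplicate
    (reader, case, method) rows are rejected.
    """
    df = pd.read_csv(source, dtype=str).fillna("")
    missing = [c for c in _STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"reader-study table is missing columns: {missing}")
    dup = df.duplicated(subset=["reader_id", "case_id", "method"])
    if dup.any():
        rows = df.loc[dup, ["reader_id", "case_id", "method"]].to_dict("records")
        raise ValueError(f"duplicate (reader, case, method) rows: {rows}")
    bad = sorted(set(df["method"]) - set(VALID_METHODS))
    if bad:
        raise ValueError(f"unknown reporting method(s): {bad}")
    return [
        ReaderRecord(
            reader_id=r.reader_id,
            case_id=r.case_id,
            method=r.method,
            reported_code=r.reported_code,
            reference_code=r.reference_code,
        )
        for r in df[_STUDY_COLUMNS].itertuples(index=False)
    ]


def write_reader_study(records: Sequence[ReaderRecord] | pd.DataFrame, target: PathOrStream) -> None:
    """Write reader records to CSV with the canonical column order."""
    if isinstance(records, pd.DataFrame):
        df = records[_STUDY_COLUMNS]
    else:
        df = pd.DataFrame([r.__dict__ for r in records], columns=_STUDY_COLUMNS)
    if hasattr(target, "write"):
        df.to_csv(target, index=False)
    else:
        df.to_csv(Path(target), index=False)


# ---------------------------------------------------------------------------
# Rendering


def render_report_text(report: StructuredReport, classification: Optional[TNMClassification] = None) -> str:
    """Human-readable rendering with fixed section order:
    Primary tumor / Lymph nodes / Distant disease / TNM & stage."""
    if classification is None:
        classification = engine.classify_report(report)
    lines = [f"Structured staging report — case {report.case_id}", ""]
    lines.append("Primary tumor")
    p = report.primary
    if p.measurable:
        lines.append(f"  {p.lobe.value}, maximum multiplanar diameter {p.diameter_cm:.1f} cm")
    else:
        lines.append(f"  {p.lobe.value}, not measurable")
    if p.descriptors:
        for d in sorted(d.value for d in p.descriptors):
            lines.append(f"  invasion: {d.replace('_', ' ')}")
    else:
        lines.append("  invasion: none")
    if report.separate_nodules:
        for nd in report.separate_nodules:
            lines.append(f"  separate tumor nodule: {nd.lobe.value}")
    else:
        lines.append("  separate tumor nodules: none")
    lines.append("")
    lines.append("Lymph nodes")
    if report.nodes:
        for nf in report.nodes:
            verdict = "malignant" if nf.judged_malignant else "benign"
            lines.append(f"  station {nf.station} ({nf.side.value}): {verdict}")
    else:
        lines.append("  none")
    lines.append("")
    lines.append("Distant disease")
    if report.metastases:
        for mf in report.metastases:
            side = f", {mf.side.value}" if mf.side else ""
            lines.append(f"  {mf.site.value.replace('_', ' ')}{side}: {mf.lesion_count} lesion(s)")
    else:
        lines.append("  none")
    lines.append("")
    lines.append("TNM & stage")
    lines.append(f"  {engine.format_tnm(classification)}")
    lines.append(f"  UICC stage: {engine.uicc_stage(classification).value}")
    lines.append("")
    return "\n".join(lines)
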