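"""Inventory QA, pseudonymisation, repository layout and run records.

The RunRecord is the self-documenting audit trail: every pipeline operation
appends exactly one step, and the record is exportable as JSON plus a
non-interactive HTML page stored under the session's REPORTS resource.
Project-level metrics are recomputed solely from these records, so every
number in the aggregate table is auditable.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import hmac
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import jinja2

from . import dicomio
from .core import ImagingSession, ValidationError

__all__ = [
    "EXPECTED_SERIES",
    "InventoryReport",
    "RunRecord",
    "check_inventory",
    "pseudonym_for",
    "pseudonymise",
    "layout_repository",
    "project_metrics",
]

EXPECTED_SERIES = ("in_phase", "out_of_phase", "fat", "water", "b50", "b900", "adc")

RESOURCE_FOLDERS = ("DICOM", "NIFTI", "REPORTS", "SEGMENTATIONS", "ECRF")


@dataclass
class InventoryReport:
    expected: tuple[str, ...]
    present: tuple[str, ...]
    missing: tuple[str, ...]
    extraneous: tuple[str, ...]

    @property
    def verdict(self) -> str:
        return "complete" if not self.missing else "incomplete"


def check_inventory(
    session: ImagingSession, expected: Sequence[str] = EXPECTED_SERIES
) -> InventoryReport:
    """Exact set comparison of present contrast labels against the expected list."""
    if not expected:
        raise ValidationError("expected series list must be non-empty")
    present = tuple(sorted(session.series.keys()))
    expected_t = tuple(expected)
    missing = tuple(sorted(set(expected_t) - set(present)))
    extraneous = tuple(
        sorted((set(present) - set(expected_t)) | set(session.extra_series))
    )
    return InventoryReport(
        expected=expected_t, present=present, missing=missing, extraneous=extraneous
    )


# ---------------------------------------------------------------------------
# Run record
# ---------------------------------------------------------------------------

_HTML_TEMPLATE = jinja2.Template(
    """<!doctype html>
<html><head><meta charset="utf-8"><title>Run record {{ session_id }}</title>
<style>body{font-family:sans-serif;margin:2em}table{border-collapse:collapse}
td,th{border:1px solid #999;padding:4px 8px;text-align:left}</style></head>
<body><h1>Curation run record</h1>
<p>Session <b>{{ session_id }}</b> &middot; tool {{ tool_version }} &middot;
config hash <code>{{ config_hash }}</code></p>
<table><tr><th>#</th><th>time (UTC)</th><th>step</th><th>params</th><th>findings</th></tr>
{% for s in steps %}<tr><td>{{ loop.index }}</td><td>{{ s.timestamp }}</td>
<td>{{ s.name }}</td><td><code>{{ s.params }}</code></td>
<td><code>{{ s.findings }}</code></td></tr>{% endfor %}
</table></body></html>
"""
)


@dataclass
class RunRecord:
    """Append-only, timestamped log of every curation action on one session."""

    session_id: str
    tool_version: str = "wbcure 0.1.0"
    config: dict = field(default_factory=dict)
    steps: list[dict] = field(default_factory=list)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def add_step(self, name: str, params: dict | None = None, findings=None) -> dict:
        step = {
            "name": name,
            "params": params or {},
            "findings": findings,
            "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        }
        self.steps.append(step)
        return step

    def to_json(self) -> str:
        return json.dumps(
            {
                "session_id": self.session_id,
                "tool_version": self.tool_version,
                "config_hash": self.config_hash,
                "config": self.config,
                "steps": self.steps,
            },
            indent=2,
            default=str,
        )

    def to_html(self) -> str:
        return _HTML_TEMPLATE.render(
            session_id=self.session_id,
            tool_version=self.tool_version,
            config_hash=self.config_hash,
            steps=[
                {
                    "name": s["name"],
                    "params": json.dumps(s["params"], default=str),
                    "findings": json.dumps(s["findings"], default=str),
                    "timestamp": s["timestamp"],
                }
                for s in self.steps
            ],
        )

    def save(self, directory) -> tuple[str, str]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        jpath = directory / "runrecord.json"
        hpath = directory / "runrecord.html"
        jpath.write_text(self.to_json())
        hpath.write_text(self.to_html())
        return str(jpath), str(hpath)

    @classmethod
    def load(cls, path) -> "RunRecord":
        doc = json.loads(Path(path).read_text())
        rec = cls(
            session_id=doc["session_id"],
            tool_version=doc.get("tool_version", "unknown"),
            config=doc.get("config", {}),
        )
        rec.steps = doc.get("steps", [])
        return rec


# ---------------------------------------------------------------------------
# Pseudonymisation
# ---------------------------------------------------------------------------

#: Conservative subset of the DICOM basic confidentiality profile: tags whose
#: values are replaced by pseudonyms, blanked, or shifted.
_REPLACE_WITH_PSEUDONYM = (
    dicomio.TAG["PatientName"],
    dicomio.TAG["PatientID"],
)
_BLANK_TAGS = (
    dicomio.TAG["InstitutionName"],
    dicomio.TAG["ReferringPhysicianName"],
    dicomio.TAG["PatientBirthDate"],
)
_DATE_TAGS = (
    dicomio.TAG["StudyDate"],
    dicomio.TAG["SeriesDate"],
)
_MARKER_TAG = dicomio.TAG["PatientIdentityRemoved"]


def pseudonym_for(patient_id: str, salt: str) -> str:
    """Deterministic keyed-hash pseudonym (HMAC-SHA256, 16 hex chars)."""
    return "SUB-" + hmac.new(salt.encode(), patient_id.encode(), hashlib.sha256).hexdigest()[:16]


def _shift_days(patient_id: str, salt: str) -> int:
    h = hmac.new(salt.encode(), (patient_id + "|dates").encode(), hashlib.sha256)
    return int(h.hexdigest()[:4], 16) % 3650 + 1  # 1..3650 days back


def pseudonymise(
    files: Iterable, id_map: dict[str, str], salt: str, out_dir
) -> tuple[list[str], dict[str, str], list[str]]:
    """De-identify DICOM files into ``out_dir``; returns (written, id_map, skipped).

    Identifying tags are replaced (patient name/id -> keyed-hash pseudonym),
    blanked, or date-shifted by a per-patient deterministic offset; private
    tags (odd groups) are stripped.  Pixel data and geometry are untouched.
    Files already carrying the identity-removed marker are skipped with a log
    entry.  ``id_map`` (pseudonym -> original id) is updated in place.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    skipped: list[str] = []
    for f in files:
        f = Path(f)
        ds = dicomio.read_dataset(f)
        if ds.get(_MARKER_TAG, (None, ""))[1] == "YES":
            skipped.append(str(f))
            continue
        patient_id = str(ds.get(dicomio.TAG["PatientID"], ("LO", "UNKNOWN"))[1])
        pseudo = pseudonym_for(patient_id, salt)
        id_map[pseudo] = patient_id
        ds = {tag: v for tag, v in ds.items() if tag[0] % 2 == 0}  # strip private
        for tag in _REPLACE_WITH_PSEUDONYM:
            if tag in ds:
                ds[tag] = (ds[tag][0], pseudo)
        # the study/session label usually embeds the patient id
        study_tag = dicomio.TAG["StudyID"]
        if study_tag in ds:
            ds[study_tag] = ("SH", pseudonym_for(str(ds[study_tag][1]), salt)[:16])
        for tag in _BLANK_TAGS:
            if tag in ds:
                ds[tag] = (ds[tag][0], "")
        days = _shift_days(patient_id, salt)
        for tag in _DATE_TAGS:
            if tag in ds and ds[tag][1]:
                try:
                    d = _dt.datetime.strptime(str(ds[tag][1]), "%Y%m%d")
                    ds[tag] = ("DA", (d - _dt.timedelta(days=days)).strftime("%Y%m%d"))
                except ValueError:
                    ds[tag] = ("DA", "")
        ds[_MARKER_TAG] = ("CS", "YES")
        target = out_dir / f.name
        dicomio.write_dataset(target, ds)
        written.append(str(target))
    return written, id_map, skipped


def save_id_map(id_map: dict[str, str], path) -> None:
    """Persist the pseudonym map with restrictive permissions (0600)."""
    path = Path(path)
    path.write_text(json.dumps(id_map, indent=2, sort_keys=True))
    os.chmod(path, 0o600)


# ---------------------------------------------------------------------------
# Repository layout and project metrics
# ---------------------------------------------------------------------------


def layout_repository(
    project_dir, sessions: Sequence[tuple[str, str]], resources: Sequence[str] = RESOURCE_FOLDERS
) -> list[str]:
    """Create the project/subject/session/resource hierarchy.

    ``sessions`` rows are (subject_id, session_id).  Idempotent on an existing
    identical tree; duplicate session ids are an error.
    """
    project_dir = Path(project_dir)
    ids = [s for _, s in sessions]
    if len(set(ids)) != len(ids):
        dup = sorted({s for s in ids if ids.count(s) > 1})[0]
        raise ValidationError(f"duplicate session id {dup!r}")
    created = []
    for subject_id, session_id in sessions:
        for res in resources:
            d = project_dir / subject_id / session_id / res
            d.mkdir(parents=True, exist_ok=True)
            created.append(str(d))
    return created


def project_metrics(project_dir) -> dict:
    """Aggregate table recomputed solely from stored RunRecords."""
    project_dir = Path(project_dir)
    records, corrupt = [], []
    sessions_seen = set()
    missing_record = []
    for session_dir in sorted(project_dir.glob("*/*")):
        if not session_dir.is_dir():
            continue
        sessions_seen.add(session_dir.name)
        rr = session_dir / "REPORTS" / "runrecord.json"
        if not rr.exists():
            missing_record.append(session_dir.name)
            continue
        try:
            records.append(RunRecord.load(rr))
        except (json.JSONDecodeError, KeyError):
            corrupt.append(str(rr))

    n_curated = len(records)
    n_swap = 0
    excluded: dict[str, int] = {}
    protocol_mix: dict[str, int] = {}
    for rec in records:
        step_names = [s["name"] for s in rec.steps]
        swap_steps = [s for s in rec.steps if s["name"] == "detect_swaps"]
        if any(s.get("findings") for s in swap_steps):
            n_swap += 1
        for s in rec.steps:
            if s["name"] == "exclude_session":
                reason = s["params"].get("reason", "unspecified")
                excluded[reason] = excluded.get(reason, 0) + 1
            if s["name"] == "identify_protocol":
                proto = s["params"].get("protocol", "unknown")
                protocol_mix[proto] = protocol_mix.get(proto, 0) + 1
        del step_names
    return {
        "sessions_curated": n_curated,
        "sessions_excluded_by_reason": excluded,
        "swap_prevalence_percent": (100.0 * n_swap / n_curated) if n_curated else 0.0,
        "protocol_mix": protocol_mix,
        "sessions_missing_runrecord": missing_record,
        "corrupt_runrecords": corrupt,
    }
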