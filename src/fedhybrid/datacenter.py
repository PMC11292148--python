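"""Schema-driven data sharing: dictionary validation, cleaning, aggregation.

Multi-provider data pooling needs three things before any record enters the
shared pool: an agreed schema (the *data dictionary* — a static document
declaring field names, types, required status, valid ranges and the key
fields that identify a record), a cleaning pass that enforces it, and an
append step that accumulates cleaned shares into one core file while
keeping an auditable provenance trail and a copy of every upload.

Cleaning applies three rules in a fixed order, and each rejected row is
charged to the FIRST rule it violates:

1. missing   — a required field is empty;
2. range     — a value cannot be coerced to its declared type or falls
               outside its declared range / allowed set;
3. duplicate — the row repeats an earlier row's key fields (first
               occurrence wins).

At append time, keys already present in the core also win over the incoming
share (earlier uploads take precedence), and the drops are recorded in the
provenance entry. The report's counts always reconcile:
records_in = records_out + dropped_missing + dropped_range + dropped_duplicate.

A hook point (``enhance``) accepts a user-supplied transformation applied
after cleaning, mirroring study-authored enhancement scripts; the package
itself performs no imputation or derivation.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FieldSpec",
    "DataDictionary",
    "CleaningReport",
    "DictionaryError",
    "validate_dictionary",
    "clean_records",
    "aggregate_share",
]

FIELD_TYPES = ("integer", "real", "categorical", "date-string")


class DictionaryError(ValueError):
    """Schema violations; the message lists every offending field."""


@dataclass
class FieldSpec:
    name: str
    type: str
    required: bool = False
    range: list | None = None  # [min, max] for numeric/date, allowed set for categorical


@dataclass
class DataDictionary:
    fields: list[FieldSpec]
    key_fields: list[str]
    version: str = "1"

    @property
    def field_names(self) -> list[str]:
        return [f.name for f in self.fields]

    @property
    def required_names(self) -> list[str]:
        return [f.name for f in self.fields if f.required]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DataDictionary":
        return validate_dictionary(json.loads(text))


def validate_dictionary(raw: dict) -> DataDictionary:
    """Validate a parsed dictionary document, collecting every schema error."""
    errors = []
    raw_fields = raw.get("fields", [])
    fields = []
    seen = set()
    for f in raw_fields:
        spec = FieldSpec(**f) if isinstance(f, dict) else f
        if spec.name in seen:
            errors.append(f"duplicate field name {spec.name!r}")
        seen.add(spec.name)
        if spec.type not in FIELD_TYPES:
            errors.append(f"field {spec.name!r}: unknown type {spec.type!r}")
        fields.append(spec)
    key_fields = list(raw.get("key_fields", []))
    if not key_fields:
        errors.append("key_fields must be non-empty")
    by_name = {f.name: f for f in fields}
    for k in key_fields:
        if k not in by_name:
            errors.append(f"key field {k!r} is not declared")
        elif not by_name[k].required:
            errors.append(f"key field {k!r} must be required")
    if errors:
        raise DictionaryError("; ".join(errors))
    return DataDictionary(fields=fields, key_fields=key_fields,
                          version=str(raw.get("version", "1")))


@dataclass
class CleaningReport:
    records_in: int
    dropped_missing: int
    dropped_range: int
    dropped_duplicate: int
    records_out: int
    rejected: list[tuple[int, str]]  # (row index in the share, first rule violated)

    def reconciles(self) -> bool:
        return self.records_in == (
            self.records_out
            + self.dropped_missing
            + self.dropped_range
            + self.dropped_duplicate
        )


def _coerce(value, spec: FieldSpec):
    """Coerce to the declared type; return (ok, coerced)."""
    if spec.type in ("integer", "real"):
        try:
            num = float(value)
        except (TypeError, ValueError):
            return False, None
        if not np.isfinite(num):
            return False, None
        if spec.type == "integer" and num != int(num):
            return False, None
        return True, int(num) if spec.type == "integer" else num
    if spec.type == "date-string":
        try:
            return True, datetime.date.fromisoformat(str(value).strip())
        except ValueError:
            return False, None
    return True, str(value)  # categorical


def _in_range(coerced, spec: FieldSpec) -> bool:
    if spec.range is None:
        return True
    if spec.type == "categorical":
        return str(coerced) in {str(v) for v in spec.range}
    lo, hi = spec.range
    if spec.type == "date-string":
        lo, hi = datetime.date.fromisoformat(lo), datetime.date.fromisoformat(hi)
    return lo <= coerced <= hi


def _is_missing(value) -> bool:
    return pd.isna(value) or (isinstance(value, str) and value.strip() == "")


def clean_records(
    records: pd.DataFrame, dictionary: DataDictionary, enhance=None
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the missing -> range -> duplicate rules; reconcile exactly.

    ``enhance``, if given, is a DataFrame -> DataFrame hook applied to the
    surviving rows (it may not change the row count). Raises
    DictionaryError when a required column is absent from the share.
    """
    missing_cols = [c for c in dictionary.required_names if c not in records.columns]
    if missing_cols:
        raise DictionaryError(f"share rejected: required columns absent {missing_cols}")

    rejected: list[tuple[int, str]] = []
    keep_rows = []
    seen_keys = set()
    by_name = {f.name: f for f in dictionary.fields}
    for idx in range(len(records)):
        row = records.iloc[idx]
        reason = None
        for name in dictionary.required_names:
            if _is_missing(row[name]):
                reason = "missing"
                break
        if reason is None:
            for name, spec in by_name.items():
                if name not in records.columns or _is_missing(row[name]):
                    continue  # optional absent values are not range errors
                ok, coerced = _coerce(row[name], spec)
                if not ok or not _in_range(coerced, spec):
                    reason = "range"
                    break
        if reason is None:
            key = tuple(str(row[k]) for k in dictionary.key_fields)
            if key in seen_keys:
                reason = "duplicate"
            else:
                seen_keys.add(key)
        if reason is None:
            keep_rows.append(idx)
        else:
            rejected.append((idx, reason))

    clean = records.iloc[keep_rows].reset_index(drop=True)
    if enhance is not None:
        clean = enhance(clean)
        if len(clean) != len(keep_rows):
            raise DictionaryError("enhance hook may not change the row count")
    report = CleaningReport(
        records_in=len(records),
        dropped_missing=sum(1 for _, r in rejected if r == "missing"),
        dropped_range=sum(1 for _, r in rejected if r == "range"),
        dropped_duplicate=sum(1 for _, r in rejected if r == "duplicate"),
        records_out=len(clean),
        rejected=rejected,
    )
    assert report.reconciles()
    return clean, report


def aggregate_share(
    core_path: str | Path,
    share: pd.DataFrame,
    dictionary: DataDictionary,
    uploads_dir: str | Path | None = None,
    upload_label: str | None = None,
) -> dict:
    """Append a cleaned share to the core file; return the provenance entry.

    The core CSV carries the dictionary version in a sidecar
    (``<core>.meta.json``); a version mismatch rejects the share. Keys
    already present in the core win, and such rows are dropped and counted.
    Each upload is also persisted as its own file (timestamped, or named by
    ``upload_label`` for reproducible pipelines), and a JSON-lines
    provenance log next to the core records every append.
    """
    core_path = Path(core_path)
    meta_path = core_path.with_suffix(core_path.suffix + ".meta.json")
    log_path = core_path.with_suffix(core_path.suffix + ".provenance.jsonl")

    if core_path.exists():
        meta = json.loads(meta_path.read_text())
        if meta["version"] != dictionary.version:
            raise DictionaryError(
                f"dictionary version mismatch: core {meta['version']!r}, "
                f"share {dictionary.version!r}"
            )
        core = pd.read_csv(core_path, dtype=str)
    else:
        core_path.parent.mkdir(parents=True, exist_ok=True)
        meta_path.write_text(json.dumps({"version": dictionary.version}))
        core = pd.DataFrame(columns=[str(c) for c in share.columns])

    share_str = share.astype(str)
    core_keys = {
        tuple(str(v) for v in row)
        for row in core[dictionary.key_fields].itertuples(index=False)
    } if len(core) else set()
    fresh = [
        i for i in range(len(share_str))
        if tuple(share_str.iloc[i][k] for k in dictionary.key_fields) not in core_keys
    ]
    appended = share_str.iloc[fresh]
    updated = pd.concat([core, appended], ignore_index=True)
    updated.to_csv(core_path, index=False)

    label = upload_label or datetime.datetime.now().strftime("%Y%m%dT%H%M%S%f")
    upload_path = None
    if uploads_dir is not None:
        uploads_dir = Path(uploads_dir)
        uploads_dir.mkdir(parents=True, exist_ok=True)
        upload_path = uploads_dir / f"upload_{label}.csv"
        share.to_csv(upload_path, index=False)

    entry = {
        "upload": label,
        "rows_in_share": int(len(share)),
        "rows_appended": int(len(appended)),
        "rows_dropped_cross_share_duplicate": int(len(share) - len(appended)),
        "core_rows_after": int(len(updated)),
        "dictionary_version": dictionary.version,
        "upload_file": str(upload_path) if upload_path else None,
    }
    with open(log_path, "a") as fh:
        fh.write(json.dumps(entry) + "\n")
    return entry
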