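"""Reading and writing of flat study records and canonical JSON.

All JSON emitted by the package goes through :func:`canonical_dumps` so that
identical inputs produce byte-identical artifacts across runs: UTF-8, sorted
keys (FHIR JSON does not fix key order), compact separators, and a trailing
newline on files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Iterable

from pydantic import ValidationError

from .core_model import StudyRecord, MasterStudy


class NdjsonError(ValueError):
    """A malformed NDJSON line; carries the 1-based line number."""

    def __init__(self, path: str, line_no: int, message: str):
        self.path = path
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


def canonical_dumps(obj: Any) -> str:
    return json.dumps(obj, sort_keys=True, ensure_ascii=False, separators=(",", ":"))


def write_json(path: str | Path, obj: Any) -> None:
    Path(path).write_text(canonical_dumps(obj) + "\n", encoding="utf-8")


def read_ndjson(path: str | Path) -> list[dict]:
    """Parse an NDJSON file into dicts, reporting the offending line on error."""
    rows: list[dict] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise NdjsonError(str(path), line_no, f"invalid JSON: {exc.msg}") from exc
            if not isinstance(obj, dict):
                raise NdjsonError(str(path), line_no, "expected a JSON object")
            rows.append(obj)
    return rows


def write_ndjson(path: str | Path, objs: Iterable[Any]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for obj in objs:
            fh.write(canonical_dumps(obj) + "\n")


def record_to_dict(record: StudyRecord | MasterStudy) -> dict:
    return record.model_dump(mode="json")


def read_study_records(path: str | Path) -> list[StudyRecord]:
    """Load flat StudyRecords from NDJSON (or a JSON array file)."""
    text_head = _peek_nonspace(path)
    records: list[StudyRecord] = []
    if text_head == "[":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        for idx, obj in enumerate(data):
            records.append(_parse_record(StudyRecord, obj, str(path), idx + 1))
        return records
    for line_no, obj in enumerate(read_ndjson(path), start=1):
        records.append(_parse_record(StudyRecord, obj, str(path), line_no))
    return records


def read_master_studies(path: str | Path) -> list[MasterStudy]:
    return [
        _parse_record(MasterStudy, obj, str(path), line_no)
        for line_no, obj in enumerate(read_ndjson(path), start=1)
    ]


def write_study_records(path: str | Path, records: Iterable[StudyRecord | MasterStudy]) -> None:
    write_ndjson(path, (record_to_dict(r) for r in records))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _peek_nonspace(path: str | Path) -> str:
    with open(path, encoding="utf-8") as fh:
        while True:
            ch = fh.read(1)
            if not ch:
                return ""
            if not ch.isspace():
                return ch


def _parse_record(model: type, obj: dict, path: str, line_no: int):
    try:
        return model.model_validate(obj)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise NdjsonError(path, line_no, f"{loc}: {first['msg']}") from exc
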