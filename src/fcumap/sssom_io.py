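"""SSSOM TSV reader/writer, embedded-metadata mode.

The exchange format is a single TSV file whose set-level metadata is written
first as ``#``-prefixed YAML, followed by a tab-separated header and one row
per mapping. The column order is frozen; readers tolerate any column order,
missing optional columns and unknown extra columns (preserved verbatim on
re-write). Ids are CURIE-contracted through the set's curie map; dates are
ISO-8601 timestamps (date-only input is promoted to midnight UTC) and a
confidence of 1.0 renders as ``1``.

Writing is deterministic down to the byte: ``write(read(write(S)))`` equals
``write(S)``.
"""

from __future__ import annotations

import csv
import io

import yaml

from .curies import CurieMap
from .errors import FormatError, RowError, WriteRefusedError
from .mapping_core import Mapping, MappingSet, MappingSetMeta

__all__ = ["write_tsv", "read_tsv", "write_tsv_string", "read_tsv_string",
           "COLUMNS", "MANDATORY_COLUMNS"]

#: set-level metadata keys, in emission order
META_KEYS = ["mapping_set_id", "creator_id", "creator_label", "curie_map",
             "subject_source", "subject_source_version", "object_source",
             "object_source_version", "license"]

#: mapping columns, in frozen emission order
COLUMNS = ["subject_id", "subject_label", "predicate_id", "predicate_label",
           "object_id", "object_label", "confidence", "mapping_justification",
           "mapping_cardinality", "subject_type", "object_type", "author_id",
           "author_label", "reviewer_id", "reviewer_label", "mapping_date",
           "curation_rule_text", "comment"]

MANDATORY_COLUMNS = ["subject_id", "predicate_id", "object_id"]


def _yaml_scalar(value: str) -> str:
    return "'" + value.replace("'", "''") + "'"


def _format_confidence(confidence: float) -> str:
    if confidence == int(confidence):
        return str(int(confidence))
    return format(confidence, "g")


def _normalize_date(value: str) -> str:
    value = value.strip()
    if len(value) == 10 and value[4] == "-" and value[7] == "-":
        return value + "T00:00:00Z"
    return value


def write_tsv_string(mapping_set: MappingSet) -> str:
    """Render a mapping set to embedded-mode SSSOM TSV text."""
    meta = mapping_set.meta
    for m in mapping_set.mappings:
        for col in MANDATORY_COLUMNS:
            if not getattr(m, col):
                raise WriteRefusedError(f"mapping missing mandatory field {col!r}")
    buf = io.StringIO()
    for key in META_KEYS:
        if key == "curie_map":
            if meta.curie_map.bindings:
                buf.write("#curie_map:\n")
                for prefix in sorted(meta.curie_map.bindings):
                    buf.write(f"#  {prefix}: {_yaml_scalar(meta.curie_map.bindings[prefix])}\n")
            continue
        value = getattr(meta, key)
        if value is not None:
            buf.write(f"#{key}: {_yaml_scalar(str(value))}\n")

    extra_columns: list[str] = []
    for m in mapping_set.mappings:
        for col, _ in m.extras:
            if col not in extra_columns:
                extra_columns.append(col)

    writer = csv.writer(buf, delimiter="\t", lineterminator="\n",
                        quoting=csv.QUOTE_NONE, quotechar=None, escapechar=None)
    writer.writerow(COLUMNS + extra_columns)
    for m in mapping_set.mappings:
        row = []
        for col in COLUMNS:
            value = getattr(m, col)
            if col == "confidence":
                row.append(_format_confidence(value))
            elif col == "mapping_date" and value is not None:
                row.append(_normalize_date(value))
            else:
                row.append("" if value is None else str(value))
        extras = dict(m.extras)
        row.extend(extras.get(col, "") for col in extra_columns)
        writer.writerow(row)
    return buf.getvalue()


def write_tsv(mapping_set: MappingSet, path) -> None:
    """Write embedded-mode SSSOM TSV (UTF-8, Unix newlines)."""
    text = write_tsv_string(mapping_set)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)


def read_tsv_string(text: str) -> MappingSet:
    """Parse embedded-mode SSSOM TSV text into a mapping set."""
    lines = text.splitlines()
    meta_lines: list[str] = []
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            meta_lines.append(line[1:])
            body_start = i + 1
        else:
            break
    if not meta_lines:
        raise FormatError("no embedded metadata block (expected '#'-prefixed YAML)")
    try:
        meta_doc = yaml.safe_load("\n".join(meta_lines)) or {}
    except yaml.YAMLError as exc:
        raise FormatError(f"unparsable metadata block: {exc}") from exc
    if not isinstance(meta_doc, dict):
        raise FormatError("metadata block is not a YAML mapping")

    curie_map = CurieMap(bindings={str(k): str(v)
                                   for k, v in (meta_doc.get("curie_map") or {}).items()})
    meta = MappingSetMeta(
        mapping_set_id=str(meta_doc.get("mapping_set_id") or ""),
        license=str(meta_doc.get("license") or ""),
        curie_map=curie_map,
        creator_id=_opt(meta_doc, "creator_id"),
        creator_label=_opt(meta_doc, "creator_label"),
        subject_source=_opt(meta_doc, "subject_source"),
        subject_source_version=_opt(meta_doc, "subject_source_version"),
        object_source=_opt(meta_doc, "object_source"),
        object_source_version=_opt(meta_doc, "object_source_version"),
    )

    body = lines[body_start:]
    mappings: list[Mapping] = []
    if body and body[0].strip():
        rows = list(csv.reader(body, delimiter="\t", quoting=csv.QUOTE_NONE,
                               quotechar=None))
        header = rows[0]
        known = set(COLUMNS)
        for rownum, row in enumerate(rows[1:], start=body_start + 2):
            if not any(cell.strip() for cell in row):
                continue
            cells = {header[j]: row[j] if j < len(row) else "" for j in range(len(header))}
            for col in MANDATORY_COLUMNS:
                if not cells.get(col, "").strip():
                    raise RowError(f"missing mandatory cell {col!r}", rownum)
            kwargs = {}
            for col in COLUMNS:
                raw = cells.get(col, "").strip()
                if col == "confidence":
                    kwargs[col] = float(raw) if raw else 1.0
                elif col == "mapping_cardinality":
                    kwargs[col] = raw.lower() if raw else None
                elif col == "mapping_date":
                    kwargs[col] = _normalize_date(raw) if raw else None
                else:
                    kwargs[col] = raw or None
            extras = tuple((col, cells[col]) for col in header if col not in known)
            mappings.append(Mapping(**kwargs, extras=extras))
    return MappingSet(meta=meta, mappings=mappings)


def _opt(doc: dict, key: str) -> str | None:
    value = doc.get(key)
    return None if value is None else str(value)


def read_tsv(path) -> MappingSet:
    """Read an embedded-mode SSSOM TSV file."""
    with open(path, encoding="utf-8") as fh:
        return read_tsv_string(fh.read())
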