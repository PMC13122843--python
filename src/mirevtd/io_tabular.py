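"""CSV reading/writing and low-level cell checks for trait datasets.

The standard asks for machine-readable, text-based files — comma-separated
values (RFC 4180), UTF-8, ISO 8601 dates, no diacritics, no abbreviations,
numbers separated from their units.  This module owns those conventions:
cells are stored verbatim as text, a write→read round trip is the identity,
and the stricter interpretations (NA as missing, non-ISO dates recognized but
rejected) are documented here and enforced by the validation rule engine.
"""

from __future__ import annotations

import copy
import csv
import datetime as _dt
import io
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from ._errors import EncodingError, StructuralError
from .schema import DatasetSchema, FieldSpec, MAX_TEXT_LENGTH

#: Cell values treated as missing, in addition to the empty string.
MISSING_SENTINELS = ("", "NA")

_NUMERIC_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")
_ISO_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")

#: Date formats recognized as dates but rejected for not being ISO 8601.
_NON_ISO_FORMATS = (
    "%d/%m/%Y", "%m/%d/%Y", "%d/%m/%y", "%Y/%m/%d",
    "%d-%m-%Y", "%d.%m.%Y", "%Y.%m.%d",
    "%B %d, %Y", "%d %B %Y", "%b %d, %Y", "%d %b %Y", "%Y%m%d",
)

#: Tokens flagged by the abbreviation heuristic regardless of length.
ABBREVIATION_BLACKLIST = frozenset({"spp.", "sp.", "temp.", "rh", "dpi", "avg.", "no."})

_SHORT_ABBREV_RE = re.compile(r"^[A-Za-z]{1,3}\.$")


def is_missing(cell: str) -> bool:
    """True if the cell encodes a missing value (empty or the NA sentinel)."""
    return cell.strip() in MISSING_SENTINELS


def parse_numeric(cell: str):
    """Parse a cell as a plain decimal number; return float or None.

    Accepts optionally signed decimal/scientific notation only — '45 days'
    fails, which is exactly how mixed value+unit cells are detected.
    """
    s = cell.strip()
    if not _NUMERIC_RE.match(s):
        return None
    return float(s)


@dataclass(frozen=True)
class IsoDateResult:
    ok: bool
    date: _dt.date | None = None
    reason: str | None = None  # 'non_iso_parseable' | 'unparseable'


def parse_iso_date(cell: str) -> IsoDateResult:
    """Strict ISO 8601 calendar-date parse with graded failure reasons.

    Accepts exactly YYYY-MM-DD naming a real calendar date.  Common non-ISO
    layouts (DD/MM/YYYY, 'March 1, 2022', ...) are recognized but rejected
    with reason ``non_iso_parseable``; anything else is ``unparseable``.
    """
    s = cell.strip()
    if _ISO_DATE_RE.match(s):
        try:
            y, m, d = (int(p) for p in s.split("-"))
            return IsoDateResult(True, _dt.date(y, m, d))
        except ValueError:
            return IsoDateResult(False, reason="unparseable")
    for fmt in _NON_ISO_FORMATS:
        try:
            _dt.datetime.strptime(s, fmt)
            return IsoDateResult(False, reason="non_iso_parseable")
        except ValueError:
            continue
    return IsoDateResult(False, reason="unparseable")


@dataclass(frozen=True)
class TextIssue:
    code: str  # 'NON_ASCII' | 'ABBREVIATION_SUSPECT'
    detail: str


def scan_text_issues(cell: str) -> list[TextIssue]:
    """Flag non-ASCII characters and suspected abbreviations in a cell.

    NON_ASCII reports each distinct code point above 127 (diacritics and
    other special characters break naive tooling).  ABBREVIATION_SUSPECT is a
    heuristic: a token on a known blacklist (spp., RH, dpi, ...) or any token
    of at most three letters ending in a period.
    """
    issues: list[TextIssue] = []
    seen: set[str] = set()
    for ch in cell:
        if ord(ch) > 127 and ch not in seen:
            seen.add(ch)
            issues.append(TextIssue("NON_ASCII", ch))
    for raw in cell.split():
        token = raw.strip("()[]{}\"',;:")
        if not token:
            continue
        if token.lower() in ABBREVIATION_BLACKLIST or _SHORT_ABBREV_RE.match(token):
            issues.append(TextIssue("ABBREVIATION_SUSPECT", token))
    return issues


@dataclass
class DatasetMetadata:
    """Study/project metadata accompanying a trait dataset.

    The standard's minimum: a full citation of the data source, the name and
    contact of the submitter, and (if relevant) the date any embargo lifts.
    ``condition_tags`` carry the user-declared study properties that trigger
    conditional schema fields (e.g. ``transmission_study``).
    """

    citation: str = ""
    doi: str | None = None
    submitter_name: str = ""
    submitter_contact: str = ""
    embargo_date: str | None = None
    condition_tags: set[str] = field(default_factory=set)
    license_label: str | None = None

    def to_json(self) -> str:
        doc = {
            "citation": self.citation,
            "doi": self.doi,
            "submitter_name": self.submitter_name,
            "submitter_contact": self.submitter_contact,
            "embargo_date": self.embargo_date,
            "condition_tags": sorted(self.condition_tags),
            "license_label": self.license_label,
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DatasetMetadata":
        doc = json.loads(text)
        return cls(
            citation=doc.get("citation", ""),
            doi=doc.get("doi"),
            submitter_name=doc.get("submitter_name", ""),
            submitter_contact=doc.get("submitter_contact", ""),
            embargo_date=doc.get("embargo_date"),
            condition_tags=set(doc.get("condition_tags", [])),
            license_label=doc.get("license_label"),
        )


@dataclass
class TraitDataset:
    """One trait dataset: metadata, its schema, and verbatim text rows.

    Every row holds exactly the schema's field set; a missing cell is the
    empty string.  Rows preserve input order.  Typed views are derived on
    demand (``to_dataframe``, ``numeric_column``); the cells themselves are
    never coerced.
    """

    metadata: DatasetMetadata
    schema: DatasetSchema
    rows: list[dict[str, str]]
    label: str = "dataset"

    def __post_init__(self) -> None:
        names = self.schema.field_names()
        nameset = set(names)
        for i, row in enumerate(self.rows):
            if set(row) != nameset:
                missing = nameset - set(row)
                extra = set(row) - nameset
                raise StructuralError(
                    f"row {i} does not match schema fields "
                    f"(missing {sorted(missing)}, extra {sorted(extra)})"
                )

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, name: str) -> list[str]:
        return [row[name] for row in self.rows]

    def numeric_column(self, name: str) -> list[float]:
        """Parse a column as numbers, raising on the first bad cell."""
        out = []
        for i, cell in enumerate(self.column(name)):
            v = parse_numeric(cell)
            if v is None:
                raise ValueError(f"row {i}: cell {cell!r} in field {name!r} is not numeric")
            out.append(v)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.schema.field_names(), dtype=str)

    def copy(self) -> "TraitDataset":
        return TraitDataset(
            metadata=copy.deepcopy(self.metadata),
            schema=self.schema,
            rows=[dict(r) for r in self.rows],
            label=self.label,
        )


def read_dataset(
    source,
    schema: DatasetSchema,
    alias_map: dict[str, str] | None = None,
    metadata: DatasetMetadata | None = None,
    label: str | None = None,
) -> TraitDataset:
    """Read a UTF-8 RFC 4180 CSV into a :class:`TraitDataset`.

    Header names bind to schema fields by exact match, then through
    ``alias_map``; unbound columns are retained as extra fields (the standard
    allows additional columns).  Cells are stored verbatim.  Metadata travels
    out of band (a JSON sidecar) and may be attached here.

    Raises :class:`EncodingError` on undecodable bytes and
    :class:`StructuralError` on duplicate headers or ragged rows (naming the
    row number).
    """
    alias_map = alias_map or {}
    if isinstance(source, (str, Path)):
        raw = Path(source).read_bytes()
        if label is None:
            label = Path(source).name
    elif isinstance(source, bytes):
        raw = source
    else:  # file-like
        raw = source.read()
        if isinstance(raw, str):
            raw = raw.encode("utf-8")
    try:
        text = raw.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise EncodingError(f"input is not valid UTF-8: {exc}") from exc

    reader = csv.reader(io.StringIO(text, newline=""))
    try:
        header = next(reader)
    except StopIteration:
        raise StructuralError("empty file: no header record") from None
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise StructuralError(f"duplicate header names: {dupes}")

    bound: dict[str, str] = {}  # header -> canonical field name
    extra_fields: list[FieldSpec] = []
    known = set(schema.field_names())
    for h in header:
        if h in known:
            target = h
        elif h in alias_map and alias_map[h] in known:
            target = alias_map[h]
        else:
            extra_fields.append(
                FieldSpec(_sanitize_extra_name(h, known), "other", "recommended", "text")
            )
            target = extra_fields[-1].name
            known.add(target)
        if target in bound.values():
            raise StructuralError(f"two columns bind to field {target!r}")
        bound[h] = target

    full_schema = (
        replace(schema, fields=schema.fields + tuple(extra_fields))
        if extra_fields
        else schema
    )
    all_names = full_schema.field_names()

    rows: list[dict[str, str]] = []
    for i, record in enumerate(reader):
        if len(record) != len(header):
            raise StructuralError(
                f"ragged row {i}: {len(record)} cells, header has {len(header)}"
            )
        row = {name: "" for name in all_names}
        for h, cell in zip(header, record):
            row[bound[h]] = cell
        rows.append(row)

    return TraitDataset(
        metadata=metadata or DatasetMetadata(),
        schema=full_schema,
        rows=rows,
        label=label or "dataset",
    )


def _sanitize_extra_name(header: str, taken: set[str]) -> str:
    base = re.sub(r"[^A-Za-z0-9_]", "_", header.strip()) or "extra"
    if not base[0].isalpha():
        base = "x_" + base
    name = base
    k = 2
    while name in taken:
        name = f"{base}_{k}"
        k += 1
    return name[:MAX_TEXT_LENGTH]


def write_dataset(dataset: TraitDataset, sink) -> None:
    """Write a dataset as RFC 4180 CSV (UTF-8, CRLF, minimal quoting).

    The header row is the canonical field names in schema order; a
    ``read_dataset`` of the written file reproduces the dataset cell for
    cell and row for row.
    """
    names = dataset.schema.field_names()
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8", newline="") as fh:
            _write_rows(fh, names, dataset.rows)
    else:
        _write_rows(sink, names, dataset.rows)


def _write_rows(fh, names, rows) -> None:
    writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL, lineterminator="\r\n")
    writer.writerow(names)
    for row in rows:
        writer.writerow([row[n] for n in names])


def dataset_to_csv_text(dataset: TraitDataset) -> str:
    """Render the dataset's CSV as a string (used for determinism checks)."""
    buf = io.StringIO(newline="")
    _write_rows(buf, dataset.schema.field_names(), dataset.rows)
    return buf.getvalue()


def write_metadata(metadata: DatasetMetadata, sink) -> None:
    Path(sink).write_text(metadata.to_json(), encoding="utf-8")


def read_metadata(source) -> DatasetMetadata:
    return DatasetMetadata.from_json(Path(source).read_text(encoding="utf-8"))
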