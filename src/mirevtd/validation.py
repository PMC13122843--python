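"""The MIReVTD rule engine.

Evaluates a :class:`~mirevtd.io_tabular.TraitDataset` against the minimum
information checklist and produces a flagged report, analogous to the upload
checks of a trait database.  Rules whose violation destroys machine
reusability are ERRORs; stylistic or heuristic rules are WARNINGs.  A dataset
is *compliant* iff it has zero ERRORs.

Each rule carries an ``anchor`` — a one-line restatement of the piece of the
standard it enforces — so a report is self-documenting.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from ._errors import UnknownRuleError
from .io_tabular import (
    TraitDataset,
    is_missing,
    parse_iso_date,
    parse_numeric,
    scan_text_issues,
)

ERROR = "ERROR"
WARNING = "WARNING"

_PROPORTION_UNIT_RE = re.compile(r"percent|%|proportion", re.IGNORECASE)

#: Fields policed by a dedicated rule; the generic required-field rule skips
#: them so each violation maps to exactly one ERROR rule.
_OWNED_FIELDS_PREFIXES = (
    "trait_unit",
    "pathogen_",
    "location_",
    "sample_size",
    "variability_",
    "numerator",
    "denominator",
)


@dataclass(frozen=True)
class ValidationIssue:
    rule_id: str
    severity: str
    message: str
    anchor: str
    field: str | None = None
    row_index: int | None = None


@dataclass
class ValidationReport:
    dataset_label: str
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def n_errors(self) -> int:
        return sum(1 for i in self.issues if i.severity == ERROR)

    @property
    def n_warnings(self) -> int:
        return sum(1 for i in self.issues if i.severity == WARNING)

    @property
    def compliant(self) -> bool:
        return self.n_errors == 0

    def error_rule_ids(self) -> set[str]:
        return {i.rule_id for i in self.issues if i.severity == ERROR}

    def rule_ids(self) -> set[str]:
        return {i.rule_id for i in self.issues}


# ---------------------------------------------------------------------------
# rule implementations
# ---------------------------------------------------------------------------

def _active_fields(ds: TraitDataset):
    """Schema fields that are required outright or triggered by a tag."""
    tags = ds.metadata.condition_tags
    for f in ds.schema.fields:
        if f.requirement == "required":
            yield f
        elif f.requirement == "conditional" and f.condition_tag in tags:
            yield f


def _rule_required_field_missing(ds):
    anchor = ("MIReVTD: every minimum descriptor (organism, trait description, "
              "axes of variation) must be reported for each measurement")
    out = []
    for f in _active_fields(ds):
        if any(f.name.startswith(p) for p in _OWNED_FIELDS_PREFIXES):
            continue
        for i, row in enumerate(ds.rows):
            if is_missing(row[f.name]):
                out.append(ValidationIssue(
                    "REQUIRED_FIELD_MISSING", ERROR,
                    f"required field {f.name!r} is empty", anchor,
                    field=f.name, row_index=i))
    return out


def _rule_units_missing(ds):
    anchor = "MIReVTD: report the units of measurement used for every trait value"
    if not ds.schema.has_field("trait_unit"):
        cols = {"trait_unit": [""] * len(ds.rows)}
    else:
        cols = {"trait_unit": ds.column("trait_unit")}
    out = []
    for i, row in enumerate(ds.rows):
        if not is_missing(row["trait_value"]) and is_missing(cols["trait_unit"][i]):
            out.append(ValidationIssue(
                "UNITS_MISSING", ERROR,
                "trait_value present without trait_unit", anchor,
                field="trait_unit", row_index=i))
    return out


def _rule_units_not_separated(ds):
    anchor = ("MIReVTD: keep numerical data machine readable by separating "
              "values from their units into different fields")
    out = []
    for i, row in enumerate(ds.rows):
        cell = row["trait_value"]
        if not is_missing(cell) and parse_numeric(cell) is None:
            out.append(ValidationIssue(
                "UNITS_NOT_SEPARATED", ERROR,
                f"trait_value cell {cell!r} is not a bare number", anchor,
                field="trait_value", row_index=i))
    return out


def _rule_value_not_numeric(ds):
    anchor = "MIReVTD: axis-of-variation levels must be recorded as numbers"
    out = []
    for f in ds.schema.axis_value_fields():
        for i, row in enumerate(ds.rows):
            cell = row[f.name]
            if not is_missing(cell) and parse_numeric(cell) is None:
                out.append(ValidationIssue(
                    "VALUE_NOT_NUMERIC", ERROR,
                    f"axis cell {cell!r} is not numeric", anchor,
                    field=f.name, row_index=i))
    return out


_DATE_ANCHOR = "MIReVTD: use numeric dates in ISO 8601 format (YYYY-MM-DD)"


def _date_fields(ds):
    return [f for f in ds.schema.fields if f.value_kind == "date"]


def _rule_date_not_iso(ds):
    out = []
    for f in _date_fields(ds):
        for i, row in enumerate(ds.rows):
            cell = row[f.name]
            if is_missing(cell):
                continue
            res = parse_iso_date(cell)
            if not res.ok and res.reason == "non_iso_parseable":
                out.append(ValidationIssue(
                    "DATE_NOT_ISO", WARNING,
                    f"date {cell!r} is recognizable but not ISO 8601", _DATE_ANCHOR,
                    field=f.name, row_index=i))
    return out


def _rule_date_unparseable(ds):
    out = []
    for f in _date_fields(ds):
        for i, row in enumerate(ds.rows):
            cell = row[f.name]
            if is_missing(cell):
                continue
            res = parse_iso_date(cell)
            if not res.ok and res.reason == "unparseable":
                out.append(ValidationIssue(
                    "DATE_UNPARSEABLE", ERROR,
                    f"date {cell!r} cannot be interpreted", _DATE_ANCHOR,
                    field=f.name, row_index=i))
    return out


def _rule_text_scan(ds, code, severity, anchor):
    out = []
    for f in ds.schema.fields:
        if f.value_kind in ("numeric", "integer"):
            continue
        for i, row in enumerate(ds.rows):
            cell = row[f.name]
            if is_missing(cell):
                continue
            for issue in scan_text_issues(cell):
                if issue.code == code:
                    out.append(ValidationIssue(
                        code, severity,
                        f"{issue.code.lower().replace('_', ' ')}: {issue.detail!r} "
                        f"in {cell!r}", anchor,
                        field=f.name, row_index=i))
    return out


def _rule_non_ascii(ds):
    return _rule_text_scan(
        ds, "NON_ASCII", WARNING,
        "MIReVTD: avoid diacritics and other special characters (encoding hazards)")


def _rule_abbreviation(ds):
    return _rule_text_scan(
        ds, "ABBREVIATION_SUSPECT", WARNING,
        "MIReVTD: do not use abbreviations in data fields; they introduce uncertainty")


def _rule_proportion_denominator(ds):
    anchor = ("MIReVTD: for percentages or proportions, record the numerator "
              "(successes) and the denominator (total observations)")
    if not ds.schema.has_field("trait_unit"):
        return []
    have_num = ds.schema.has_field("numerator")
    have_den = ds.schema.has_field("denominator")
    out = []
    for i, row in enumerate(ds.rows):
        unit = row.get("trait_unit", "")
        if is_missing(unit) or not _PROPORTION_UNIT_RE.search(unit):
            continue
        num_ok = have_num and not is_missing(row["numerator"])
        den_ok = have_den and not is_missing(row["denominator"])
        if not (num_ok and den_ok):
            out.append(ValidationIssue(
                "PROPORTION_DENOMINATOR_MISSING", ERROR,
                f"proportion-like unit {unit!r} without numerator/denominator",
                anchor, field="trait_unit", row_index=i))
    return out


def _rule_duplicate_identifier(ds):
    anchor = ("MIReVTD: a unique identifier links repeat measures on the same "
              "individual; identical identifier and axis levels suggest an "
              "accidental duplicate")
    if not ds.schema.has_field("unique_identifier"):
        return []
    axis_names = [f.name for f in ds.schema.axis_value_fields()]
    seen: dict[tuple, int] = {}
    out = []
    for i, row in enumerate(ds.rows):
        ident = row["unique_identifier"]
        if is_missing(ident):
            continue
        key = (ident, tuple(row[a] for a in axis_names))
        if key in seen:
            out.append(ValidationIssue(
                "DUPLICATE_IDENTIFIER", WARNING,
                f"identifier {ident!r} repeated with identical axis levels "
                f"(first at row {seen[key]})", anchor,
                field="unique_identifier", row_index=i))
        else:
            seen[key] = i
    return out


_LOCATION_ANCHOR = ("MIReVTD: for field studies report the collection location, "
                    "preferably latitude and longitude")


def _rule_latlong_out_of_range(ds):
    bounds = {"latitude": (-90.0, 90.0), "longitude": (-180.0, 180.0)}
    out = []
    for f in ds.schema.fields:
        if f.value_kind not in bounds:
            continue
        lo, hi = bounds[f.value_kind]
        for i, row in enumerate(ds.rows):
            cell = row[f.name]
            if is_missing(cell):
                continue
            v = parse_numeric(cell)
            if v is None or not (lo <= v <= hi):
                out.append(ValidationIssue(
                    "LATLONG_OUT_OF_RANGE", ERROR,
                    f"{f.value_kind} {cell!r} outside [{lo}, {hi}]",
                    _LOCATION_ANCHOR, field=f.name, row_index=i))
    return out


def _rule_location_missing(ds):
    if "field_study" not in ds.metadata.condition_tags:
        return []
    lat = [f for f in ds.schema.fields if f.value_kind == "latitude"]
    lon = [f for f in ds.schema.fields if f.value_kind == "longitude"]
    out = []
    for i, row in enumerate(ds.rows):
        has_lat = any(not is_missing(row[f.name]) for f in lat)
        has_lon = any(not is_missing(row[f.name]) for f in lon)
        if not (has_lat and has_lon):
            out.append(ValidationIssue(
                "LOCATION_MISSING", WARNING,
                "field study without latitude/longitude", _LOCATION_ANCHOR,
                row_index=i))
    return out


_META_ANCHOR = ("MIReVTD: metadata must include a full citation of the data "
                "source and the submitter's name and contact")


def _rule_citation_missing(ds):
    if ds.metadata.citation.strip():
        return []
    return [ValidationIssue("CITATION_MISSING", ERROR,
                            "metadata citation is empty", _META_ANCHOR)]


def _rule_submitter_missing(ds):
    if ds.metadata.submitter_name.strip() and ds.metadata.submitter_contact.strip():
        return []
    return [ValidationIssue("SUBMITTER_MISSING", ERROR,
                            "submitter name or contact is empty", _META_ANCHOR)]


def _rule_embargo_malformed(ds):
    anchor = ("MIReVTD: report the date any embargo lifts as an ISO 8601 "
              "calendar date")
    e = ds.metadata.embargo_date
    if e is None or not str(e).strip():
        return []
    if parse_iso_date(str(e)).ok:
        return []
    return [ValidationIssue("EMBARGO_MALFORMED", ERROR,
                            f"embargo date {e!r} is not ISO 8601", anchor)]


_AGG_ANCHOR = ("MIReVTD: when only summaries are reported, include metrics of "
               "variability (e.g. standard error) and sample sizes")


def _rule_aggregation_incomplete(ds):
    if "aggregated_data" not in ds.metadata.condition_tags:
        return []
    needed = ("sample_size", "variability_metric", "variability_value")
    out = []
    for i, row in enumerate(ds.rows):
        if is_missing(row["trait_value"]):
            continue
        missing = [n for n in needed
                   if not ds.schema.has_field(n) or is_missing(row[n])]
        if missing:
            out.append(ValidationIssue(
                "AGGREGATION_INCOMPLETE", ERROR,
                f"aggregated row lacks {', '.join(missing)}", _AGG_ANCHOR,
                row_index=i))
    return out


def _rule_aggregated_discouraged(ds):
    if "aggregated_data" not in ds.metadata.condition_tags:
        return []
    return [ValidationIssue(
        "AGGREGATED_DISCOURAGED", WARNING,
        "dataset is aggregated; the less processed the data, the more reusable",
        "MIReVTD: provide per-organism data when possible — aggregation "
        "irreversibly loses information")]


def _rule_pathogen_missing(ds):
    if "transmission_study" not in ds.metadata.condition_tags:
        return []
    anchor = ("MIReVTD: transmission studies must report the species or strain "
              "of pathogen")
    has_col = ds.schema.has_field("pathogen_taxonomy")
    out = []
    for i, row in enumerate(ds.rows):
        if not has_col or is_missing(row["pathogen_taxonomy"]):
            out.append(ValidationIssue(
                "PATHOGEN_MISSING", ERROR,
                "transmission study without pathogen taxonomy", anchor,
                field="pathogen_taxonomy", row_index=i))
    return out


#: rule_id -> (severity, implementation). Severities are fixed per rule.
RULE_REGISTRY = {
    "REQUIRED_FIELD_MISSING": (ERROR, _rule_required_field_missing),
    "UNITS_MISSING": (ERROR, _rule_units_missing),
    "UNITS_NOT_SEPARATED": (ERROR, _rule_units_not_separated),
    "VALUE_NOT_NUMERIC": (ERROR, _rule_value_not_numeric),
    "DATE_NOT_ISO": (WARNING, _rule_date_not_iso),
    "DATE_UNPARSEABLE": (ERROR, _rule_date_unparseable),
    "NON_ASCII": (WARNING, _rule_non_ascii),
    "ABBREVIATION_SUSPECT": (WARNING, _rule_abbreviation),
    "PROPORTION_DENOMINATOR_MISSING": (ERROR, _rule_proportion_denominator),
    "DUPLICATE_IDENTIFIER": (WARNING, _rule_duplicate_identifier),
    "LATLONG_OUT_OF_RANGE": (ERROR, _rule_latlong_out_of_range),
    "LOCATION_MISSING": (WARNING, _rule_location_missing),
    "CITATION_MISSING": (ERROR, _rule_citation_missing),
    "SUBMITTER_MISSING": (ERROR, _rule_submitter_missing),
    "EMBARGO_MALFORMED": (ERROR, _rule_embargo_malformed),
    "AGGREGATION_INCOMPLETE": (ERROR, _rule_aggregation_incomplete),
    "AGGREGATED_DISCOURAGED": (WARNING, _rule_aggregated_discouraged),
    "PATHOGEN_MISSING": (ERROR, _rule_pathogen_missing),
}

ERROR_RULES = tuple(r for r, (s, _) in RULE_REGISTRY.items() if s == ERROR)
WARNING_RULES = tuple(r for r, (s, _) in RULE_REGISTRY.items() if s == WARNING)


def _canonical_order(issues: list[ValidationIssue]) -> list[ValidationIssue]:
    # row-major (dataset-level issues first), then rule_id, then field
    return sorted(
        issues,
        key=lambda i: (
            -1 if i.row_index is None else i.row_index,
            i.rule_id,
            i.field or "",
        ),
    )


def check_rule(rule_id: str, dataset: TraitDataset) -> list[ValidationIssue]:
    """Evaluate a single registered rule against the dataset."""
    if rule_id not in RULE_REGISTRY:
        raise UnknownRuleError(rule_id, sorted(RULE_REGISTRY))
    _, impl = RULE_REGISTRY[rule_id]
    return _canonical_order(impl(dataset))


def validate(dataset: TraitDataset) -> ValidationReport:
    """Run every registered rule and return the full report.

    The report's issue list equals the concatenation of :func:`check_rule`
    over all rules, in a deterministic canonical order.
    """
    issues: list[ValidationIssue] = []
    for rule_id in RULE_REGISTRY:
        _, impl = RULE_REGISTRY[rule_id]
        issues.extend(impl(dataset))
    return ValidationReport(dataset_label=dataset.label,
                            issues=_canonical_order(issues))


def render_report(report: ValidationReport, format: str = "text") -> str:
    """Render a report as human-readable text or a stable JSON document."""
    if format == "json":
        doc = {
            "report_version": 1,
            "dataset_label": report.dataset_label,
            "compliant": report.compliant,
            "n_errors": report.n_errors,
            "n_warnings": report.n_warnings,
            "issues": [
                {
                    "rule_id": i.rule_id,
                    "severity": i.severity,
                    "field": i.field,
                    "row_index": i.row_index,
                    "message": i.message,
                    "anchor": i.anchor,
                }
                for i in report.issues
            ],
        }
        return json.dumps(doc, indent=2)
    if format != "text":
        raise ValueError(f"unknown report format {format!r} (use 'text' or 'json')")
    lines = [
        f"Validation report for {report.dataset_label}",
        f"  compliant: {'yes' if report.compliant else 'no'} "
        f"({report.n_errors} errors, {report.n_warnings} warnings)",
    ]
    for severity in (ERROR, WARNING):
        group = [i for i in report.issues if i.severity == severity]
        if not group:
            continue
        lines.append(f"{severity}S:")
        for i in group:
            where = []
            if i.row_index is not None:
                where.append(f"row {i.row_index}")
            if i.field:
                where.append(f"field {i.field}")
            loc = f" ({', '.join(where)})" if where else ""
            lines.append(f"  [{i.rule_id}]{loc} {i.message}")
            lines.append(f"      anchor: {i.anchor}")
    return "\n".join(lines) + "\n"
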