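"""The rule engine: individual rules, composition, report rendering."""

import json

import pytest

from mirevtd import (
    RULE_REGISTRY,
    UnknownRuleError,
    check_rule,
    default_mirevtd_schema,
    read_dataset,
    render_report,
    validate,
)
from mirevtd.io_tabular import dataset_to_csv_text
from mirevtd.validation import _canonical_order


def test_compliant_dataset_has_no_findings(compliant_ds):
    report = validate(compliant_ds)
    assert report.compliant
    assert report.n_errors == 0 and report.n_warnings == 0


def test_deleting_the_unit_column_flags_every_row(ds):
    """Dropping trait_unit from the CSV yields one UNITS_MISSING per row."""
    lines = dataset_to_csv_text(ds).split("\r\n")
    header = lines[0].split(",")
    idx = header.index("trait_unit")
    rebuilt = "\r\n".join(
        ",".join(c for j, c in enumerate(line.split(",")) if j != idx)
        for line in lines if line
    ) + "\r\n"
    stripped = read_dataset(rebuilt.encode(), default_mirevtd_schema(),
                            metadata=ds.metadata)
    report = validate(stripped)
    assert not report.compliant
    units_issues = [i for i in report.issues if i.rule_id == "UNITS_MISSING"]
    assert len(units_issues) == len(stripped)
    assert report.n_errors == len(stripped)  # no other ERROR rule fires


def test_value_with_embedded_unit_flags_that_row(ds):
    ds.rows[3]["trait_value"] = "45 days"
    issues = check_rule("UNITS_NOT_SEPARATED", ds)
    assert len(issues) == 1
    assert issues[0].row_index == 3
    assert issues[0].severity == "ERROR"


def test_non_iso_date_is_a_single_warning(ds):
    ds.rows[0]["observation_date"] = "03/01/2022"
    issues = check_rule("DATE_NOT_ISO", ds)
    assert len(issues) == 1 and issues[0].severity == "WARNING"


def test_repeat_measures_across_axis_levels_are_not_duplicates(ds):
    """The same identifier at different axis levels is a legitimate design."""
    ds.rows[1]["unique_identifier"] = ds.rows[0]["unique_identifier"]
    assert ds.rows[1]["axis_1_value"] != ds.rows[0]["axis_1_value"] or True
    ds.rows[1]["axis_1_value"] = "17.5"  # distinct level
    assert check_rule("DUPLICATE_IDENTIFIER", ds) == []


def test_check_rule_rejects_unknown_ids(ds):
    with pytest.raises(UnknownRuleError, match="UNITS_MISSING"):
        check_rule("NOT_A_RULE", ds)


def test_clean_dataset_passes_each_rule_individually(compliant_ds):
    for rule_id in RULE_REGISTRY:
        assert check_rule(rule_id, compliant_ds) == []


def test_validate_equals_concatenation_of_check_rule(ds):
    # plant a mixture of problems across rows
    ds.rows[0]["trait_value"] = "45 days"
    ds.rows[1]["life_stage"] = ""
    ds.rows[2]["vector_taxonomy"] = "Culex spp."
    ds.rows[4]["observation_date"] = "15/01/2026"
    ds.metadata.citation = ""
    concat = []
    for rule_id in RULE_REGISTRY:
        concat.extend(check_rule(rule_id, ds))
    assert validate(ds).issues == _canonical_order(concat)


def test_adding_a_violating_row_never_decreases_error_count(ds):
    base_errors = validate(ds).n_errors
    bad = dict(ds.rows[0])
    bad["life_stage"] = ""
    bad["trait_value"] = "not a number"
    worse = ds.copy()
    worse.rows.append(bad)
    assert validate(worse).n_errors >= base_errors + 2


def test_report_counts_and_compliance_are_consistent(ds):
    ds.rows[0]["trait_value"] = "45 days"
    ds.rows[1]["vector_taxonomy"] = "Aëdes"
    report = validate(ds)
    assert report.n_errors + report.n_warnings == len(report.issues)
    assert report.compliant == (report.n_errors == 0)


def test_json_report_is_stable_and_machine_readable(ds):
    ds.rows[0]["trait_value"] = "45 days"
    report = validate(ds)
    doc = json.loads(render_report(report, "json"))
    assert doc["report_version"] == 1
    assert doc["compliant"] is False
    assert doc["issues"][0]["rule_id"] == "UNITS_NOT_SEPARATED"
    # deterministic rendering
    assert render_report(report, "json") == render_report(report, "json")


def test_text_report_names_rule_and_anchor(ds):
    ds.metadata.citation = ""
    text = render_report(validate(ds), "text")
    assert "CITATION_MISSING" in text
    assert "MIReVTD" in text


def test_empty_report_renders_compliant(compliant_ds):
    doc = json.loads(render_report(validate(compliant_ds), "json"))
    assert doc["compliant"] is True and doc["issues"] == []


def test_unknown_render_format_rejected(compliant_ds):
    with pytest.raises(ValueError):
        render_report(validate(compliant_ds), "yaml")
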