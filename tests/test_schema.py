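"""The canonical schema and its extension operations."""

import pytest

from mirevtd import (
    FieldSpec,
    SchemaError,
    default_mirevtd_schema,
    extend_with_axis,
    extend_with_interactor,
    schema_from_json,
    schema_to_json,
)
from mirevtd.schema import check_schema


def test_default_schema_satisfies_its_own_invariants():
    schema = default_mirevtd_schema()
    check_schema(schema)  # raises on violation
    assert schema.n_axes == 1
    assert schema.n_interactors == 1


def test_default_schema_carries_the_minimum_field_set():
    names = set(default_mirevtd_schema().field_names())
    assert {
        "vector_taxonomy", "unique_identifier", "life_stage", "sex",
        "trait_name", "trait_value", "trait_unit",
        "axis_1_name", "axis_1_value", "axis_1_unit",
        "pathogen_taxonomy", "numerator", "denominator",
        "sample_size", "variability_metric",
        "location_latitude", "location_longitude",
    } <= names


def test_default_schema_field_examples():
    schema = default_mirevtd_schema()
    assert "Aedes aegypti" in schema.get("vector_taxonomy").example_values
    units = schema.get("trait_unit").example_values
    assert "days" in units and "eggs laid" in units


def test_every_descriptor_category_has_a_required_field():
    schema = default_mirevtd_schema()
    for descriptor in ("organism", "trait", "axis"):
        assert any(
            f.descriptor == descriptor and f.requirement == "required"
            for f in schema.fields
        )


def test_conditional_fields_name_their_trigger():
    for f in default_mirevtd_schema().fields:
        if f.requirement == "conditional":
            assert f.condition_tag


@pytest.mark.parametrize("axis_name,unit", [
    ("temperature gradient", "Degrees celsius"),
    ("initial resource concentration", "mg per larva"),
])
def test_extend_with_axis_adds_a_value_unit_pair(axis_name, unit):
    base = default_mirevtd_schema()
    extended = extend_with_axis(base, axis_name, unit)
    assert extended.n_axes == 2
    assert extended.has_field("axis_2_value") and extended.has_field("axis_2_unit")
    assert axis_name in extended.axis_labels()
    check_schema(extended)
    # purity: the input schema is unchanged
    assert base.n_axes == 1 and not base.has_field("axis_2_value")


def test_extend_with_axis_rejects_duplicate_axis_name():
    base = default_mirevtd_schema()
    extended = extend_with_axis(base, "relative humidity", "percent")
    with pytest.raises(SchemaError):
        extend_with_axis(extended, "relative humidity", "percent")


def test_extend_with_interactor_numbers_pathogen_blocks():
    base = default_mirevtd_schema()
    once = extend_with_interactor(base)
    assert once.n_interactors == 2
    assert "Plasmodium falciparum (N54 strain)" in once.get("pathogen_taxonomy").example_values
    twice = extend_with_interactor(once)
    assert twice.n_interactors == 3
    assert twice.has_field("pathogen_taxonomy_2")
    assert twice.has_field("pathogen_taxonomy_3")
    check_schema(twice)
    assert base.n_interactors == 1  # purity


def test_schema_json_round_trip():
    schema = extend_with_axis(default_mirevtd_schema(), "photoperiod", "hours light")
    again = schema_from_json(schema_to_json(schema))
    assert again == schema


@pytest.mark.parametrize("kwargs", [
    dict(name="bad name!", descriptor="trait", requirement="required", value_kind="text"),
    dict(name="x", descriptor="nope", requirement="required", value_kind="text"),
    dict(name="x", descriptor="trait", requirement="conditional", value_kind="text"),
    dict(name="temp.", descriptor="trait", requirement="required", value_kind="text"),
])
def test_field_spec_rejects_invalid_definitions(kwargs):
    with pytest.raises(SchemaError):
        FieldSpec(**kwargs)
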