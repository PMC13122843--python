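"""Machine-readable encoding of the MIReVTD minimum-information descriptors.

The MIReVTD standard asks that every reported vector trait measurement carry
three groups of descriptors — the organism (taxonomy, life stage, sex, an
identifier for individually measured data), the trait description (name,
numeric value, units in a separate field), and at least one axis of variation
(the experimental gradient, with its own units).  The standard deliberately
does not fix field names; this module fixes one canonical snake_case naming
as the toolkit's concrete data standard, plus an alias map so other headers
(e.g. VecTraits-style CamelCase) can be bound to canonical fields at read
time.

Requirement levels follow the standard's must/should language:

* ``required`` — must be present and non-empty in every row;
* ``conditional`` — required only when the dataset's metadata carries the
  named condition tag (``transmission_study``, ``field_study``,
  ``aggregated_data``, ``proportion_trait``);
* ``recommended`` — flagged never, or at WARNING level only.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

from ._errors import SchemaError

DESCRIPTORS = ("organism", "trait", "axis", "metadata", "other")
REQUIREMENTS = ("required", "conditional", "recommended")
VALUE_KINDS = (
    "text",
    "numeric",
    "integer",
    "date",
    "latitude",
    "longitude",
    "identifier",
    "unit",
)

#: Condition tags understood by the conditional requirement machinery.
CONDITION_TAGS = (
    "transmission_study",
    "field_study",
    "aggregated_data",
    "proportion_trait",
)

#: Text cells and field names are capped at this many characters.
MAX_TEXT_LENGTH = 255

_NAME_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*$")


@dataclass(frozen=True)
class FieldSpec:
    """Specification of a single column in the canonical data standard."""

    name: str
    descriptor: str
    requirement: str
    value_kind: str
    condition_tag: str | None = None
    example_values: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name or not _NAME_RE.match(self.name):
            raise SchemaError(
                f"field name {self.name!r} must be non-empty ASCII without "
                "punctuation or abbreviation periods"
            )
        if len(self.name) > MAX_TEXT_LENGTH:
            raise SchemaError(f"field name {self.name!r} exceeds {MAX_TEXT_LENGTH} chars")
        if self.descriptor not in DESCRIPTORS:
            raise SchemaError(f"unknown descriptor {self.descriptor!r}")
        if self.requirement not in REQUIREMENTS:
            raise SchemaError(f"unknown requirement {self.requirement!r}")
        if self.value_kind not in VALUE_KINDS:
            raise SchemaError(f"unknown value_kind {self.value_kind!r}")
        if self.requirement == "conditional" and not self.condition_tag:
            raise SchemaError(
                f"field {self.name!r} is conditional but names no condition_tag"
            )


@dataclass(frozen=True)
class DatasetSchema:
    """An ordered collection of :class:`FieldSpec` forming one data standard."""

    fields: tuple[FieldSpec, ...]
    n_axes: int = 1
    n_interactors: int = 1
    version_label: str = "mirevtd-1"

    def __post_init__(self) -> None:
        check_schema(self)

    # -- lookups ---------------------------------------------------------
    def field_names(self) -> list[str]:
        return [f.name for f in self.fields]

    def get(self, name: str) -> FieldSpec:
        for f in self.fields:
            if f.name == name:
                return f
        raise KeyError(name)

    def has_field(self, name: str) -> bool:
        return any(f.name == name for f in self.fields)

    def axis_value_fields(self) -> list[FieldSpec]:
        return [
            f
            for f in self.fields
            if f.descriptor == "axis" and f.name.endswith("_value")
        ]

    def axis_labels(self) -> list[str]:
        """Declared axis-of-variation labels (first example of each name field)."""
        labels = []
        for f in self.fields:
            if f.descriptor == "axis" and f.name.endswith("_name") and f.example_values:
                labels.append(f.example_values[0])
        return labels


def check_schema(schema: DatasetSchema) -> None:
    """Raise :class:`SchemaError` if the schema breaks a structural invariant."""
    names = [f.name for f in schema.fields]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise SchemaError(f"duplicate field names: {dupes}")
    if schema.n_axes < 1 or schema.n_interactors < 1:
        raise SchemaError("n_axes and n_interactors must be >= 1")
    if not any(f.descriptor == "organism" and f.requirement == "required" for f in schema.fields):
        raise SchemaError("schema lacks a required organism descriptor field")
    numeric_traits = [
        f for f in schema.fields if f.descriptor == "trait" and f.name == "trait_value"
    ]
    if len(numeric_traits) != 1 or numeric_traits[0].value_kind != "numeric":
        raise SchemaError("schema must contain exactly one numeric trait_value field")
    if not any(f.value_kind == "unit" for f in schema.fields):
        raise SchemaError("schema lacks a unit field")
    axis_fields = [f for f in schema.fields if f.descriptor == "axis"]
    if not axis_fields:
        raise SchemaError("schema lacks an axis-of-variation field")
    # axis fields come in (value, unit) pairs
    stems = {f.name.rsplit("_", 1)[0] for f in axis_fields}
    for stem in stems:
        have = {f.name.rsplit("_", 1)[1] for f in axis_fields if f.name.startswith(stem + "_")}
        if not {"value", "unit"} <= have:
            raise SchemaError(f"axis block {stem!r} lacks a (value, unit) pair")


def _axis_block(index: int, label: str, unit: str, label_examples: tuple[str, ...] = ()) -> list[FieldSpec]:
    stem = f"axis_{index}"
    return [
        FieldSpec(f"{stem}_name", "axis", "required", "text",
                  example_values=(label, *label_examples)),
        FieldSpec(f"{stem}_value", "axis", "required", "numeric"),
        FieldSpec(f"{stem}_unit", "axis", "required", "unit", example_values=(unit,)),
    ]


def default_mirevtd_schema() -> DatasetSchema:
    """The canonical minimum-information schema for vector trait data.

    One row is one trait measurement on one organism or replicate.  Field
    examples are drawn from the standard's printed illustrations so that
    generated fixtures double as documentation.
    """
    fields = [
        FieldSpec("vector_taxonomy", "organism", "required", "text",
                  example_values=("Aedes aegypti",
                                  "Culex quinquefasciatus Sebring colony",
                                  "Delphacodes kuscheli")),
        FieldSpec("unique_identifier", "organism", "recommended", "identifier",
                  example_values=("Mosquito1", "tick 45")),
        FieldSpec("pathogen_taxonomy", "organism", "conditional", "text",
                  condition_tag="transmission_study",
                  example_values=("Plasmodium falciparum (N54 strain)",
                                  "West Nile virus",
                                  "Dengue virus DENV-4 (strain H241)")),
        FieldSpec("pathogen_strain", "organism", "recommended", "text",
                  example_values=("N54", "Strain CDC")),
        FieldSpec("life_stage", "organism", "required", "text",
                  example_values=("L1 larvae", "nymphs",
                                  "3-4 day old post eclosion adults")),
        FieldSpec("sex", "organism", "required", "text",
                  example_values=("males", "unknown", "mixed")),
        FieldSpec("trait_name", "trait", "required", "text",
                  example_values=("mortality", "lifespan", "fecundity",
                                  "development time, hatch to adult")),
        FieldSpec("trait_value", "trait", "required", "numeric",
                  example_values=("45", "170.25")),
        FieldSpec("trait_unit", "trait", "required", "unit",
                  example_values=("days", "eggs laid", "percent mortality", "LT50")),
        FieldSpec("numerator", "trait", "conditional", "integer",
                  condition_tag="proportion_trait"),
        FieldSpec("denominator", "trait", "conditional", "integer",
                  condition_tag="proportion_trait"),
        FieldSpec("sample_size", "trait", "conditional", "integer",
                  condition_tag="aggregated_data"),
        FieldSpec("variability_metric", "trait", "conditional", "text",
                  condition_tag="aggregated_data",
                  example_values=("standard error of the mean",)),
        FieldSpec("variability_value", "trait", "conditional", "numeric",
                  condition_tag="aggregated_data"),
        FieldSpec("variability_description", "trait", "recommended", "text"),
        FieldSpec("observation_date", "other", "recommended", "date",
                  example_values=("2022-03-01",)),
        FieldSpec("location_latitude", "other", "conditional", "latitude",
                  condition_tag="field_study"),
        FieldSpec("location_longitude", "other", "conditional", "longitude",
                  condition_tag="field_study"),
        *_axis_block(1, "temperature", "Degrees celsius",
                     label_examples=("relative humidity", "photoperiod")),
    ]
    return DatasetSchema(fields=tuple(fields), n_axes=1, n_interactors=1)


def extend_with_axis(schema: DatasetSchema, axis_name: str, axis_unit: str) -> DatasetSchema:
    """Return a new schema with an additional axis-of-variation column block.

    The standard recommends separating different axes of variation into
    different columns; this adds an ``axis_<k>_name/_value/_unit`` trio whose
    declared label is ``axis_name``.  The input schema is unmodified.
    """
    if axis_name in schema.axis_labels():
        raise SchemaError(f"axis {axis_name!r} already present in schema")
    k = schema.n_axes + 1
    new_fields = schema.fields + tuple(_axis_block(k, axis_name, axis_unit))
    return replace(schema, fields=new_fields, n_axes=k)


def extend_with_interactor(schema: DatasetSchema) -> DatasetSchema:
    """Return a new schema with an additional interactor (pathogen) block.

    Transmission studies must report the species/strain of the pathogen; each
    further interacting organism gets a suffix-numbered pair of conditional
    taxonomy/strain fields.
    """
    k = schema.n_interactors + 1
    new_fields = schema.fields + (
        FieldSpec(f"pathogen_taxonomy_{k}", "organism", "conditional", "text",
                  condition_tag="transmission_study",
                  example_values=("Plasmodium falciparum (N54 strain)",)),
        FieldSpec(f"pathogen_strain_{k}", "organism", "recommended", "text"),
    )
    return replace(schema, fields=new_fields, n_interactors=k)


#: Example alias map binding VecTraits-style headers to canonical fields.
VECTRAITS_ALIASES: dict[str, str] = {
    "Interactor1Genus": "vector_taxonomy",
    "Interactor1Species": "vector_taxonomy",
    "Interactor1ID": "unique_identifier",
    "Interactor1Stage": "life_stage",
    "Interactor1Sex": "sex",
    "Interactor2Species": "pathogen_taxonomy",
    "OriginalTraitName": "trait_name",
    "OriginalTraitValue": "trait_value",
    "OriginalTraitUnit": "trait_unit",
    "DaysAlive": "trait_value",
    "AmbientTemp": "axis_1_value",
    "AmbientTempUnit": "axis_1_unit",
    "Latitude": "location_latitude",
    "Longitude": "location_longitude",
}


# -- JSON serialization ---------------------------------------------------

def schema_to_json(schema: DatasetSchema) -> str:
    """Serialize a schema to a JSON document third parties can extend."""
    doc = {
        "version_label": schema.version_label,
        "n_axes": schema.n_axes,
        "n_interactors": schema.n_interactors,
        "fields": [
            {
                "name": f.name,
                "descriptor": f.descriptor,
                "requirement": f.requirement,
                "value_kind": f.value_kind,
                "condition_tag": f.condition_tag,
                "example_values": list(f.example_values),
            }
            for f in schema.fields
        ],
    }
    return json.dumps(doc, indent=2, sort_keys=False)


def schema_from_json(text: str) -> DatasetSchema:
    """Parse a schema from its JSON document form (inverse of schema_to_json)."""
    doc = json.loads(text)
    try:
        fields = tuple(
            FieldSpec(
                name=f["name"],
                descriptor=f["descriptor"],
                requirement=f["requirement"],
                value_kind=f["value_kind"],
                condition_tag=f.get("condition_tag"),
                example_values=tuple(f.get("example_values", ())),
            )
            for f in doc["fields"]
        )
        return DatasetSchema(
            fields=fields,
            n_axes=int(doc["n_axes"]),
            n_interactors=int(doc["n_interactors"]),
            version_label=str(doc["version_label"]),
        )
    except KeyError as exc:  # pragma: no cover - defensive
        raise SchemaError(f"schema document missing key {exc}") from exc
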