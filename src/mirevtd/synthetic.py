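"""Synthetic trait datasets with known ground truth.

Two jobs: (i) generate minimum-information-compliant datasets emulating an
*Aedes aegypti* juvenile development-rate (or lifespan) experiment across a
temperature gradient — optionally with a second resource-level axis, the
classic two-stressor layout — with trait values drawn from a known Briere
thermal performance curve plus Gaussian noise, so parameter-recovery
experiments have an exact truth to recover; (ii) plant minimal, targeted
rule violations into a compliant dataset so every validation rule has a
failing fixture.

The generator's defaults are the toolkit's reference study conditions:
truth q = 7e-5, T_min = 10 degC, T_max = 38 degC (peak rate ~0.12/day near
31.6 degC, realistic for mosquito juvenile development), noise SD 0.01 on
the rate scale, 8 temperatures spanning 16-36 degC, 20 individuals each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import FixtureError, UnknownRuleError
from .io_tabular import DatasetMetadata, TraitDataset
from .schema import default_mirevtd_schema, extend_with_axis
from .tpc import TPCModel, briere
from .validation import RULE_REGISTRY

#: Floor keeping simulated rates positive (trait units).
RATE_FLOOR = 1e-6

DEFAULT_TRUTH = TPCModel(q=7e-5, t_min=10.0, t_max=38.0, sigma=0.01)
DEFAULT_TEMPERATURES = (16.0, 19.0, 22.0, 25.0, 28.0, 31.0, 34.0, 36.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study design for one simulated dataset."""

    trait: str = "development_rate"  # or "juvenile_lifespan"
    tpc_truth: TPCModel = DEFAULT_TRUTH
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    n_per_temp: int = 20
    resource_levels: tuple[float, ...] | None = None
    seed: int = 0
    organism_label: str = "Aedes aegypti"

    def __post_init__(self) -> None:
        if self.trait not in ("development_rate", "juvenile_lifespan"):
            raise ValueError(f"unknown trait {self.trait!r}")
        if self.n_per_temp < 1:
            raise ValueError("n_per_temp must be >= 1")
        if not self.temperatures:
            raise ValueError("temperatures must be non-empty")
        tr = self.tpc_truth
        if not any(tr.t_min < t < tr.t_max for t in self.temperatures):
            raise ValueError(
                "no temperature lies inside (t_min, t_max); all traits would be zero")


def _fmt(x: float) -> str:
    return format(x, ".10g")


def _default_metadata() -> DatasetMetadata:
    return DatasetMetadata(
        citation=("Example Lab (2026). Synthetic juvenile trait measurements of "
                  "Aedes aegypti across a temperature gradient. Generated by the "
                  "mirevtd toolkit."),
        doi=None,
        submitter_name="mirevtd toolkit",
        submitter_contact="maintainer@example.org",
    )


def simulate_individual_dataset(config: SimulationConfig) -> TraitDataset:
    """Generate one compliant individual-level dataset.

    One row per individual: a unique identifier (mosquito_0001, ...), the
    organism descriptors, the trait value drawn as
    max(briere(T, truth) + N(0, sigma), floor) for development rate — or the
    rounded reciprocal in whole days for juvenile lifespan — and the axis
    block(s).  The same config and seed reproduce the dataset exactly, and
    the output carries zero ERROR-level findings under validation.
    """
    rng = np.random.default_rng(config.seed)
    schema = default_mirevtd_schema()
    two_axes = config.resource_levels is not None
    if two_axes:
        schema = extend_with_axis(schema, "initial resource concentration",
                                  "mg per larva")
    resources = tuple(config.resource_levels) if two_axes else (None,)

    if config.trait == "development_rate":
        trait_name, trait_unit = "juvenile development rate", "per day"
    else:
        trait_name, trait_unit = "juvenile lifespan", "days"

    names = schema.field_names()
    rows: list[dict[str, str]] = []
    ident = 0
    truth = config.tpc_truth
    for temp in config.temperatures:
        mu = briere(temp, truth.q, truth.t_min, truth.t_max)
        for res in resources:
            noise = rng.normal(0.0, truth.sigma, size=config.n_per_temp)
            rates = np.maximum(mu + noise, RATE_FLOOR)
            for r in rates:
                ident += 1
                row = {n: "" for n in names}
                row["vector_taxonomy"] = config.organism_label
                row["unique_identifier"] = f"mosquito_{ident:04d}"
                row["life_stage"] = "L1 larvae to adult eclosion"
                row["sex"] = "mixed"
                row["trait_name"] = trait_name
                if config.trait == "development_rate":
                    row["trait_value"] = _fmt(float(r))
                else:
                    row["trait_value"] = str(int(max(1, round(1.0 / float(r)))))
                row["trait_unit"] = trait_unit
                row["observation_date"] = "2026-01-15"
                row["axis_1_name"] = "temperature"
                row["axis_1_value"] = _fmt(float(temp))
                row["axis_1_unit"] = "Degrees celsius"
                if two_axes:
                    row["axis_2_name"] = "initial resource concentration"
                    row["axis_2_value"] = _fmt(float(res))
                    row["axis_2_unit"] = "mg per larva"
                rows.append(row)

    return TraitDataset(
        metadata=_default_metadata(),
        schema=schema,
        rows=rows,
        label=f"synthetic {config.trait} (seed {config.seed})",
    )


# ---------------------------------------------------------------------------
# rule-violation fixtures
# ---------------------------------------------------------------------------

def _need_rows(ds: TraitDataset, n: int = 1) -> None:
    if len(ds) < n:
        raise FixtureError(f"need at least {n} rows to plant this violation")


def _set_cell(ds, row, fieldname, value):
    _need_rows(ds, row + 1)
    if not ds.schema.has_field(fieldname):
        raise FixtureError(f"dataset has no field {fieldname!r}")
    ds.rows[row][fieldname] = value


def _p_required(ds):
    _set_cell(ds, 0, "life_stage", "")


def _p_units_missing(ds):
    _set_cell(ds, 0, "trait_unit", "")


def _p_units_not_separated(ds):
    _set_cell(ds, 0, "trait_value", "45 days")


def _p_value_not_numeric(ds):
    _set_cell(ds, 0, "axis_1_value", "warm")


def _p_date_not_iso(ds):
    _set_cell(ds, 0, "observation_date", "15/01/2026")


def _p_date_unparseable(ds):
    _set_cell(ds, 0, "observation_date", "sometime last winter")


def _p_non_ascii(ds):
    _set_cell(ds, 0, "vector_taxonomy", "Aëdes aegypti")


def _p_abbreviation(ds):
    _set_cell(ds, 0, "vector_taxonomy", "Culex spp.")


def _p_proportion(ds):
    _set_cell(ds, 0, "trait_unit", "percent mortality")


def _p_duplicate_identifier(ds):
    _need_rows(ds, 2)
    ds.rows[1]["unique_identifier"] = ds.rows[0]["unique_identifier"]
    for f in ds.schema.axis_value_fields():
        ds.rows[1][f.name] = ds.rows[0][f.name]


def _p_latlong(ds):
    _set_cell(ds, 0, "location_latitude", "123.456")
    _set_cell(ds, 0, "location_longitude", "-58.4")


def _p_location_missing(ds):
    ds.metadata.condition_tags.add("field_study")


def _p_citation(ds):
    ds.metadata.citation = ""


def _p_submitter(ds):
    ds.metadata.submitter_name = ""


def _p_embargo(ds):
    ds.metadata.embargo_date = "01/03/2026"


def _p_aggregation_incomplete(ds):
    ds.metadata.condition_tags.add("aggregated_data")


def _p_aggregated_discouraged(ds):
    ds.metadata.condition_tags.add("aggregated_data")
    for row in ds.rows:
        row["sample_size"] = "20"
        row["variability_metric"] = "standard error of the mean"
        row["variability_value"] = "0.002"


def _p_pathogen(ds):
    ds.metadata.condition_tags.add("transmission_study")


_PERTURBATIONS = {
    "REQUIRED_FIELD_MISSING": _p_required,
    "UNITS_MISSING": _p_units_missing,
    "UNITS_NOT_SEPARATED": _p_units_not_separated,
    "VALUE_NOT_NUMERIC": _p_value_not_numeric,
    "DATE_NOT_ISO": _p_date_not_iso,
    "DATE_UNPARSEABLE": _p_date_unparseable,
    "NON_ASCII": _p_non_ascii,
    "ABBREVIATION_SUSPECT": _p_abbreviation,
    "PROPORTION_DENOMINATOR_MISSING": _p_proportion,
    "DUPLICATE_IDENTIFIER": _p_duplicate_identifier,
    "LATLONG_OUT_OF_RANGE": _p_latlong,
    "LOCATION_MISSING": _p_location_missing,
    "CITATION_MISSING": _p_citation,
    "SUBMITTER_MISSING": _p_submitter,
    "EMBARGO_MALFORMED": _p_embargo,
    "AGGREGATION_INCOMPLETE": _p_aggregation_incomplete,
    "AGGREGATED_DISCOURAGED": _p_aggregated_discouraged,
    "PATHOGEN_MISSING": _p_pathogen,
}

assert set(_PERTURBATIONS) == set(RULE_REGISTRY)


def perturb_for_fixture(dataset: TraitDataset, violation: str) -> TraitDataset:
    """Return a minimally modified copy that triggers exactly one rule.

    The target rule fires; no *other* ERROR-level rule does (warnings may
    legitimately co-occur, e.g. AGGREGATED_DISCOURAGED alongside
    AGGREGATION_INCOMPLETE).  The modification is recorded in the returned
    dataset's label.
    """
    if violation not in _PERTURBATIONS:
        raise UnknownRuleError(violation, sorted(_PERTURBATIONS))
    out = dataset.copy()
    _PERTURBATIONS[violation](out)
    out.label = f"{dataset.label} [planted {violation}]"
    return out


def fixture_catalog(config: SimulationConfig | None = None) -> dict[str, TraitDataset]:
    """One failing fixture per registered rule, from one compliant base."""
    base = simulate_individual_dataset(config or SimulationConfig(n_per_temp=2))
    return {rule: perturb_for_fixture(base, rule) for rule in _PERTURBATIONS}
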