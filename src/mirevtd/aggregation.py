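"""Moving between individual-level and aggregated trait data.

The standard advocates reporting the least-aggregated form available; when
only summaries exist, it requires sample sizes and a variability metric
alongside every mean.  This module computes those summaries from individual
rows (per-level mean, standard error of the mean, n), rebuilds a compliant
aggregated dataset from them, and classifies a dataset's aggregation status.
Aggregation is one-way: nothing here attempts to reconstruct individuals
from summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io_tabular import TraitDataset, is_missing, parse_numeric

#: Canonical variability metric label written by to_aggregated_dataset.
SE_LABEL = "standard error of the mean"


@dataclass(frozen=True)
class AggregatedGroup:
    """Per-axis-level summary of a trait: mean, SE of the mean, and n.

    ``se`` is the sample standard deviation (n-1 denominator) divided by
    sqrt(n); it is None (undefined, never silently zero) when n == 1.
    """

    axis_value: float
    mean: float
    se: float | None
    n: int
    axis_unit: str = ""
    trait_unit: str = ""

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group sample size must be >= 1")
        if self.n == 1 and self.se is not None:
            raise ValueError("se is undefined for n == 1")
        if self.se is not None and self.se < 0:
            raise ValueError("se must be non-negative")


def _mean_se(values: list[float]) -> tuple[float, float | None]:
    n = len(values)
    mean = math.fsum(values) / n
    if n == 1:
        return mean, None
    var = math.fsum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var) / math.sqrt(n)


def aggregate_by_axis(dataset: TraitDataset, axis_field: str) -> list[AggregatedGroup]:
    """Group trait values by the distinct levels of one numeric axis.

    Returns one :class:`AggregatedGroup` per distinct axis value, ordered by
    ascending axis value.  Axis levels compare numerically with exact
    equality after parsing.  Raises ``ValueError`` on an empty dataset or on
    any non-numeric trait/axis cell (citing the row).
    """
    if len(dataset) == 0:
        raise ValueError("cannot aggregate an empty dataset")
    if not dataset.schema.has_field(axis_field):
        raise KeyError(axis_field)
    groups: dict[float, list[float]] = {}
    for i, row in enumerate(dataset.rows):
        t = parse_numeric(row[axis_field])
        if t is None:
            raise ValueError(f"row {i}: axis cell {row[axis_field]!r} is not numeric")
        y = parse_numeric(row["trait_value"])
        if y is None:
            raise ValueError(f"row {i}: trait cell {row['trait_value']!r} is not numeric")
        groups.setdefault(t, []).append(y)

    axis_unit = _paired_unit(dataset, axis_field)
    trait_unit = dataset.rows[0].get("trait_unit", "") if dataset.schema.has_field("trait_unit") else ""
    out = []
    for t in sorted(groups):
        mean, se = _mean_se(groups[t])
        out.append(AggregatedGroup(axis_value=t, mean=mean, se=se, n=len(groups[t]),
                                   axis_unit=axis_unit, trait_unit=trait_unit))
    return out


def _paired_unit(dataset: TraitDataset, axis_field: str) -> str:
    unit_field = axis_field.rsplit("_", 1)[0] + "_unit"
    if dataset.schema.has_field(unit_field) and dataset.rows:
        return dataset.rows[0][unit_field]
    return ""


def _fmt(x: float) -> str:
    return format(x, ".12g")


def to_aggregated_dataset(groups: list[AggregatedGroup], template: TraitDataset,
                          axis_field: str = "axis_1_value") -> TraitDataset:
    """Build the aggregated representation the standard tolerates.

    One row per group: trait_value is the group mean, with sample_size,
    variability_metric (SE of the mean) and variability_value populated.  The
    metadata gains the ``aggregated_data`` condition tag, so validation will
    emit the AGGREGATED_DISCOURAGED warning — and an AGGREGATION_INCOMPLETE
    error if any group's SE is undefined (n == 1).
    """
    if not groups:
        raise ValueError("no groups to aggregate")
    if len(template) == 0:
        raise ValueError("template dataset has no rows to copy constant fields from")
    base = template.rows[0]
    names = template.schema.field_names()
    rows = []
    for g in groups:
        row = {n: "" for n in names}
        for keep in ("vector_taxonomy", "life_stage", "sex", "trait_name",
                     "trait_unit", "observation_date"):
            if keep in row:
                row[keep] = base.get(keep, "")
        # axis block of the grouping axis; other axes are left blank
        stem = axis_field.rsplit("_", 1)[0]
        if f"{stem}_name" in row:
            row[f"{stem}_name"] = base.get(f"{stem}_name", "")
        row[axis_field] = _fmt(g.axis_value)
        if f"{stem}_unit" in row:
            row[f"{stem}_unit"] = g.axis_unit or base.get(f"{stem}_unit", "")
        row["trait_value"] = _fmt(g.mean)
        if "sample_size" in row:
            row["sample_size"] = str(g.n)
        if "variability_metric" in row:
            row["variability_metric"] = SE_LABEL
        if "variability_value" in row:
            row["variability_value"] = _fmt(g.se) if g.se is not None else ""
        rows.append(row)

    out = template.copy()
    out.rows = rows
    out.metadata.condition_tags = set(out.metadata.condition_tags) | {"aggregated_data"}
    out.label = f"{template.label} (aggregated)"
    return out


def disaggregation_status(dataset: TraitDataset) -> str:
    """Classify a dataset as 'individual', 'aggregated', or 'ambiguous'.

    Aggregated: the aggregated_data tag is set, or sample_size/variability
    cells are populated.  Individual: unique identifiers are present and no
    variability fields are populated.  Otherwise ambiguous.
    """
    if "aggregated_data" in dataset.metadata.condition_tags:
        return "aggregated"
    for name in ("sample_size", "variability_value", "variability_metric"):
        if dataset.schema.has_field(name) and any(
            not is_missing(c) for c in dataset.column(name)
        ):
            return "aggregated"
    if dataset.schema.has_field("unique_identifier") and any(
        not is_missing(c) for c in dataset.column("unique_identifier")
    ):
        return "individual"
    return "ambiguous"
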