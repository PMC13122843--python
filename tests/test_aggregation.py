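"""Mean/SE/n summaries and aggregation-status classification."""

import math

import numpy as np
import pytest

from mirevtd import (
    AggregatedGroup,
    DatasetMetadata,
    TraitDataset,
    aggregate_by_axis,
    default_mirevtd_schema,
    disaggregation_status,
    read_dataset,
    to_aggregated_dataset,
    validate,
)
from mirevtd.io_tabular import dataset_to_csv_text

SCHEMA = default_mirevtd_schema()


def _dataset(pairs, unit="per day"):
    """Build a minimal dataset from (axis, value) pairs."""
    names = SCHEMA.field_names()
    rows = []
    for i, (t, y) in enumerate(pairs):
        row = {n: "" for n in names}
        row.update(unique_identifier=f"m{i}", vector_taxonomy="Aedes aegypti",
                   life_stage="larvae", sex="mixed", trait_name="rate",
                   trait_value=str(y), trait_unit=unit, axis_1_name="temperature",
                   axis_1_value=str(t), axis_1_unit="Degrees celsius")
        rows.append(row)
    return TraitDataset(metadata=DatasetMetadata(citation="c", submitter_name="s",
                                                 submitter_contact="s@x"),
                        schema=SCHEMA, rows=rows)


def test_hand_computed_mean_and_se():
    groups = aggregate_by_axis(_dataset([(20, 1), (20, 2), (20, 3)]), "axis_1_value")
    (g,) = groups
    assert g.mean == pytest.approx(2.0)
    assert g.se == pytest.approx(1.0 / math.sqrt(3), abs=1e-12)  # sd=1, n=3
    assert g.n == 3


def test_single_observation_group_has_undefined_se():
    (g,) = aggregate_by_axis(_dataset([(25, 5)]), "axis_1_value")
    assert g.mean == 5 and g.n == 1 and g.se is None


def test_zero_variance_group_has_zero_se():
    (g,) = aggregate_by_axis(_dataset([(20, 4), (20, 4)]), "axis_1_value")
    assert g.mean == 4 and g.se == 0.0 and g.n == 2


def test_groups_ordered_ascending_and_conserve_n(compliant_ds):
    groups = aggregate_by_axis(compliant_ds, "axis_1_value")
    axis = [g.axis_value for g in groups]
    assert axis == sorted(axis)
    assert sum(g.n for g in groups) == len(compliant_ds)


def test_agrees_with_two_pass_brute_force_to_1e12():
    rng = np.random.default_rng(42)
    pairs = [(float(rng.integers(15, 20)), float(rng.normal(10, 3)))
             for _ in range(200)]
    groups = aggregate_by_axis(_dataset(pairs), "axis_1_value")
    for g in groups:
        vals = np.array([y for t, y in pairs if t == g.axis_value])
        assert g.n == vals.size
        assert g.mean == pytest.approx(vals.mean(), rel=1e-12)
        expect_se = vals.std(ddof=1) / math.sqrt(vals.size)
        assert g.se == pytest.approx(expect_se, rel=1e-12)


def test_non_numeric_cells_rejected_citing_row():
    bad = _dataset([(20, 1), (21, 2)])
    bad.rows[1]["trait_value"] = "two"
    with pytest.raises(ValueError, match="row 1"):
        aggregate_by_axis(bad, "axis_1_value")


def test_empty_dataset_rejected():
    with pytest.raises(ValueError):
        aggregate_by_axis(_dataset([]), "axis_1_value")


def test_aggregated_dataset_shape_and_validation(compliant_ds):
    groups = aggregate_by_axis(compliant_ds, "axis_1_value")
    agg = to_aggregated_dataset(groups, compliant_ds)
    assert len(agg) == len(groups)
    assert all(r["sample_size"] for r in agg.rows)
    report = validate(agg)
    assert report.n_errors == 0
    assert "AGGREGATED_DISCOURAGED" in report.rule_ids()


def test_undefined_se_makes_aggregation_incomplete(compliant_ds):
    groups = [AggregatedGroup(axis_value=20.0, mean=1.0, se=None, n=1)]
    agg = to_aggregated_dataset(groups, compliant_ds)
    report = validate(agg)
    assert "AGGREGATION_INCOMPLETE" in report.error_rule_ids()


def test_status_classification(compliant_ds):
    assert disaggregation_status(compliant_ds) == "individual"
    groups = aggregate_by_axis(compliant_ds, "axis_1_value")
    agg = to_aggregated_dataset(groups, compliant_ds)
    assert disaggregation_status(agg) == "aggregated"
    bare = compliant_ds.copy()
    for row in bare.rows:
        row["unique_identifier"] = ""
    assert disaggregation_status(bare) == "ambiguous"


def test_status_stable_under_round_trip(compliant_ds):
    groups = aggregate_by_axis(compliant_ds, "axis_1_value")
    agg = to_aggregated_dataset(groups, compliant_ds)
    for d in (compliant_ds, agg):
        again = read_dataset(dataset_to_csv_text(d).encode(), SCHEMA,
                             metadata=d.metadata)
        assert disaggregation_status(again) == disaggregation_status(d)


def test_group_invariants_enforced():
    with pytest.raises(ValueError):
        AggregatedGroup(axis_value=1.0, mean=0.0, se=0.0, n=1)  # se defined at n=1
    with pytest.raises(ValueError):
        AggregatedGroup(axis_value=1.0, mean=0.0, se=-0.1, n=2)
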