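"""Build the canonical schema, simulate a compliant dataset, break it, and
see the rule engine flag exactly what went wrong."""

from mirevtd import (
    SimulationConfig,
    default_mirevtd_schema,
    extend_with_axis,
    perturb_for_fixture,
    render_report,
    simulate_individual_dataset,
    validate,
)

schema = default_mirevtd_schema()
print(f"canonical schema: {len(schema.fields)} fields, {schema.n_axes} axis block")

two_stressor = extend_with_axis(schema, "initial resource concentration", "mg per larva")
print(f"with a second stressor axis: {two_stressor.n_axes} axis blocks\n")

ds = simulate_individual_dataset(SimulationConfig(n_per_temp=2, seed=1))
print(f"simulated {len(ds)} individual rows; "
      f"errors in clean data: {validate(ds).n_errors}")

broken = perturb_for_fixture(ds, "UNITS_NOT_SEPARATED")
print("\nafter planting a '45 days' cell (value and unit mixed in one field):")
print(render_report(validate(broken), "text"))
# The single ERROR above is the point of the units-separation rule: a cell
# like "45 days" is unusable by any downstream numeric analysis until a
# human re-splits it.
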