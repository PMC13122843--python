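"""Exception hierarchy for the toolkit."""


class MirevtdError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(MirevtdError):
    """A schema or field specification violates its invariants."""


class EncodingError(MirevtdError):
    """Input bytes do not decode as UTF-8."""


class StructuralError(MirevtdError):
    """A CSV file is structurally malformed (ragged row, duplicate header)."""


class UnknownRuleError(MirevtdError):
    """A rule id is not in the registered rule set."""

    def __init__(self, rule_id: str, registered: list[str]):
        self.rule_id = rule_id
        self.registered = list(registered)
        super().__init__(
            f"unknown rule id {rule_id!r}; registered rules: {', '.join(registered)}"
        )


class FixtureError(MirevtdError):
    """A requested rule violation cannot be planted on this dataset."""


class InferenceError(MirevtdError):
    """Invalid input to the thermal-performance-curve fitting machinery."""
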