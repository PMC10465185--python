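"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A simulation or pipeline configuration field is invalid."""


class SchemaError(ValueError):
    """A tabular input does not match the expected column schema."""


class UndefinedResultError(ArithmeticError):
    """A statistic is undefined for the given (otherwise valid) input,
    e.g. the proliferation index of a population with no divided cells."""
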