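"""Exception types shared across the package."""


class SchemaError(ValueError):
    """A phenotype field or coefficient does not match the declared schema."""


class ContractError(ValueError):
    """A component violated a declared interface contract (e.g. encoder dim)."""


class PlacementError(RuntimeError):
    """Synthetic nuclei could not be placed at the requested density."""


class ConfigError(ValueError):
    """Invalid, unknown or ill-typed configuration key."""


class DependencyError(RuntimeError):
    """A pipeline stage ran before its upstream artifacts existed."""


class EvaluationError(ValueError):
    """Metric computation impossible on the given inputs (e.g. one class)."""
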