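"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid or inconsistent run configuration / design-space definition."""


class DomainError(ValueError):
    """Numeric input outside the mathematical domain of an operation."""


class BoundsError(ValueError):
    """A condition violates the design-space bounds (or a per-solvent override)."""


class DegenerateDescriptorError(ValueError):
    """A descriptor column has zero variance and cannot be standardized."""


class SolventLookupError(KeyError):
    """A solvent label is not part of the design space / library."""
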