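"""Exception hierarchy shared across the package."""


class FluxDesignError(Exception):
    """Base class for all package-specific errors."""


class NetworkValidationError(FluxDesignError):
    """A network document violates the schema or an invariant.

    The message names the offending record (metabolite or reaction).
    """


class InfeasibleError(FluxDesignError):
    """The stoichiometric equality system admits no solution."""


class ConstraintError(FluxDesignError):
    """A flux state or design violates bounds or inequality constraints."""

    def __init__(self, message, violations=None):
        super().__init__(message)
        self.violations = list(violations or [])


class ConfigurationError(FluxDesignError):
    """Invalid configuration: missing atom maps, bad coefficients, unknown names."""


class DegeneracyError(FluxDesignError):
    """A labeling system or measurement group is degenerate (dead pool, zero mass)."""
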