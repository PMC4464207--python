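"""Exception hierarchy shared across the package."""


class LipotrapError(Exception):
    """Base class for all package-specific errors."""


class DomainError(LipotrapError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ValidationError(LipotrapError, ValueError):
    """A domain object violates one of its invariants."""


class DegenerateSampleError(LipotrapError, ValueError):
    """A sample carries no information for the requested fit."""


class FitError(LipotrapError, RuntimeError):
    """A numerical fit failed to converge or a component fit failed."""
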