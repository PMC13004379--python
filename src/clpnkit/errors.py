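"""Exception hierarchy shared across the package."""


class ClpnError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ClpnError, ValueError):
    """Input data violates a domain invariant (score ranges, Likert bounds, ...)."""


class SchemaError(ClpnError, ValueError):
    """A required column or field is missing from tabular input."""


class IntegrityError(ClpnError, ValueError):
    """A shipped fixture failed its integrity checks."""


class ConfigurationError(ClpnError, ValueError):
    """An estimation or simulation configuration is inconsistent."""


class DegenerateFitError(ClpnError, ValueError):
    """A model fit is degenerate (constant outcome, zero margin, ...)."""


class AlignmentError(ClpnError, ValueError):
    """Two objects that must share node sets or shapes do not."""
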