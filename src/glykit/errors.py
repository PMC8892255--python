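"""Exception hierarchy.

Everything raised on purpose by glykit derives from :class:`GlykitError`,
so callers can catch one base class at CLI or pipeline boundaries.
"""


class GlykitError(Exception):
    """Base class for all glykit errors."""


class ValidationError(GlykitError, ValueError):
    """Input data violates a documented invariant (bad record, bad labels...)."""


class ConfigError(GlykitError, ValueError):
    """Bad configuration: unknown unit, unknown index, malformed config file."""


class IntegrationError(GlykitError, RuntimeError):
    """ODE integration failed; carries solver diagnostics when available."""

    def __init__(self, message, params=None, diagnostics=None):
        super().__init__(message)
        self.params = params
        self.diagnostics = diagnostics


class FittingError(GlykitError, RuntimeError):
    """Parameter estimation failed to produce any converged run."""


class DegenerateDensitiesError(GlykitError, ValueError):
    """Two fitted densities are identical; no crossing point exists."""


class UndefinedNumberError(GlykitError, ValueError):
    """A dimensionless number is undefined for these inputs (e.g. D == 0)."""


class SeparationError(FittingError):
    """Logistic fit is non-identifiable because classes are perfectly separated."""
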