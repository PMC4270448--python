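"""Exception hierarchy.

Everything raised on bad scientific input derives from
:class:`JunctionFitError`, so callers (and the CLI) can catch one type.
"""


class JunctionFitError(Exception):
    """Base class for all package errors."""


class DomainError(JunctionFitError, ValueError):
    """A parameter or argument is outside its physical domain."""


class UnitError(JunctionFitError, ValueError):
    """Missing or inconsistent time/concentration unit tags."""


class TableFormatError(JunctionFitError, ValueError):
    """An intensity table violates its dialect (names the offending row/column)."""


class NoSignalError(JunctionFitError, ValueError):
    """Data carry no usable signal for the requested fit (e.g. flat trace)."""


class UnidentifiableError(JunctionFitError, ValueError):
    """The requested parameter cannot be identified from the data
    (e.g. an all-bound or all-free titration)."""


class FitConvergenceError(JunctionFitError, RuntimeError):
    """The optimizer failed to converge after all restarts; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class IntegrationError(JunctionFitError, RuntimeError):
    """Numerical ODE integration did not converge."""
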