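"""Exception hierarchy.

Argument/precondition violations raise plain :class:`ValueError` so they are
distinguishable from data-content problems (:class:`DataError`), fitting
failures (:class:`FitError`) and ODE-integrator failures
(:class:`IntegrationError`).
"""


class BufferscanError(Exception):
    """Base class for all package-specific errors."""


class DataError(BufferscanError):
    """Input tables are malformed or internally inconsistent."""


class DegenerateDataError(DataError):
    """A computation is undefined because the data carry no dispersion."""


class FitError(BufferscanError):
    """A nonlinear fit failed to converge; carries diagnostics when available."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NoTransitionError(FitError):
    """A melt curve shows no resolvable unfolding transition."""


class IntegrationError(BufferscanError):
    """The ODE integrator failed to meet its accuracy target."""
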