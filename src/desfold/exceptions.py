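"""Exception hierarchy shared across analysis stages."""


class DesfoldError(Exception):
    """Base class for all package errors."""


class InvalidInputError(DesfoldError, ValueError):
    """An argument violates a precondition (wrong sign, range, units...)."""


class NonUniformGridError(InvalidInputError):
    """A derivative operation received a non-uniform wavelength grid.

    Resample the spectrum onto a uniform grid before differentiating;
    this package refuses to interpolate silently.
    """


class FeatureNotFoundError(DesfoldError):
    """A required spectral feature (local extremum, peak) was absent."""


class UndefinedResultError(DesfoldError):
    """The requested quantity is undefined for this input (e.g. CSM of a
    zero spectrum, relative activity against a zero-rate reference)."""


class InsufficientDataError(DesfoldError):
    """Too few points inside the analysis window."""


class FitFailureError(DesfoldError):
    """A nonlinear fit failed to converge; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateBaselineError(DesfoldError):
    """Native and denatured baselines cross inside the data span, making
    the fraction denatured ill-defined."""
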