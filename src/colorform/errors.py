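"""Exception hierarchy shared across the package."""


class ColorformError(Exception):
    """Base class for all package-specific errors."""


class InputDomainError(ColorformError, ValueError):
    """An argument lies outside the documented domain of an operation."""


class DegenerateInputError(ColorformError, ValueError):
    """Input is formally valid but degenerate (empty mask, zero variance, ...)."""


class DataIntegrityError(ColorformError, ValueError):
    """Data violates a structural contract (asymmetry, non-finite values, ...)."""


class GamutError(ColorformError, ValueError):
    """A requested color cannot be represented in the target gamut.

    Attributes
    ----------
    max_admissible : float or None
        Largest parameter value (e.g. saturation) that would have been
        representable, when that quantity is well defined.
    """

    def __init__(self, message: str, max_admissible: float | None = None):
        super().__init__(message)
        self.max_admissible = max_admissible


class AdapterEnvironmentError(ColorformError, RuntimeError):
    """A model adapter's backing framework or weights are unavailable."""
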