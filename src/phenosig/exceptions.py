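"""Exception hierarchy used across the package."""


class PhenosigError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PhenosigError, ValueError):
    """Input data violates a documented precondition (shape, monotonicity, finiteness)."""


class FormatError(PhenosigError, ValueError):
    """A file does not conform to the expected on-disk format."""


class DomainError(PhenosigError, ValueError):
    """A value is outside the mathematical domain of an operation (e.g. OD <= 0)."""


class ParameterError(PhenosigError, ValueError):
    """A configuration parameter is out of its admissible range."""


class IntegrationError(PhenosigError, RuntimeError):
    """Numerical integration of an ODE model failed or blew up."""


class SearchError(PhenosigError, RuntimeError):
    """A stochastic search could not produce any viable candidate."""
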