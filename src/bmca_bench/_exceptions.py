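"""Exception hierarchy shared across the package."""


class BmcaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BmcaError, ValueError):
    """Invalid user configuration (preset counts, empty enzyme lists, ...)."""


class ModelLookupError(BmcaError, KeyError):
    """Reference to an undeclared reaction or species."""


class DomainError(BmcaError, ValueError):
    """Input outside the mathematical domain (negative concentration, ...)."""


class SteadyStateError(BmcaError, RuntimeError):
    """No steady state could be found within the solver budget."""


class NormalizationError(BmcaError, ValueError):
    """Reference-state normalization is undefined (zero reference flux, ...)."""


class ModelParseError(BmcaError, ValueError):
    """Malformed SBML document; carries a location hint."""


class FitError(BmcaError, RuntimeError):
    """Variational or MCMC fit failed (non-finite ELBO, all chains failed)."""


class DegenerateDensityError(BmcaError, ValueError):
    """Kernel density estimate is degenerate (zero-variance draws)."""
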