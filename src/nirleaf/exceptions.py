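"""Exception hierarchy for nirleaf.

All errors raised by the package derive from :class:`NirleafError` so callers
can catch pipeline failures with a single ``except`` clause.
"""


class NirleafError(Exception):
    """Base class for all nirleaf errors."""


class FormatError(NirleafError):
    """A file does not conform to the documented CSV layout."""


class ValidationError(NirleafError):
    """Inputs are structurally valid but inconsistent with each other."""


class DomainError(NirleafError):
    """A value lies outside the mathematical domain of an operation."""


class DegenerateSpectrumError(NirleafError):
    """A spectrum cannot be normalized (e.g. constant row under SNV)."""


class ConfigurationError(NirleafError):
    """A configuration value violates its documented constraints."""


class RankError(NirleafError):
    """More latent variables requested than the data matrix supports."""


class ConvergenceError(NirleafError):
    """An iterative fit failed to converge within its iteration budget."""


class ComputationError(NirleafError):
    """A derived statistic is undefined for the fitted model."""
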