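"""Exception and warning types used across the package."""


class JointPsychError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(JointPsychError, ValueError):
    """A psychometric parameter vector violates its domain constraints."""


class DataValidationError(JointPsychError, ValueError):
    """Input block data violate the dataset invariants."""


class SamplingError(JointPsychError, RuntimeError):
    """A Monte Carlo routine cannot produce a usable result."""


class DegenerateFitWarning(UserWarning):
    """Effective sample size of an importance-resampled fit fell below the
    configured floor; the posterior approximation may be unreliable."""
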