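"""Exception hierarchy shared across the package."""


class GfrModelsError(Exception):
    """Base class for all package errors."""


class ValidationError(GfrModelsError):
    """A record or configuration violates a domain invariant."""


class FormatError(GfrModelsError):
    """A delimited-text file is malformed (e.g. a mandatory column is missing)."""


class InsufficientDataError(GfrModelsError):
    """Too few records to perform the requested operation."""


class CollinearityError(GfrModelsError):
    """The regression design matrix is rank deficient."""


class EvaluationError(GfrModelsError):
    """A model cannot be evaluated on a record (missing covariate, bad domain)."""


class TrainingError(GfrModelsError):
    """Numerical failure during network training (e.g. exploding loss)."""


class ConfigurationError(GfrModelsError):
    """An invalid simulation / training / GA configuration."""
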