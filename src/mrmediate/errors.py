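"""Exception types shared across the pipeline."""


class MRMediateError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRMediateError):
    """A config file, column map or flag is malformed or incomplete."""


class InputError(MRMediateError):
    """An input table violates a structural precondition (empty file,
    no overlapping variants, invalid LD matrix...)."""


class EstimationError(MRMediateError):
    """An estimator cannot be computed on the given harmonised set
    (degenerate instruments, rank-deficient design, collinearity)."""
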