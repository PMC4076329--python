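"""Exception hierarchy for transfinemap.

All package-specific failures derive from :class:`TransfinemapError` so callers
can catch one base class at pipeline boundaries.
"""


class TransfinemapError(Exception):
    """Base class for all transfinemap errors."""


class ParseError(TransfinemapError):
    """A file could not be parsed under the requested dialect."""


class FormatError(TransfinemapError):
    """A record violates the format contract (e.g. non-diploid call)."""


class SchemaError(TransfinemapError):
    """A tabular input is missing mandatory columns."""


class InputError(TransfinemapError):
    """Operation preconditions on the input data are not met."""


class ConfigError(TransfinemapError):
    """Invalid configuration values."""


class DegenerateError(TransfinemapError):
    """A statistic is undefined for this input (e.g. monomorphic SNP)."""


class FitError(TransfinemapError):
    """A model fit failed (e.g. complete separation in logistic regression)."""


class TransformError(TransfinemapError):
    """A phenotype transform cannot be applied (e.g. group too small)."""
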