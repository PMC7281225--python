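"""Typed exceptions raised across the package.

Every reader and analysis entry point fails loudly with one of these types;
malformed input is never silently coerced.
"""


class ImmunocytError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ImmunocytError):
    """Input violates a structural invariant (negative TPM, end < start, ...)."""


class ParseError(FormatError):
    """A cell or line could not be parsed; message names the offending line."""


class DuplicateKeyError(FormatError):
    """A key that must be unique (gene symbol, sample id, set name) repeats."""


class MissingGeneError(ImmunocytError):
    """A gene required by a score panel is absent from the expression matrix."""


class DegenerateInputError(ImmunocytError):
    """Too little data for the operation (empty group, < 2 samples, ...)."""


class AlignmentError(ImmunocytError):
    """Sample ids of two inputs do not overlap at all."""


class SingularityError(ImmunocytError):
    """Design matrix is rank-deficient (constant or duplicated covariate)."""


class NoOverlapError(ImmunocytError):
    """A gene set shares no members with the ranked gene list."""


class UndefinedDiversityError(ImmunocytError):
    """Repertoire diversity requested with zero total reads."""


class ConfigError(ImmunocytError):
    """Invalid simulation or pipeline configuration."""
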