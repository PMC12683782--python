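"""Exception hierarchy.

Exit-code mapping used by the CLI: FormatError -> 2, StateError -> 3,
UsageError -> 4.
"""


class EnsembleAgeError(Exception):
    """Base class for all package errors."""


class FormatError(EnsembleAgeError):
    """Malformed input file (bad CSV dialect, duplicate ids, bad values)."""


class RangeError(FormatError):
    """A beta value outside [0, 1]."""


class StateError(EnsembleAgeError):
    """Operation called on data in the wrong state (e.g. missing values
    still present where a fully imputed matrix is required)."""


class UsageError(EnsembleAgeError):
    """Invalid arguments or preconditions violated by the caller."""


class ImputationError(EnsembleAgeError):
    """Imputation cannot proceed (e.g. a fully missing CpG with no prior)."""
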