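"""Exception hierarchy shared across pipeline stages."""


class IrspliceError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(IrspliceError):
    """An invalid configuration field; the message names the field."""


class InputError(IrspliceError):
    """Malformed or inconsistent pipeline input."""


class UndefinedStratumError(IrspliceError):
    """A 2x2 report table with an empty exposure or comparator stratum."""


class InsufficientDataError(IrspliceError):
    """Too few complete observations for the requested statistic."""


class CollinearityError(IrspliceError):
    """Rank-deficient regression design; the message names the columns."""


class NestingError(IrspliceError):
    """Likelihood-ratio comparison of models that are not properly nested."""


class GroupingError(IrspliceError):
    """A group comparison with an empty or degenerate group."""
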