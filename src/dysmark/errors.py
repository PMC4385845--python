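"""Exception hierarchy shared by all analysis stages."""


class DysmarkError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DysmarkError, ValueError):
    """Invalid configuration value; message names the offending field."""


class InsufficientDataError(DysmarkError, ValueError):
    """Too few usable observations for the requested statistic."""


class LookupError_(DysmarkError, KeyError):
    """Unknown feature, probe, or sample identifier."""


class FormatError(DysmarkError, ValueError):
    """Malformed input file (duplicate ids, non-numeric cells, ...)."""


class DegenerateDataError(DysmarkError, ValueError):
    """Statistic undefined on this input (zero variance, zero marginal, ...)."""


class NoEventsError(DysmarkError, ValueError):
    """Survival test requested but no events occurred in either group."""


class NoWoundError(DysmarkError, ValueError):
    """Baseline wound image contains no detectable cell-free region."""
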