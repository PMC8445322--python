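"""Exception hierarchy.

Two broad families matter to callers: configuration problems (bad
parameters, bad config files) and data problems (inputs that exist but
cannot be analysed). The CLI maps them to distinct exit codes.
"""


class RetroQuantError(Exception):
    """Base class for all package errors."""


class ConfigError(RetroQuantError):
    """Invalid configuration or parameter values."""


class DataError(RetroQuantError):
    """Input data present but unusable."""


class DomainError(ConfigError):
    """Argument outside its mathematical domain (negative rate, non-finite ratio...)."""


class PlateauUndefinedError(DomainError):
    """Plateau requested for a parameter regime where no plateau exists (k_cleave == 0)."""


class InsufficientDataError(DataError):
    """Too few observations for the requested fit."""


class NormalizationError(DataError):
    """First-frame corrected intensity non-positive; curve cannot be normalized."""


class PlacementError(RetroQuantError):
    """Geometry sampler exhausted its retry budget without a valid placement."""
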