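"""Exception hierarchy for mrpath.

All analysis-level failures derive from :class:`MrPathError` so callers can
distinguish them from programming errors; configuration problems get their
own branch because the CLI maps them to a distinct exit code.
"""


class MrPathError(Exception):
    """Base class for all mrpath analysis errors."""


class ConfigurationError(MrPathError):
    """A config file, column mapping, or parameter set is invalid."""


class EmptyInputError(MrPathError):
    """An input table contained no usable rows."""


class NoOverlapError(MrPathError):
    """Exposure and outcome summary statistics share no variants."""


class InsufficientInstrumentsError(MrPathError):
    """Fewer instruments than the estimator's minimum (1 for Wald/IVW,
    2 for random-effects IVW, 3 for Egger/median/mode, 4 for PRESSO)."""


class UndefinedRatioError(MrPathError):
    """Wald ratio requested with a zero exposure effect."""


class UndefinedProportionError(MrPathError):
    """Mediation proportion requested with a zero total effect."""
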