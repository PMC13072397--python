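"""Exception hierarchy shared across modules."""


class MitocompError(Exception):
    """Base class for all package-specific errors."""


class GenBankParseError(MitocompError):
    """A GenBank record could not be parsed; the message names the locus."""


class FrameError(MitocompError):
    """A coding sequence violates reading-frame expectations."""


class FeatureNotFoundError(MitocompError, KeyError):
    """A named gene feature is absent from a mitogenome."""


class InsufficientDataError(MitocompError):
    """Too few observations for the requested statistic."""


class UndefinedStatisticError(MitocompError):
    """The statistic is mathematically undefined on this input."""


class SaturationError(MitocompError):
    """Jukes-Cantor correction undefined: observed proportion >= 3/4."""


class ConfigError(MitocompError):
    """Invalid simulation or pipeline configuration."""


class FitError(MitocompError):
    """Likelihood optimisation failed to converge."""
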