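"""Exception hierarchy for mrlink."""


class MrlinkError(Exception):
    """Base class for all mrlink errors."""


class InputError(MrlinkError):
    """Malformed or empty input data."""


class ConfigError(MrlinkError):
    """Invalid configuration (missing columns, bad thresholds, absent files)."""


class InsufficientInstrumentsError(MrlinkError):
    """Too few instruments for the requested estimator."""


class UndefinedRatioError(MrlinkError):
    """Wald ratio requested with a zero exposure effect."""


class CollinearityError(MrlinkError):
    """Rank-deficient multivariable design matrix."""


class VariantNotFoundError(MrlinkError):
    """A named variant is absent from a summary-statistics table."""


class DegenerateCorrectionError(MrlinkError):
    """Outlier correction would remove every instrument."""
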