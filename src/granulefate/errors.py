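"""Exception hierarchy shared across the pipeline stages."""


class GranuleFateError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GranuleFateError):
    """A simulation or pipeline configuration violates its invariants."""


class FormulaError(GranuleFateError, ValueError):
    """A chemical formula string could not be parsed."""


class CalibrationError(GranuleFateError):
    """A calibration curve cannot be fit or is degenerate."""


class RecoveryError(GranuleFateError):
    """Spike recovery is undefined (postspike does not exceed unspiked)."""


class ScreenError(GranuleFateError):
    """Suspect screening received an unknown compound or invalid peak."""


class RarefactionError(GranuleFateError):
    """Requested rarefaction depth exceeds the library total."""


class PairingError(GranuleFateError):
    """DNA and cDNA matrices cannot be paired sample-by-sample."""


class DataError(GranuleFateError):
    """An input table is malformed or inconsistent."""
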