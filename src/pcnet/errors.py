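"""Exception hierarchy for pcnet."""


class PCNetError(Exception):
    """Base class for all pcnet errors."""


class StructureError(PCNetError):
    """Array/parameter shapes inconsistent with the network specification."""


class ConfigurationError(PCNetError):
    """Invalid configuration value (bad hyperparameter, unknown name, ...)."""


class NumericError(PCNetError):
    """Non-finite values appeared during computation."""


class DivergenceError(PCNetError):
    """Free energy grew past the explosion threshold during inference."""
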