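"""Exception types shared across the package."""


class PdVoiceError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PdVoiceError):
    """Invalid configuration value (unknown protocol, bad probability, ...)."""


class FormatError(PdVoiceError):
    """Malformed external file (posterior CSV schema or value violations)."""


class ContractError(PdVoiceError):
    """An operation was called with input violating its contract."""


class UnsupportedRateError(ContractError):
    """Audio sampled below the 16 kHz target cannot be downsampled."""


class DegenerateCodebookError(PdVoiceError):
    """Unique ON/OFF codebooks are both empty; the protocol cannot decide."""


class UndecidableError(PdVoiceError):
    """Every protocol abstained; no patient-level call is possible."""


class LeakageError(PdVoiceError):
    """Held-out patient data leaked into a training fold."""


class TrainingDivergedError(PdVoiceError):
    """Loss became non-finite during network training."""
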