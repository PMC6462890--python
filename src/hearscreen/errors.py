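"""Exception hierarchy shared across the package."""


class HearScreenError(Exception):
    """Base class for all hearscreen errors."""


class DomainError(HearScreenError, ValueError):
    """An input outside the domain of an operation (unknown frequency,
    out-of-range scale index, missing threshold, ...)."""


class ConfigError(HearScreenError, ValueError):
    """An inconsistent protocol, engine, or staircase configuration."""


class CalibrationError(DomainError):
    """A level/frequency that the calibration profile cannot produce."""


class ClippingError(HearScreenError, ValueError):
    """Waveform samples outside [-1, 1]; raised instead of silently clipping."""


class SessionFormatError(HearScreenError, ValueError):
    """A session file that cannot be parsed or has an unsupported schema."""
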