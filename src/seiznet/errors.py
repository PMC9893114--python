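"""Exception types raised by the seiznet pipeline."""


class SeizNetError(Exception):
    """Base class for all seiznet errors."""


class ConfigurationError(SeizNetError):
    """Invalid configuration (bad parameter values, overlapping windows, unknown keys)."""


class SeriesTooShortError(SeizNetError):
    """Signal shorter than the 2*M + 1 samples the event detector needs."""


class InsufficientEventsError(SeizNetError):
    """An event train has too few events for the pair-delay rule."""


class InsufficientSamplesError(SeizNetError):
    """Too few index values for a kernel-density estimate."""
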