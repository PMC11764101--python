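"""Exception types raised across the pipeline."""


class ConfigurationError(ValueError):
    """A parameter value is inconsistent with the data or with another parameter."""


class SignalLengthError(ValueError):
    """A signal is too short for the requested operation (filter padding, DWT depth, ...)."""


class EpochingError(ValueError):
    """One or more event windows fall outside the continuous recording."""


class ChannelMismatchError(ValueError):
    """Channel count of the input does not match the fitted model."""


class DecompositionError(ValueError):
    """Wavelet decomposition cannot reach the requested depth."""
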