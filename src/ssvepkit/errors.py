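"""Exception and warning types shared across the package."""


class ConfigurationError(ValueError):
    """A parameter combination is invalid (e.g. a harmonic above Nyquist)."""


class UnsupportedRateError(ConfigurationError):
    """Sampling-rate conversion requested with a non-integer decimation factor."""


class DegenerateInputError(ValueError):
    """An input carries no usable signal (e.g. an all-zero epoch)."""


class EpochTruncationError(ValueError):
    """A requested epoch extends past the end of the recording."""


class ResolutionWarning(UserWarning):
    """A requested analysis frequency falls between DFT bins by more than half a bin."""


class ShortEpochWarning(UserWarning):
    """An epoch is short relative to the filter transients of the filter bank."""
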