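"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A user-supplied configuration (column map, thresholds, ...) cannot be resolved."""


class InputDataError(ValueError):
    """An input file or dataset is unusable (empty intersection, all rows filtered, ...)."""


class FormatError(InputDataError):
    """A binary/text input does not conform to its declared format."""


class NumericalError(RuntimeError):
    """A non-finite quantity appeared where a finite one is required."""
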