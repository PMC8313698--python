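"""Exception hierarchy shared across the pipeline stages."""


class LoyCiteError(Exception):
    """Base class for all errors raised by loycite."""


class FormatError(LoyCiteError):
    """A file on disk does not conform to its declared format."""


class InputError(LoyCiteError):
    """Well-formed input that violates a stage's preconditions."""


class ConfigurationError(LoyCiteError):
    """Invalid parameterization (thresholds, panels, simulation config)."""
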