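"""Exception hierarchy for the scmetland pipeline.

Every error raised on purpose by the package derives from
:class:`ScmetlandError`, so callers (and the CLI) can separate validation
failures (exit code 1) from compute failures (exit code 2).
"""


class ScmetlandError(Exception):
    """Base class for all scmetland errors."""


class ValidationError(ScmetlandError):
    """Input data violates a documented contract (bad field, bad margin...)."""


class FormatError(ValidationError):
    """A file on disk could not be parsed; message carries the line number."""


class ConfigError(ValidationError):
    """A configuration value is out of its admissible range."""


class StateError(ScmetlandError):
    """An operation was applied at the wrong pipeline stage."""


class InsufficientDataError(ScmetlandError):
    """Too few cells / groups / genes remain to carry out the operation."""
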