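"""Exception types shared across the package."""


class MuscleNetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MuscleNetError, ValueError):
    """An invalid parameter value; the message names the offending field."""


class ParseError(MuscleNetError, ValueError):
    """Malformed input file; the message carries the file location."""


class PipelineError(MuscleNetError, RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""
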