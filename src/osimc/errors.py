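"""Exception types shared across the pipeline."""


class OsimcError(Exception):
    """Base class for pipeline errors."""


class FormatError(OsimcError, ValueError):
    """A tabular input violates the expected dialect or schema."""


class ConfigError(OsimcError, ValueError):
    """A configuration object or file is invalid."""


class DegenerateSplitError(OsimcError, ValueError):
    """A median dichotomization is undefined (all values identical)."""


class NoEventsError(OsimcError, ValueError):
    """A survival analysis was requested on data with zero observed events."""


class PipelineError(OsimcError, RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""
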