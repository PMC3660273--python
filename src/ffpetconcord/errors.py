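"""Exception types shared across the pipeline."""


class FFPETConcordError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FFPETConcordError):
    """A configuration field is missing, malformed, or out of range."""


class GenerationError(FFPETConcordError):
    """The synthetic-data generator could not satisfy a constraint."""


class InputError(FFPETConcordError):
    """User-supplied data violates a precondition (bad sequence, duplicate id...)."""


class AnalysisError(FFPETConcordError):
    """A metric is undefined on the given data (empty blank set, zero variance...)."""
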