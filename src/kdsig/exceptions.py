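"""Exception hierarchy shared by all kdsig modules."""


class KdsigError(Exception):
    """Base class for all kdsig errors."""


class FormatError(KdsigError, ValueError):
    """An on-disk artifact violates its expected file format."""


class ValidationError(KdsigError, ValueError):
    """An in-memory object violates a domain invariant."""


class ParameterError(KdsigError, ValueError):
    """A caller-supplied parameter is outside its admissible range."""


class StratificationError(KdsigError, ValueError):
    """Sample stratification cannot produce valid groups (e.g. all scores tied)."""


class DegenerateTestError(KdsigError, ValueError):
    """A statistical test is undefined on the given data (e.g. zero log-rank variance)."""


class PipelineError(KdsigError, RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""
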