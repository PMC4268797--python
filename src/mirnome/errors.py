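"""Exception hierarchy shared by all pipeline stages."""


class MirnomeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MirnomeError):
    """A study design, signal specification, or pipeline config is invalid."""


class InputError(MirnomeError, ValueError):
    """Input data violates a documented precondition."""


class DegenerateInputError(InputError):
    """Input is formally valid but statistically degenerate (e.g. zero variance)."""
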