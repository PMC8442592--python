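"""Exception hierarchy for the lscpm pipeline."""


class LscpmError(Exception):
    """Base class for all package errors."""


class ParameterError(LscpmError, ValueError):
    """An argument or configuration field is invalid; the message names it."""


class PreconditionError(LscpmError, ValueError):
    """A documented operation precondition does not hold for these inputs."""


class DataError(LscpmError, ValueError):
    """Input data violate a contract (shape, units, finiteness, schema)."""


class DegenerateCorrelationError(DataError):
    """|r| is numerically 1, so the Fisher z transform would be infinite."""
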