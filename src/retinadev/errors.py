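"""Exception hierarchy shared across the pipeline.

Two failure families matter operationally: malformed inputs or
configuration (:class:`ValidationError`, CLI exit code 2) and inputs that
are well-formed but do not satisfy a statistical precondition, e.g. too
few groups for a trend test (:class:`PreconditionError`, CLI exit code 3).
"""


class RetinadevError(Exception):
    """Base class for all package errors."""


class ValidationError(RetinadevError):
    """Malformed input data or configuration (names the offending field)."""


class PreconditionError(RetinadevError):
    """A statistical precondition of an operation is not met."""
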