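"""Exception hierarchy.

``ValidationError`` means the *input* is unusable (bad file, empty set,
infeasible parameters) and maps to CLI exit code 2; ``ComputationError``
means a stage could not produce a result from valid-looking input (e.g. no
linear window found) and maps to exit code 3.
"""


class CocultrxError(Exception):
    """Base class for all package errors."""


class ValidationError(CocultrxError, ValueError):
    """Invalid or infeasible input."""


class ComputationError(CocultrxError, RuntimeError):
    """A computation could not be completed on otherwise valid input."""
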