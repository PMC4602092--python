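"""Exception hierarchy."""


class SpikecochError(Exception):
    """Base class for all package errors."""


class FormatError(SpikecochError, IOError):
    """A file could not be parsed in the declared format."""


class ValidationError(SpikecochError, ValueError):
    """An input violated a documented precondition or invariant."""


class DesignError(SpikecochError, ValueError):
    """A filterbank design request produced an unstable or invalid cascade."""


class SolverError(SpikecochError, RuntimeError):
    """A linear system could not be solved reliably."""
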