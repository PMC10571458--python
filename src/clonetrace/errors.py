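"""Exception hierarchy shared across the package.

Configuration problems (bad parameter values, violated invariants in a
simulation or pipeline config) and data problems (malformed inputs,
unsatisfiable reconstructions) are kept distinct so the command line
surface can map them to different exit codes.
"""


class ClonetraceError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ClonetraceError):
    """A configuration value violates a documented invariant."""


class DataError(ClonetraceError):
    """Input data are malformed or an operation's preconditions fail."""
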