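"""Exception types shared across the package.

``ValidationError`` marks malformed or contract-violating input (exit code 2
at the command line); any other exception is treated as a runtime failure
(exit code 3).
"""


class MirauditError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MirauditError, ValueError):
    """Input data violates a documented contract (bad table, bad config...)."""
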