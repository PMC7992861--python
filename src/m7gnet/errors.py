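"""Exception hierarchy.

Everything user-facing derives from :class:`M7GNetError` so callers (and the
CLI) can catch one base class; the subclasses distinguish malformed files from
records or matrices that parse but violate a domain contract.
"""


class M7GNetError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(M7GNetError, ValueError):
    """A file could not be parsed in the expected delimited dialect."""


class ValidationError(M7GNetError, ValueError):
    """A parsed record or matrix violates a domain invariant."""


class ContractError(M7GNetError, ValueError):
    """Arguments to an operation violate its preconditions."""
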