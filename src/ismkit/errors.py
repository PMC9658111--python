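"""Exception hierarchy for ismkit.

Every error raised on bad user input derives from :class:`ISMError`, so
callers (and the CLI) can catch one type. ``ContractError`` signals misuse
of the API — e.g. asking for power profiles of a matrix that has not been
transitively closed — and is a programming error, not a data error.
"""


class ISMError(Exception):
    """Base class for all ismkit errors."""


class SSIMParseError(ISMError):
    """A SSIM file could not be parsed (bad symbol, malformed layout)."""


class CompletenessError(ISMError):
    """A SSIM is missing one or more upper-triangle judgments."""


class RosterError(ISMError):
    """Factor roster is invalid (duplicate/empty ids) or mismatched."""


class ContractError(ISMError):
    """An operation was invoked outside its contract."""


class ConsistencyError(ISMError):
    """Internal consistency check failed (corrupted or non-closed input)."""
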