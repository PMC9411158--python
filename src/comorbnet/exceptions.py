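"""Exception hierarchy for comorbnet.

Everything user-facing derives from :class:`ComorbnetError` so the CLI can
map any anticipated failure to exit status 2.
"""


class ComorbnetError(Exception):
    """Base class for all comorbnet errors."""


class LoadError(ComorbnetError):
    """A required input file is missing or unreadable."""


class ParseError(ComorbnetError):
    """An input file exists but its contents are malformed."""


class ValidationError(ComorbnetError):
    """Parsed inputs violate a cross-reference or type invariant."""


class DomainError(ComorbnetError, ValueError):
    """A numeric argument lies outside the operation's domain."""
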