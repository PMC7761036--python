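"""Exception hierarchy.

Errors carry enough context (column names, row numbers, offending tokens)
to be actionable from a shell or a notebook.
"""


class GlycolinkerError(Exception):
    """Base class for all package errors."""


class FormatError(GlycolinkerError):
    """A file does not conform to the documented dialect (e.g. missing column)."""


class ValidationError(GlycolinkerError):
    """Input values violate a contract (negative area, mixed fractions, ...)."""


class SchemaError(GlycolinkerError):
    """A configuration file contains unknown tokens or malformed structure."""
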