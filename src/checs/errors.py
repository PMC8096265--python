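"""Exception hierarchy shared across the package.

All checs-specific errors derive from :class:`ChecsError` so callers (and the
CLI) can distinguish data problems from programming errors.
"""


class ChecsError(Exception):
    """Base class for all checs errors."""


class ParameterError(ChecsError, ValueError):
    """An argument value is outside its documented domain."""


class SchemaError(ChecsError, ValueError):
    """A table is structurally invalid (missing roles, samples, columns)."""


class FormatError(ChecsError, ValueError):
    """A file does not conform to its documented on-disk schema."""


class DataError(ChecsError, ValueError):
    """Values are syntactically fine but semantically impossible."""
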