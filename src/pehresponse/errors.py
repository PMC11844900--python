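"""Typed exceptions raised by the pipeline.

All inherit from :class:`PehError` so callers can catch the package's own
failures without masking programming errors. None of these subclass
``ValueError`` on purpose: they must propagate unwrapped through pydantic
model validation.
"""


class PehError(Exception):
    """Base class for all pehresponse errors."""


class SchemaError(PehError):
    """A required column or field is missing from an input table."""


class ParseError(PehError):
    """A cell could not be converted to the expected type."""


class IntegrityError(PehError):
    """Values violate a dataset invariant (duplicates, impossible pressures)."""


class DomainError(PehError):
    """An argument lies outside the mathematical domain of an operation."""
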