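"""Exception hierarchy for bpdrisk.

All package errors derive from :class:`BpdRiskError` so callers can catch
one base class at pipeline boundaries.
"""


class BpdRiskError(Exception):
    """Base class for all bpdrisk errors."""


class SchemaError(BpdRiskError):
    """A file or table is missing required columns or is unparseable."""


class ValidationError(BpdRiskError):
    """A record or parameter violates a model invariant."""


class NotFoundError(BpdRiskError):
    """A requested (analyte, food category) or preset cell does not exist."""


class InsufficientDataError(BpdRiskError):
    """Too few observations for the requested statistic."""
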