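"""Exception hierarchy.

Everything derives from :class:`TDSError` (a ``ValueError``) so callers can
catch domain failures with one handler while still treating them as value
errors in generic code.
"""


class TDSError(ValueError):
    """Base class for all tdsim domain errors."""


class ValidationError(TDSError):
    """A trial or event sequence violates the TDS data model."""


class LexiconError(TDSError):
    """An attribute label or index is not in the lexicon."""


class ShapeError(TDSError):
    """Two discretized objects are not comparable (different R or q)."""


class DegenerateDistributionError(TDSError):
    """A statistic is undefined because the sample has zero spread."""


class ParseError(TDSError):
    """An input file violates the event-log schema."""
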