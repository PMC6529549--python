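"""Exception hierarchy shared across the toolkit.

All toolkit errors derive from :class:`CultevError` so callers (and the CLI)
can distinguish domain failures from programming errors.  Unbounded/degenerate
analytical outcomes get their own types: they are legitimate answers ("no
finite break-even exists"), not input mistakes.
"""


class CultevError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(CultevError, ValueError):
    """An input violated a precondition (non-finite, out of range, malformed)."""


class UnboundedBreakEvenError(CultevError):
    """No finite break-even exists (e.g. cP = 1: expectation is always positive)."""


class EmptyProjectError(CultevError):
    """Project expectation requested for zero isolates; EV is undefined, not 0."""


class DegenerateDenominatorError(CultevError):
    """Interval estimation impossible: rounded trial count below the success count."""


class InfeasibleDesignError(CultevError):
    """A planning target cannot be met (zero yield rate, zero occurrences)."""


class UnknownTaxonError(CultevError, KeyError):
    """A taxon id was referenced that the design or catalog does not contain."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return Exception.__str__(self)


class ParseError(CultevError):
    """A TSV input could not be parsed; the message names the offending line."""
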