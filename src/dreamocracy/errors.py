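"""Exception hierarchy.

All package-specific failures derive from :class:`DreamocracyError` so callers
can catch one base class; most also derive from :class:`ValueError` because
they signal bad input rather than internal faults.
"""


class DreamocracyError(Exception):
    """Base class for all dreamocracy errors."""


class InvalidNameError(DreamocracyError, ValueError):
    """A drug name is empty (or empty after trimming)."""


class SchemaError(DreamocracyError, ValueError):
    """A tabular input is missing a required column."""


class GMTParseError(DreamocracyError, ValueError):
    """A gene-set (GMT) line is malformed; carries the line number."""


class EmptyLibraryError(DreamocracyError, ValueError):
    """An annotation table yielded zero parseable drug records."""


class EmptyListError(DreamocracyError, ValueError):
    """A study drug-list file yielded zero drugs."""


class UnusableCollectionError(DreamocracyError, ValueError):
    """Every list of a disease collection is empty after resolution."""


class DomainError(DreamocracyError, ValueError):
    """A numeric argument is outside its documented domain."""


class DegenerateTestError(DreamocracyError, ValueError):
    """A statistical test cannot be run (e.g. all paired differences zero)."""


class UndefinedResultError(DreamocracyError, ValueError):
    """A regression/summary is undefined (too few points, zero variance)."""


class ConfigError(DreamocracyError, ValueError):
    """A run or simulation configuration is invalid."""
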