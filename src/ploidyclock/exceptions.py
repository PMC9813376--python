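"""Exception hierarchy.

``PloidyclockError`` is the base for everything this package raises on
bad input; internal bugs surface as ordinary Python exceptions.
"""


class PloidyclockError(Exception):
    """Base class for all package-level errors."""


class FormatError(PloidyclockError):
    """A file could not be parsed (malformed header, bad field, ...)."""


class ValidationError(PloidyclockError):
    """Parsed data violates a documented invariant."""


class UncoveredLocusError(PloidyclockError):
    """A queried locus is not covered by any copy-number segment."""


class EmptyProfileError(PloidyclockError):
    """An operation needing segments was given an empty profile."""
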