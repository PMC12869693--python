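"""Exception hierarchy.

Exit-code mapping in the CLI: usage problems -> 1, data/integrity problems -> 2.
"""


class PantagError(Exception):
    """Base class for all pantag errors."""


class GFAFormatError(PantagError):
    """Malformed or unsupported GFA input (names the offending line)."""


class ConflictError(PantagError):
    """A tag run insertion overlaps a differently-tagged region.

    During construction this always signals an algorithmic bug: the three
    stages are designed so that overlapping insertions carry equal tags.
    """


class IntegrityError(PantagError):
    """Internal consistency violation (stage mismatch, cursor exhaustion,
    container corruption)."""
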