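"""Exception hierarchy.

Validation failures raise distinct, named exceptions so callers can react to
the specific defect (a duplicated assay id is recoverable by renaming; an
ambiguous panel whose analyte masses collide is a design flaw).
"""


class MaldiplexError(Exception):
    """Base class for all package errors."""


class InvalidSequenceError(MaldiplexError):
    """A primer/codon string contains a symbol outside A, C, G, T."""

    def __init__(self, sequence: str, position: int):
        self.sequence = sequence
        self.position = position
        super().__init__(
            f"invalid base {sequence[position]!r} at position {position} "
            f"in sequence {sequence!r}"
        )


class MassTableError(MaldiplexError):
    """A mass table violates its invariants (non-positive or colliding masses)."""


class PanelValidationError(MaldiplexError):
    """Base class for panel-definition defects."""


class DuplicateAssayError(PanelValidationError):
    """Two assays in one panel share an assay_id."""


class UnknownBaseError(PanelValidationError):
    """An assay references a base outside A, C, G, T."""


class PoolSizeError(PanelValidationError):
    """A pool is empty or exceeds the maximum plex level."""


class ComplexGroupError(PanelValidationError):
    """A complex group is inconsistent (missing member, mismatched codon)."""


class AmbiguousPanelError(MaldiplexError):
    """Two expected analyte masses lie within the match tolerance of each other."""


class SpectrumError(MaldiplexError):
    """A spectrum is structurally invalid (empty, unsorted, length mismatch)."""


class NoSignalError(MaldiplexError):
    """All analyte peaks of an assay are absent; nothing can be quantified."""
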