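"""Exception hierarchy.

Every error raised by this package derives from :class:`RsnpScanError`
so callers (and the CLI) can catch the whole family at once.
"""


class RsnpScanError(Exception):
    """Base class for all package errors."""


class UsageError(RsnpScanError):
    """An operation was called with arguments that violate its contract."""


class AlignmentError(RsnpScanError):
    """A site alignment is malformed (unequal lengths, too few sites)."""


class AlphabetError(RsnpScanError):
    """A sequence contains characters outside the {A,C,G,T} alphabet
    where strict DNA is required."""


class ParseError(RsnpScanError):
    """A text input (JASPAR record, region string, variant notation,
    model TSV) could not be parsed."""


class DegenerateModelError(RsnpScanError):
    """A scoring model would contain non-finite log-odds entries
    (zero observation count with zero pseudocount)."""


class CoordinateError(RsnpScanError):
    """A position is invalid in the requested coordinate system
    (e.g. position 0 in a TSS/ATG-relative system) or a required
    anchor is missing from the context."""


class ReferenceMismatchError(RsnpScanError):
    """The declared reference allele of a variant disagrees with the
    base actually present in the working sequence."""

    def __init__(self, position: int, expected: str, observed: str):
        self.position = position
        self.expected = expected
        self.observed = observed
        super().__init__(
            f"reference mismatch at absolute position {position}: "
            f"variant declares ref {expected!r} but sequence has {observed!r}"
        )


class InternalConsistencyError(RsnpScanError):
    """An internal invariant was violated (e.g. duplicate hit keys
    within one allele's hit list)."""


class GenerationError(RsnpScanError):
    """The synthetic-data generator could not satisfy the requested
    configuration (e.g. infeasible site packing)."""
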