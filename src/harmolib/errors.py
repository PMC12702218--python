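"""Exception hierarchy for the harmonization pipeline.

Every stage raises a subclass of :class:`HarmolibError` so the CLI can map
failures onto exit codes (config/input problems -> 2, stage failures -> 1).
"""


class HarmolibError(Exception):
    """Base class for all package errors."""


class FormatError(HarmolibError):
    """A file does not conform to the expected dialect (names the offending
    column and, where known, the 1-based line number)."""


class IntegrityError(HarmolibError):
    """Input data is self-contradictory (e.g. duplicate precursors with
    conflicting scores, or a peptide flagged both target and decoy)."""


class ConfigError(HarmolibError):
    """A configuration value violates its documented invariant."""


class OutOfRangeError(HarmolibError):
    """A precursor m/z falls outside the isolation scheme's range."""


class InsufficientAnchorsError(HarmolibError):
    """Too few shared peptides to fit a retention-time warp."""


class DegenerateInputError(HarmolibError):
    """Input has no usable variation (e.g. zero retention-time variance)."""


class UnimputableError(HarmolibError):
    """No chain of warps reaches a matrix; carries the affected peptides."""

    def __init__(self, message: str, peptides=()):
        super().__init__(message)
        self.peptides = list(peptides)


class InsufficientTracesError(HarmolibError):
    """Fewer than two fragment chromatograms for peak-shape scoring."""


class BoundaryError(HarmolibError):
    """An integration boundary does not intersect the trace's time range."""


class NormalizationError(HarmolibError):
    """No complete-case rows to anchor run-level normalization."""
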