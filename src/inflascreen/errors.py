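"""Exception hierarchy for the screening pipeline.

Everything raised on bad input derives from :class:`ScreenError` so callers
(and the CLI) can catch one base class. Validation errors carry enough
context (row numbers, well labels, plate ids) to locate the offending input.
"""

from __future__ import annotations


class ScreenError(Exception):
    """Base class for all pipeline errors."""


class FormatError(ScreenError):
    """A file is structurally unusable (missing columns, undetectable dialect)."""


class ValidationError(ScreenError):
    """Rows or records violate the data model; carries row context."""

    def __init__(self, message: str, rows: list[int] | None = None):
        self.rows = rows or []
        if self.rows:
            message = f"{message} (rows: {', '.join(map(str, self.rows))})"
        super().__init__(message)


class WellLabelError(ValidationError):
    """A well label does not parse to a 384-well coordinate."""


class UndefinedRatioError(ScreenError):
    """HTRF ratio undefined because the 620 nm (donor) channel is zero."""


class DegenerateWindowError(ScreenError):
    """High- and low-control means coincide; normalization/Z' undefined."""


class InsufficientControlsError(ScreenError):
    """Fewer than two control values for a plate/analyte/role."""


class InsufficientDosesError(ScreenError):
    """Fewer than three distinct doses for a dose-response fit."""


class IncompletePairError(ScreenError):
    """A compound lacks one of the two analyte measurements."""

    def __init__(self, message: str, compound_ids: list[str] | None = None):
        self.compound_ids = compound_ids or []
        if self.compound_ids:
            shown = ", ".join(self.compound_ids[:10])
            more = "" if len(self.compound_ids) <= 10 else f" (+{len(self.compound_ids) - 10} more)"
            message = f"{message}: {shown}{more}"
        super().__init__(message)


class AlignmentError(ScreenError):
    """Dose grids of the two analytes do not match."""
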