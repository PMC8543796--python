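"""Exception hierarchy for the harmonization toolkit."""


class HarmonizationError(Exception):
    """Base class for all toolkit errors."""


class StructuralError(HarmonizationError):
    """The crosswalk or dataset violates a structural invariant
    (duplicate rows, gate cycles, unresolvable references)."""


class RecodeParseError(HarmonizationError):
    """A recode mini-grammar string could not be parsed.

    Carries the cell coordinates (row, column) when raised during
    crosswalk reading.
    """

    def __init__(self, message, row=None, column=None):
        self.row = row
        self.column = column
        if row is not None:
            message = f"{message} (row {row}, column {column!r})"
        super().__init__(message)


class UndomainedCodeError(HarmonizationError):
    """A raw code observed in the data is outside the recode rule's domain."""

    def __init__(self, code, count):
        self.code = code
        self.count = count
        super().__init__(
            f"raw code {code} observed {count} time(s) is not in the "
            f"recode rule's domain; declare it as a response option or "
            f"missing code in the crosswalk"
        )


class RangeError(HarmonizationError):
    """A harmonized value falls outside its declared range."""


class ConfigError(HarmonizationError):
    """An invalid or contradictory generator/pipeline configuration."""


class DegenerateItemError(HarmonizationError):
    """An item unsuitable for IRT estimation reached the model stage.

    Items with 0% or 100% endorsement must be removed by the QC
    filters (no-variability check) before model fitting.
    """


class EstimationError(HarmonizationError):
    """Model estimation failed structurally (too few items/pairs)."""
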