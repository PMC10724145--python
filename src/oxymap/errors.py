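"""Exception hierarchy for the oxymap pipeline."""


class OxymapError(Exception):
    """Base class for all oxymap errors."""


class SchemaError(OxymapError):
    """A mandatory column is missing from a measurement table."""


class RowParseError(OxymapError):
    """A cell in a data row could not be parsed; carries the row index."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


class InsufficientDataError(OxymapError):
    """Too few observations for the requested fit or test."""


class DegenerateBoundsError(OxymapError):
    """A normalization variable is constant (max == min)."""


class DegenerateDataError(OxymapError):
    """Random splits repeatedly produced constant training predictors."""


class ParameterError(OxymapError):
    """An argument is outside its valid range."""


class CalibrationConfigError(OxymapError):
    """An instrument group present in the data has no calibration fit."""


class CoregistrationError(OxymapError):
    """Raster layers disagree in shape, transform, or CRS."""


class RasterFormatError(OxymapError):
    """Unsupported raster file (multi-band, missing georeference, ...)."""
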