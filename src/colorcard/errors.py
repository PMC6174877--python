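"""Exception hierarchy for the colorcard package."""


class ColorCardError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ColorCardError):
    """Raised for non-finite, out-of-range, or malformed numeric input."""


class SingularDesignError(ColorCardError):
    """Extended chip design is rank-deficient; the transform is incalculable.

    Carries the numerical rank that was found so callers can report how many
    independent chip colors remain.
    """

    def __init__(self, rank: int, required: int = 9):
        self.rank = rank
        self.required = required
        super().__init__(
            f"extended chip design has numerical rank {rank} < {required}; "
            "too few independent chip colors to fit the transform"
        )


class CorrespondenceError(ColorCardError):
    """Source and target chips are not homologous (ids or count mismatch)."""


class GeometryError(ColorCardError):
    """A region of interest falls outside the image or is empty."""


class FormatError(ColorCardError):
    """Raster has the wrong number of channels or dtype."""


class ConfigError(ColorCardError):
    """A configuration file or parameter is invalid."""


class EmptyObjectError(ColorCardError):
    """A mask contains no foreground pixels."""


class GridError(ColorCardError):
    """Two histograms are not defined on the same bin grid."""
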