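"""Exception hierarchy shared across the package."""


class ThumbRomError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ThumbRomError, ValueError):
    """An input object violates a documented invariant."""


class FormatError(ValidationError):
    """A landmark table on disk does not conform to the documented dialect."""


class SchemaError(ValidationError):
    """A feature table does not match the column names/order a model expects."""


class DegenerateGeometryError(ThumbRomError, ValueError):
    """A geometric quantity is undefined (zero-length arm, coincident points)."""


class ProjectionError(ThumbRomError, ValueError):
    """A 3D point cannot be projected (non-positive depth in camera frame)."""


class CalibrationError(ThumbRomError, RuntimeError):
    """Noise calibration could not bracket the requested target."""


class UndefinedStatisticError(ThumbRomError, ValueError):
    """A statistic (Pearson CC, R^2) is undefined for the given data.

    The error still carries the error metrics that *are* defined, so callers
    can report RMSE/MAE for degenerate (zero-variance) label sequences.
    """

    def __init__(self, message: str, rmse: float | None = None,
                 mae: float | None = None):
        super().__init__(message)
        self.rmse = rmse
        self.mae = mae
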