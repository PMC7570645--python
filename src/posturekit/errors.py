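"""Exception hierarchy for posturekit."""


class PostureKitError(Exception):
    """Base class for all posturekit errors."""


class InvalidDataError(PostureKitError, ValueError):
    """Input data are malformed (non-finite values, wrong shape, mixed units...)."""


class InvalidParameterError(PostureKitError, ValueError):
    """A parameter is outside its valid domain (e.g. confidence not in (0, 1))."""


class CalibrationDataError(PostureKitError, ValueError):
    """Not enough calibration data to fit a full-rank trivariate Gaussian."""


class NumericalDegeneracyError(PostureKitError, ArithmeticError):
    """A covariance matrix is singular beyond what regularization may repair."""


class UndefinedScoreError(PostureKitError, ValueError):
    """A session score was requested over a window containing no records."""


class TraceParseError(InvalidDataError):
    """A trace file failed to parse; ``line`` is the 1-based offending line."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class SaturationWarning(UserWarning):
    """A simulated magnetometer reading exceeded the sensor dynamic range."""
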