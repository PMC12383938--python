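"""Exception hierarchy for the sobprbe pipeline.

Every error raised by the package derives from :class:`SobpRbeError` so callers
can catch pipeline failures without masking programming errors.
"""


class SobpRbeError(Exception):
    """Base class for all sobprbe errors."""


class NotFoundError(SobpRbeError):
    """A named fixture or resource does not exist."""


class InvalidTruthError(SobpRbeError):
    """Synthetic ground-truth parameters yield an impossible survival probability."""


class PlacementError(SobpRbeError):
    """Requested colonies cannot be placed without overlap inside a well ROI."""


class UniformImageError(SobpRbeError):
    """An intensity histogram has fewer than two occupied bins; no threshold exists."""


class ROIError(SobpRbeError):
    """A well ROI is invalid (out of image bounds or overlapping another ROI)."""


class ControlError(SobpRbeError):
    """Control colony-count reference is non-positive."""


class WindowError(SobpRbeError):
    """A column window selects too few columns to summarize."""


class InsufficientDataError(SobpRbeError):
    """Too few points or distinct doses for a model fit."""


class FitError(SobpRbeError):
    """Nonlinear least squares failed to converge."""


class NoIsoeffectDoseError(SobpRbeError):
    """The photon LQ model admits no nonnegative real isoeffect dose for this SF.

    Carries the surviving fraction and LQ parameters for diagnostics.
    """

    def __init__(self, sf: float, alpha: float, beta: float, column_index=None):
        self.sf = sf
        self.alpha = alpha
        self.beta = beta
        self.column_index = column_index
        where = "" if column_index is None else f" (column {column_index})"
        super().__init__(
            f"no nonnegative real isoeffect dose for sf={sf:.6g} "
            f"with alpha={alpha:.6g}, beta={beta:.6g}{where}"
        )


class DegenerateInputError(SobpRbeError):
    """Statistical input is degenerate (zero variance, too few observations)."""


class SchemaError(SobpRbeError):
    """A table fails schema validation; the message names the row and field."""
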