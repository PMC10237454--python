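"""Exception hierarchy shared across the pipeline stages."""


class TugSpeedError(Exception):
    """Base class for all package errors."""


class InvalidInputError(TugSpeedError):
    """Input data violates a documented precondition."""


class InvalidParameterError(TugSpeedError):
    """A configuration parameter is outside its documented range."""


class CalibrationDegenerateError(TugSpeedError):
    """Calibration markers coincide along the axis they are meant to scale."""


class UnusableTrackError(TugSpeedError):
    """A centroid track has too few valid frames to process."""


class SegmentationError(TugSpeedError):
    """A TUG subtask boundary could not be located."""


class InvalidConfigError(TugSpeedError):
    """A synthetic-trial configuration is internally inconsistent."""
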