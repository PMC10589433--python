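"""Exception hierarchy shared across the pipeline stages."""


class CVRKitError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(CVRKitError, ValueError):
    """An argument violates a documented precondition."""


class EmptyTraceError(CVRKitError):
    """No end-tidal peaks could be extracted from a physiological recording."""


class InsufficientTraceError(CVRKitError):
    """The EtCO2 trace covers too little of the scan window to resample."""


class GridMismatchError(CVRKitError):
    """Two volumes or masks do not share the same voxel grid."""


class OrientationError(CVRKitError):
    """Anatomical axis mapping is required but unavailable."""


class EmptyROIError(CVRKitError):
    """A region-of-interest mask contains no voxels."""


class SignalError(CVRKitError):
    """A BOLD series is unusable (e.g. non-positive temporal mean)."""


class DegenerateDesignError(CVRKitError):
    """The regression design matrix is rank-deficient (constant regressor)."""


class EstimationError(CVRKitError):
    """No valid fit could be produced at any candidate delay."""


class InsufficientDataError(CVRKitError):
    """Too few complete cases to fit a model or contrast."""


class CollinearityWarning(UserWarning):
    """Design matrix condition number exceeds the configured threshold."""
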