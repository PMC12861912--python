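"""Exception hierarchy shared across the package."""


class RsifitError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(RsifitError, ValueError):
    """An argument violates a documented precondition."""


class UnfittableVoxelError(RsifitError):
    """A voxel signal cannot support the requested model fit."""


class EmptyROIError(RsifitError):
    """The ROI mask intersects no fitted voxels."""


class DegenerateTableError(RsifitError, ValueError):
    """A contingency table has a zero marginal or zero cell where forbidden."""


class UndefinedICCError(RsifitError):
    """Total variance is zero; the intraclass correlation is undefined."""


class SeparationError(RsifitError):
    """Perfect separation detected during logistic maximum likelihood."""

    def __init__(self, predictor: str):
        self.predictor = predictor
        super().__init__(
            f"perfect separation detected; offending predictor: {predictor!r}"
        )


class CollinearityError(RsifitError, ValueError):
    """The design matrix is rank deficient."""


class ConvergenceError(RsifitError):
    """Iterative fitting failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        self.trace = list(trace) if trace is not None else []
        super().__init__(message)


class ConfigError(RsifitError, ValueError):
    """A run configuration references missing files or invalid settings."""
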