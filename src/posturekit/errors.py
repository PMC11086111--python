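"""Exception hierarchy for posturekit."""


class PostureKitError(Exception):
    """Base class for all posturekit errors."""


class FormatError(PostureKitError):
    """An input file violates the landmark record schema."""


class LandmarkParseError(FormatError):
    """A coordinate or score field could not be parsed."""


class OrientationError(PostureKitError):
    """Body orientation could not be determined from a capture."""


class DegenerateSegmentError(PostureKitError):
    """A zero-length segment was passed to an angle computation."""


class UndefinedMeanError(PostureKitError):
    """Circular mean undefined: the resultant vector is (numerically) zero."""


class WrongViewError(PostureKitError):
    """An operation received a capture from the wrong view."""


class InsufficientDataError(PostureKitError):
    """Not enough captures/values to compute the requested quantity."""


class ParameterComputationError(PostureKitError):
    """One or more named postural parameters could not be computed."""

    def __init__(self, message, parameters=()):
        super().__init__(message)
        self.parameters = tuple(parameters)


class InsufficientSampleError(PostureKitError):
    """Sample too small for the requested statistic."""


class InsufficientVarianceError(PostureKitError):
    """Sample is (numerically) constant; the statistic is undefined."""


class IncompleteDesignError(PostureKitError):
    """Missing cells in a subjects x sessions measurement matrix."""


class PairingError(PostureKitError):
    """Subject ids of two sessions could not be matched."""

    def __init__(self, message, orphans=()):
        super().__init__(message)
        self.orphans = tuple(orphans)


class InvalidInputError(PostureKitError):
    """A numeric argument is outside its valid domain."""


class SpecError(PostureKitError):
    """A synthetic-cohort specification is invalid or infeasible."""


class PoseInfeasibleError(PostureKitError):
    """No stick-figure pose realizes the requested parameter combination."""
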