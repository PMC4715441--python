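"""Exception hierarchy.

Three broad families map onto distinct CLI exit codes: input problems
(malformed files, bad schemas), geometry problems (segments that cannot be
hulled, broken surfaces) and statistics problems (under-determined fits,
singular covariances).
"""


class HullMassError(Exception):
    """Base class for all package errors."""


class InputError(HullMassError):
    """A file or table could not be read or violates its schema."""


class InvalidSpec(InputError):
    """A synthetic-data specification is internally inconsistent."""


class GeometryError(HullMassError):
    """Base class for geometric failures."""


class DegenerateGeometry(GeometryError):
    """A point set is too sparse or too flat to bound a 3D hull.

    Carries the offending segment label in ``label`` when raised while
    processing a skeleton.
    """

    def __init__(self, message: str, label: str | None = None):
        super().__init__(message)
        self.label = label


class OpenSurface(GeometryError):
    """A facet set does not close up into a watertight surface."""


class InvalidPlane(GeometryError):
    """A mirror plane was given a zero-length normal."""


class StatsError(HullMassError):
    """Base class for statistical failures."""


class InsufficientData(StatsError):
    """Too few observations for the requested fit or test."""


class NonPositiveValue(StatsError):
    """A mass or volume that must be positive is not."""


class MissingTip(StatsError):
    """A species in the dataset has no matching tip in the phylogeny."""


class SingularCovariance(StatsError):
    """The phylogenetic covariance matrix is not positive definite."""


class UnknownTag(StatsError):
    """An unrecognized preparation subset tag."""


class ZeroVariance(StatsError):
    """A sample with zero variance cannot support a t-test."""


class VariantMismatch(StatsError):
    """Model predictor variant does not match the supplied volume column."""
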