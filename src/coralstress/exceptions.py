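"""Exception hierarchy shared across the package.

Every error raised by coralstress derives from :class:`CoralStressError`
so callers can catch the package's failures with a single clause while
still discriminating the stage that failed.
"""


class CoralStressError(Exception):
    """Base class for all coralstress errors."""


class ConfigurationError(CoralStressError):
    """An experiment/design configuration violates its invariants."""


class ModelCoverageError(CoralStressError):
    """A simulation model lacks parameters for a requested design cell."""


class SamplingError(CoralStressError):
    """More biomarker replicates requested than surviving fragments."""


class DegenerateCurveError(CoralStressError):
    """A standard curve is unusable (zero slope or rank-deficient standards)."""


class NormalizationError(CoralStressError):
    """Protein normalization requested with non-positive total protein."""


class GroupingError(CoralStressError):
    """A species in a condition table has no group assignment."""


class DegeneracyError(CoralStressError):
    """A statistical model cannot be estimated (singular covariance, zero SD)."""


class DesignError(CoralStressError):
    """An analysis design is unusable (empty factor level, too few cells)."""


class TransformError(CoralStressError):
    """A data transform cannot be applied (e.g. log of non-positive values)."""


class GeometryError(CoralStressError):
    """Star-plot geometry is undefined (fewer than 3 spokes, negative radius)."""
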