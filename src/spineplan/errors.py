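"""Exception hierarchy for the spineplan pipeline.

Every error carries a human-readable message naming the offending
structure, field, or landmark so CLI diagnostics stay one line.
"""


class SpinePlanError(Exception):
    """Base class for all spineplan errors."""


class OutOfBoundsError(SpinePlanError):
    """A structure, keypoint, or plane falls outside the voxel grid."""


class InvalidSpecError(SpinePlanError):
    """A phantom spec violates its invariants."""


class InvalidRangeError(SpinePlanError):
    """A cohort variation range is infeasible."""


class ShapeMismatchError(SpinePlanError):
    """Two arrays that must share a shape do not."""


class NoReferenceFoundError(SpinePlanError):
    """No candidate qualifies as the L5/S1 reference disc."""


class NoCandidatesError(SpinePlanError):
    """Every heatmap channel is empty."""


class DegenerateMaskError(SpinePlanError):
    """A binary mask is too small for a stable decomposition."""


class InsufficientPointsError(SpinePlanError):
    """Fewer points than the fit requires."""


class InsufficientDiscsError(SpinePlanError):
    """Fewer than two labeled discs; spacing statistics undefined."""


class MissingLandmarkError(SpinePlanError):
    """A measurement's landmark is absent."""


class MissingStructureError(SpinePlanError):
    """A labeled structure required by a measurement is absent."""


class DegenerateDirectionError(SpinePlanError):
    """A direction vector has (near-)zero length."""


class DegenerateCanalError(SpinePlanError):
    """Canal area is zero on the evaluated slice."""


class DegenerateLandmarkError(SpinePlanError):
    """A landmark construction (e.g. the intra-facet line) is degenerate."""


class EmptyCohortError(SpinePlanError):
    """A cohort-level statistic was requested on zero phantoms."""


class FormatError(SpinePlanError):
    """A file could not be parsed into a volume or report."""


class ConfigError(SpinePlanError):
    """Pipeline configuration failed validation."""
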