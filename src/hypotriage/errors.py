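"""Exception hierarchy for structure, cohort and configuration errors."""


class HypotriageError(Exception):
    """Base class for all package-specific errors."""


class CoregistrationError(HypotriageError):
    """Two masks do not share grid shape, spacing, origin and orientation."""


class EmptyStructureError(HypotriageError):
    """An operation that requires a nonempty structure received an empty one."""


class InvalidContourError(HypotriageError):
    """A planar contour is degenerate (fewer than three vertices)."""


class ExtentError(HypotriageError):
    """A structure or contour stack does not fit inside the target grid."""


class DegenerateCohortError(HypotriageError):
    """A labelled cohort is empty or contains only one eligibility class."""


class StratificationError(HypotriageError):
    """A class has too few members to be split across two folds."""


class MissingStructureError(HypotriageError):
    """A constraint references a structure with no matching DVH."""
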