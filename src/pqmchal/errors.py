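"""Exception hierarchy for the challenge pipeline."""


class PqmchalError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(PqmchalError):
    """Phantom specification violates an invariant (nesting, bounds, volume)."""


class CalibrationError(PqmchalError):
    """Cohort calibration is unusable (missing fields, irreparable matrix)."""


class InfeasibleTargetError(PqmchalError):
    """A combination of per-plan metric targets cannot be painted."""


class EmptyStructureError(PqmchalError):
    """A metric was requested on a structure with no voxels."""


class AlignmentError(PqmchalError):
    """Dose grid and structure mask do not share a grid."""


class SchemeValidationError(PqmchalError):
    """A scoring scheme violates its structural invariants."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid scoring scheme:\n- " + "\n- ".join(self.violations))


class InputError(PqmchalError):
    """Required input (metric value, metadata field) is missing or malformed."""


class DegenerateInputError(PqmchalError):
    """Statistical routine received an input with no information (e.g. all zeros)."""


class FormatError(PqmchalError):
    """A file does not conform to its documented schema."""
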