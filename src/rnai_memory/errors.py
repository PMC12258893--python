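"""Exception hierarchy for the rnai_memory package."""


class RnaiMemoryError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RnaiMemoryError):
    """A table is missing a required column or has a malformed header."""


class ValidationError(RnaiMemoryError):
    """A row or value violates a data-model invariant."""


class ParameterError(RnaiMemoryError):
    """A parameter is outside its admissible range."""


class GroupingError(RnaiMemoryError):
    """Records passed to a per-replicate operation do not share a group key."""


class ScheduleError(RnaiMemoryError):
    """A generation schedule cannot resolve a temperature or environment label."""


class AlignmentError(RnaiMemoryError):
    """Replicate trajectories do not share a common generation grid."""


class AliasingError(RnaiMemoryError):
    """The fixed-effects design is rank deficient (collinear factor levels)."""


class EstimabilityError(RnaiMemoryError):
    """A requested marginal mean involves an empty design cell."""


class ConvergenceError(RnaiMemoryError):
    """An iterative fit failed to reach its stopping tolerance."""


class RightCensored(RnaiMemoryError):
    """Signal: the trajectory never sustainedly reaches the threshold.

    Raised by bracket selection and handled by the half-life caller, which
    converts it into a ``censored`` estimate rather than an error.
    """


class LeftAnchored(RnaiMemoryError):
    """Signal: every scored point is already at or above the threshold.

    Handled by the half-life caller by anchoring the bracket at the fully
    silenced G0 point (0% GFP-positive at coordinate 0).
    """
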