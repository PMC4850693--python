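"""Exception types shared across the package."""


class WaveArcError(ValueError):
    """Base class for all domain errors raised by this package."""


class TrajectoryError(WaveArcError):
    """Malformed or degenerate gantry-ring trajectory."""


class InfeasiblePlanError(WaveArcError):
    """A delivery plan cannot be realised under the machine constraints.

    Carries the name of the binding constraint and, for per-sub-arc
    failures, the index of the offending sub-arc.
    """

    def __init__(self, message: str, *, binding: str, subarc: int | None = None):
        super().__init__(message)
        self.binding = binding
        self.subarc = subarc


class DegenerateApertureError(WaveArcError):
    """MLC aperture with no open leaf pair where one is required."""


class DegenerateInputError(WaveArcError):
    """Statistically or numerically degenerate input (e.g. zero variance)."""


class PlanFileError(WaveArcError):
    """Schema violation in a plan file; lists every offending field."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid plan file: " + "; ".join(self.problems))
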