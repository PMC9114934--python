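"""Exception types shared across the toolkit."""


class InvalidArgumentError(ValueError):
    """An argument violates an operation's preconditions."""


class SimulationDivergedError(RuntimeError):
    """The integrator blew up.  Carries whatever trajectory prefix exists."""

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial


class NoSolutionError(RuntimeError):
    """Inverse kinematics (or another solver) found no admissible solution."""


class TrainingDivergedError(RuntimeError):
    """A learning update produced non-finite losses."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is exactly zero (e.g. zero total variance)."""
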