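"""Exception hierarchy for phasecell."""


class PhasecellError(Exception):
    """Base class for all phasecell errors."""


class ConfigurationError(PhasecellError):
    """Invalid run configuration, parameters, or preconditions."""


class NumericalError(PhasecellError):
    """Non-finite values or other numerical faults in field operations."""


class InstabilityError(NumericalError):
    """A time step produced a non-finite or blown-up phase field.

    Carries the index of the offending cell (``cell_index``) and, when
    raised inside an evolution loop, the last good state (``last_state``).
    """

    def __init__(self, message, cell_index=None, last_state=None):
        super().__init__(message)
        self.cell_index = cell_index
        self.last_state = last_state


class DisappearanceError(PhasecellError):
    """A cell's phase field collapsed below the detection threshold mid-run.

    Attributes
    ----------
    cell_names : list of str
        Names of the collapsed cells.
    last_state : SimState or None
        The last snapshot before the abort.
    """

    def __init__(self, message, cell_names=(), last_state=None):
        super().__init__(message)
        self.cell_names = list(cell_names)
        self.last_state = last_state


class SchedulingError(PhasecellError):
    """Division schedule is inconsistent with the current cell population."""


class PackingError(PhasecellError):
    """Random packing failed to reach the overlap-free postcondition."""


class ScheduleParseError(ConfigurationError):
    """Malformed division-schedule file; carries the offending line number."""

    def __init__(self, message, line=None):
        super().__init__(message)
        self.line = line
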