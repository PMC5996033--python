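"""Exception hierarchy for plusmaze.

All package errors derive from :class:`PlusMazeError` so callers can catch
everything with one clause; the subclasses distinguish bad trial data,
illegal model parameters, malformed log files and unusable configuration.
"""


class PlusMazeError(Exception):
    """Base class for all plusmaze errors."""


class InvalidTrialError(PlusMazeError, ValueError):
    """A trial violates the task's structural invariants.

    Raised e.g. when an offered pair repeats an arm, odor or LED color,
    or when a reward is inconsistent with the deterministic schedule.
    """


class ParameterError(PlusMazeError, ValueError):
    """A model parameter is outside its legal range.

    Learning rates live in [0, 1], inverse temperatures in [0, 30], and
    decision weights on the probability simplex.
    """


class LogValidationError(PlusMazeError, ValueError):
    """A behavioral-log file failed validation (bad schema, bad row, bad order)."""


class ConfigError(PlusMazeError, ValueError):
    """A fitting or pipeline configuration is unusable (e.g. empty grid)."""


class NoComparableDaysError(PlusMazeError):
    """Model comparison found no day passing the inclusion filter."""
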