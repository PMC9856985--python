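"""Exception hierarchy for the restwatch pipeline.

Validation failures raise a subclass of :class:`RestwatchError` so callers can
distinguish bad input from genuine computation errors (exit codes in the CLI).
"""


class RestwatchError(Exception):
    """Base class for all restwatch-specific errors."""


# --- io_formats ---------------------------------------------------------
class MalformedEpochFile(RestwatchError):
    """Epoch CSV violates the dialect: irregular spacing, bad types, negative counts."""


class EmptySeries(RestwatchError):
    """An epoch series with no rows."""


class SchemaError(RestwatchError):
    """A table does not match its declared schema."""


class UnparseableTime(RestwatchError):
    """A clock-time field could not be parsed as HH:MM."""


# --- rest_activity ------------------------------------------------------
class NoInBedEpochs(RestwatchError):
    """No in-bed epochs available for the dichotomy index."""


class AllMissing(RestwatchError):
    """Every epoch in the required pool is missing."""


class SeriesTooShort(RestwatchError):
    """Series too short for the 24-h lag autocorrelation."""


class NoWakeSpan(RestwatchError):
    """Fewer than two in-bed intervals, so no between-sleep span exists."""


# --- sleep_metrics ------------------------------------------------------
class IntervalOutsideSeries(RestwatchError):
    """An in-bed interval is not fully covered by the epoch series."""


class NoSleepDetected(RestwatchError):
    """No qualifying sleep-onset run inside the in-bed interval."""


class InconsistentTimes(RestwatchError):
    """Diary clock times are mutually inconsistent (e.g. TWAK < 0 or TIB <= 0)."""


class TooFewNights(RestwatchError):
    """Fewer nights than required for a participant-level aggregate."""


# --- feature_assembly ---------------------------------------------------
class UnknownLevel(RestwatchError):
    """A categorical value is not among the declared ordinal levels."""


class TooMuchMissingness(RestwatchError):
    """A feature exceeds the allowed missing fraction before imputation."""


# --- survival_models ----------------------------------------------------
class NoEvents(RestwatchError):
    """Too few events to fit or test a survival model."""


class DegenerateFeature(RestwatchError):
    """A feature with zero variance cannot be standardised."""


class AllTied(RestwatchError):
    """All predicted hazards identical; no median split possible."""


class ZeroVariance(RestwatchError):
    """A correlation input has zero variance."""


# --- univariate_survival ------------------------------------------------
class DegenerateSplit(RestwatchError):
    """A grouping rule put every participant in one group."""


class IncompleteMatrix(RestwatchError):
    """The day-by-participant matrix for the ICC contains missing cells."""
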