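"""Exception hierarchy for glymseg.

All errors raised by the library derive from :class:`GlymsegError` so callers
can distinguish domain failures (bad data, non-identifiable models) from
programming errors.
"""


class GlymsegError(Exception):
    """Base class for all glymseg errors."""


class InvalidReferenceError(GlymsegError):
    """Reference-ROI T1 value is non-positive or non-finite."""


class EmptySeriesError(GlymsegError):
    """A filtering or selection step produced a series with no observations."""


class MappingError(GlymsegError):
    """An atlas segment has no composite-region mapping."""


class DegenerateTestError(GlymsegError):
    """A summary test statistic is undefined (e.g. zero variance everywhere)."""


class InsufficientDataError(GlymsegError):
    """Too few observations to fit the segmented model."""


class NonConvergenceError(GlymsegError):
    """No breakpoint initialization produced a convergent iteration.

    Carries the restart RSS profile (candidate breakpoint -> final RSS) for
    diagnosis when available.
    """

    def __init__(self, message, rss_profile=None):
        super().__init__(message)
        self.rss_profile = rss_profile


class UnidentifiableBreakpointError(GlymsegError):
    """The post-breakpoint slope is indistinguishable from zero, so the
    breakpoint location carries no information."""


class EmptyGridError(GlymsegError):
    """No admissible candidate breakpoint on the requested grid."""


class DegenerateR2Error(GlymsegError):
    """Total sum of squares is zero (constant outcome), so R^2 is undefined."""


class EmptyFamilyError(GlymsegError):
    """Multiplicity adjustment requested for an empty p-value family."""


class InvalidScenarioError(GlymsegError):
    """A simulation scenario violates its invariants."""


class MissingCohortError(GlymsegError):
    """A requested cohort label has no observations."""
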