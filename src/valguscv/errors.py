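"""Exception hierarchy for valguscv.

Every error raised by the library derives from :class:`ValgusError`, so
callers (and the CLI) can catch one base class. Names mirror the failure
modes of the pipeline stages: image/config validation, marker assignment,
degenerate geometry, reliability-analysis preconditions, and synthetic-data
spec validation.
"""


class ValgusError(Exception):
    """Base class for all valguscv errors."""


# --- detection ---------------------------------------------------------


class ImageTooSmall(ValgusError):
    """Image smaller than the 64x64 px minimum."""


class ConfigInvalid(ValgusError):
    """Detection config fails validation (empty colors, inverted bounds...)."""


class TooFewMarkers(ValgusError):
    """Fewer than three candidate blobs available for landmark assignment."""


class AmbiguousOrdering(ValgusError):
    """Two selected blobs are too close vertically to order reliably."""


# --- geometry ----------------------------------------------------------


class DegenerateGeometry(ValgusError):
    """A patella->landmark ray is shorter than 1 px."""


# --- reliability -------------------------------------------------------


class InsufficientSubjects(ValgusError):
    """Fewer than 3 complete subjects in the pivoted measurement matrix."""


class ZeroVariance(ValgusError):
    """All measurements identical; ICC / correlation undefined."""


class IccAboveOne(ValgusError):
    """SEM requested with ICC > 1."""


class NonPositiveMean(ValgusError):
    """CV requested for a condition whose mean is not positive."""


class DesignColumnsMissing(ValgusError):
    """Measurement table lacks the condition levels the design requires."""


# --- synthetic data ----------------------------------------------------


class SpecOutOfBounds(ValgusError):
    """A scene spec places markers or distractors outside the canvas."""


class DoesNotFit(ValgusError):
    """Requested landmark geometry does not fit the canvas."""


class Infeasible(ValgusError):
    """No non-negative variance decomposition achieves the target ICC."""


class SpecInvalid(ValgusError):
    """Simulation spec JSON is malformed."""


# --- cli ---------------------------------------------------------------


class EmptyInput(ValgusError):
    """No input images / rows found."""


class UnparsableFilename(ValgusError):
    """Filename does not follow subject_rater_occasion and no manifest given."""
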