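"""Exception types raised by the measurement chain.

Per-cell analysis failures raise one of these; the cohort driver catches
them so that a single failed cell never aborts a cohort run.
"""


class MicropassageError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MicropassageError):
    """Invalid or incomplete configuration."""


class FormatError(MicropassageError):
    """Malformed movie file or sidecar."""


class NoCellDetected(MicropassageError):
    """Cell segmentation found no foreground component above the minimum area."""


class NoNucleusDetected(MicropassageError):
    """Nucleus segmentation found nothing inside the (dilated) cell mask."""


class EmptyPerinuclearRegion(MicropassageError):
    """Cortex and nucleus have disjoint axial supports."""


class TrackTooShort(MicropassageError):
    """Fewer than two frames with valid masks."""


class UndefinedBaseline(MicropassageError):
    """No usable frames before the nucleus touched the constriction."""


class NotEncountered(MicropassageError):
    """The cell front never reached the constriction entrance; the cell is
    excluded from passage denominators."""


class CellNotInConstriction(MicropassageError):
    """Cell mask does not intersect the constriction region."""


class NaNIntensity(MicropassageError):
    """Degenerate intensity normalization (zero mean denominator)."""


class BeadOutsideCell(MicropassageError):
    """Bead mask lies outside the cell mask."""


class InsufficientColumns(MicropassageError):
    """Fewer than three axial columns qualify for the DNA-thickness regression."""


class NoRingSignal(MicropassageError):
    """Lamina ring median intensity is indistinguishable from zero."""


class BorderTouchWarning(UserWarning):
    """Mask touches the image border; perimeter-based metrics are unreliable."""
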