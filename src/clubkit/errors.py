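"""Exception hierarchy for the clubbing-assessment pipeline.

Every stage raises a subclass of :class:`ClubkitError`; the ``assess``
cascade catches these and converts them into structured failure records.
"""


class ClubkitError(Exception):
    """Base class for all errors raised by clubkit."""


class ValidationError(ClubkitError, ValueError):
    """A parameter is outside its documented domain.

    The message always names the offending field.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class NoFingerError(ClubkitError):
    """Segmentation found no foreground region ("no finger detected")."""


class OrientationError(ClubkitError):
    """The mask is too round for a principal axis to be meaningful."""


class ContourError(ClubkitError):
    """The silhouette boundary is open, fragmented, or too short."""


class FoldNotFoundError(ClubkitError):
    """No curvature extremum above the noise floor on the dorsal contour.

    Carries the largest prominence that *was* observed, to aid debugging.
    """

    def __init__(self, message: str, max_prominence_deg: float):
        self.max_prominence_deg = float(max_prominence_deg)
        super().__init__(f"{message} (max prominence {max_prominence_deg:.2f} deg)")


class DegenerateTripletError(ClubkitError):
    """Two landmarks coincide (or are antiparallel), so no angle exists."""
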