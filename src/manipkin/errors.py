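"""Exception hierarchy for manipkin.

Every failure mode surfaced to callers is a subclass of :class:`ManipkinError`
so CLI wrappers can catch one type and report structured messages.
"""


class ManipkinError(Exception):
    """Base class for all manipkin errors."""


class FileFormatError(ManipkinError):
    """A file could not be parsed; message names the offending location."""


class DialectError(FileFormatError):
    """CSV content does not match the documented dialect."""


class MissingMarkerError(ManipkinError):
    """A downstream metric requires a marker label the trial lacks."""

    def __init__(self, labels, context: str = ""):
        self.labels = tuple(labels)
        msg = f"missing required marker(s): {', '.join(self.labels)}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class MissingForceError(FileFormatError):
    """A file carries point data but no usable analog force channels."""


class FilterError(ManipkinError):
    """Invalid filter configuration (e.g. cutoff at/above Nyquist)."""


class DegenerateFrameError(ManipkinError):
    """Too few visible markers to estimate a pose for a frame."""


class RankDeficiencyError(ManipkinError):
    """Visible markers are (near-)collinear; the rotation is unobservable."""


class NoEventError(ManipkinError):
    """No manipulation event above threshold was found in a force series."""


class NoThrustError(ManipkinError):
    """No marker displacement excursion above the noise floor."""


class SegmentationError(ManipkinError):
    """Phase turning points are inconsistent (e.g. negative loaded force)."""


class WindowError(ManipkinError):
    """An analysis window is empty, fully masked, or out of range."""


class ConfigError(ManipkinError):
    """Invalid analysis or simulation configuration."""


class StatsError(ManipkinError):
    """Degenerate input to a statistical test."""
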