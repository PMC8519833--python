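"""Exception hierarchy for the measurement pipeline.

Each pipeline stage raises its own subclass so the command line interface
can report which stage failed.
"""


class MammometryError(Exception):
    """Base class for all package errors."""


class MeshFormatError(MammometryError):
    """Scan file is missing, malformed, or outside the supported OBJ dialect."""


class CropError(MammometryError):
    """A crop plane removed the entire mesh."""


class DetectionError(MammometryError):
    """Sticker segmentation or UV-to-surface mapping failed."""


class LabelingError(MammometryError):
    """Detections cannot be assigned to the expected anatomical labels."""


class GeometryError(MammometryError):
    """A geometric construction (plane, guideline intersection) is degenerate."""


class MeasurementError(MammometryError):
    """A required landmark or endpoint is missing, or points are unreachable."""


class PhantomError(MammometryError):
    """Invalid phantom configuration or degenerate phantom geometry."""


class StatsError(MammometryError):
    """Invalid input to a statistical routine."""
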