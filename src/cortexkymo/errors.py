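"""Exception types raised by the pipeline stages."""


class CortexKymoError(Exception):
    """Base class for all pipeline errors."""


class InvalidGeometryError(CortexKymoError):
    """Simulated cell geometry is inconsistent (e.g. bud larger than mother)."""


class NoCellsError(CortexKymoError):
    """Segmentation found no foreground objects."""


class TopologyError(CortexKymoError):
    """A labeled component is not simply connected (interior holes)."""


class BorderTruncationError(CortexKymoError):
    """A labeled component touches the image border; its outline is incomplete."""


class LandmarkError(CortexKymoError):
    """A neck landmark lies too far from the extracted contour."""


class BandOutOfBoundsError(CortexKymoError):
    """The normal sampling band extends outside the image for some rows."""

    def __init__(self, rows, msg=None):
        self.rows = list(rows)
        super().__init__(msg or f"sampling band leaves the image at rows {self.rows}")


class PipelineError(CortexKymoError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, msg: str):
        self.stage = stage
        super().__init__(f"{stage}: {msg}")
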