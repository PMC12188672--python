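"""Exception hierarchy.

Every failure mode raised by the library derives from :class:`LatentGeoError`
so that pipeline code can distinguish domain failures from programming errors.
"""


class LatentGeoError(Exception):
    """Base class for all library errors."""


class SchemaError(LatentGeoError):
    """A declared column is missing or the column mapping is invalid."""


class ValidationError(LatentGeoError):
    """Input data violates a structural invariant (e.g. duplicate times)."""


class ParseError(LatentGeoError):
    """A cell could not be parsed as a number; carries the row index."""


class InsufficientDataError(LatentGeoError):
    """Too few observations for the requested operation."""


class DegenerateSeriesError(LatentGeoError):
    """A series is constant, so no discretization alphabet can be built."""


class EstimationError(LatentGeoError):
    """An information-theoretic estimate cannot be formed (e.g. no overlap)."""


class GeometryError(LatentGeoError):
    """A cone or embedding quantity is undefined (e.g. both radii zero)."""


class EmbeddingError(LatentGeoError):
    """An embedding cannot be constructed in the requested space."""


class DegenerateHistogramError(LatentGeoError):
    """All values identical: no histogram threshold exists."""


class PipelineError(LatentGeoError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
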