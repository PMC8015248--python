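"""Exception hierarchy for the pipeline."""


class MorphoframeError(Exception):
    """Base class for all package errors."""


class MeshFormatError(MorphoframeError):
    """A mesh file could not be parsed in the named format."""


class UnsupportedTopologyError(MorphoframeError):
    """Mesh has non-triangular faces or otherwise unusable connectivity."""


class OrientationError(MorphoframeError):
    """Signed enclosed volume is non-positive (inward-facing winding)."""


class DegenerateAxisError(MorphoframeError):
    """A coordinate sequence has zero variance and cannot be standardized."""


class StationaryCellError(MorphoframeError):
    """Velocity is zero over the whole trajectory; no frame is definable."""


class ConvergenceError(MorphoframeError):
    """Iterative procedure failed to reach its tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class DegenerateShapeError(MorphoframeError):
    """A degree-1 harmonic coefficient in a denominator is ~zero."""


class IncompatibleDescriptorError(MorphoframeError):
    """Spherical-harmonic descriptors have mismatched truncation degree."""
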