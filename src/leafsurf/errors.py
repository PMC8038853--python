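"""Exception hierarchy for the leaf-surface reconstruction pipeline."""


class LeafSurfError(Exception):
    """Base class for all package errors."""


class PLYParseError(LeafSurfError):
    """Malformed PLY file; the message names the offending header line."""


class DegenerateGeometryError(LeafSurfError):
    """Input geometry does not support the requested operation
    (collinear cloud, zero-area polygon, zero a-spread, ...)."""


class InsufficientPointsError(LeafSurfError):
    """Fewer points than the operation's minimum (e.g. degree+1 for a fit)."""


class StripTooSparseError(LeafSurfError):
    """A strip holds fewer than ``delta`` points and must be skipped.

    This is a *skip signal*, not a fatal condition: callers drop the strip
    and log it, mirroring the discard rule for unreliable skeleton fits.
    """


class DegenerateSegmentError(LeafSurfError):
    """Two coincident skeleton points define no segment direction."""


class GenerationError(LeafSurfError):
    """Synthetic-leaf generation failed (self-intersecting distortion,
    holes removing every point, ...)."""


class PipelineError(LeafSurfError):
    """A pipeline stage failed; the message names the stage."""
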