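"""Exception hierarchy for the stripecluster pipeline."""


class StripeClusterError(Exception):
    """Base class for all package-specific errors."""


class DegenerateThresholdError(StripeClusterError, ValueError):
    """Automatic thresholding was asked for on a constant-valued channel."""


class FrameTooCrowdedError(StripeClusterError, RuntimeError):
    """Non-overlapping cell placement failed after the allowed rejection budget."""


class EmptyBackgroundError(StripeClusterError, ValueError):
    """A stripe class has no cell-free pixels, so its background level cannot
    be estimated from the image; supply a fallback constant instead."""


class MissingDesignCellError(StripeClusterError, ValueError):
    """A (strain, stimulus) cell of the 2x2 factorial design is empty."""


class ShapeMismatchError(StripeClusterError, ValueError):
    """Input grids do not share a common shape."""
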