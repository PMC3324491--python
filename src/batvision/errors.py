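"""Exception hierarchy shared across the pipeline."""


class BatVisionError(Exception):
    """Base class for all package-specific errors."""


class FrameError(BatVisionError):
    """Alignment is ragged or its width is not a multiple of three."""


class AlignmentIntegrityError(BatVisionError):
    """A sequence violates a coding-sequence invariant (e.g. in-frame stop)."""


class SaturationError(BatVisionError):
    """A distance correction's logarithm argument is non-positive."""

    def __init__(self, message, degeneracy_class=None, pair=None):
        super().__init__(message)
        self.degeneracy_class = degeneracy_class
        self.pair = pair


class TreeError(BatVisionError):
    """Malformed newick, duplicate leaves, or an invalid tree operation."""


class ModelError(BatVisionError):
    """Substitution-model parameter outside its domain."""


class OptimizationError(BatVisionError):
    """Optimizer failed to converge; carries the best fit found so far."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class ConfigError(BatVisionError):
    """Pipeline configuration invalid or referenced files missing."""
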