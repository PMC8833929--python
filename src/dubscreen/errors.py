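"""Exception hierarchy shared across the pipeline."""


class DubscreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DubscreenError, ValueError):
    """A simulation or run configuration violates its invariants."""


class PlacementError(DubscreenError, RuntimeError):
    """Non-overlapping object placement failed within the attempt limit."""


class ParameterError(DubscreenError, ValueError):
    """An operation parameter is outside its valid range."""


class DimensionError(DubscreenError, ValueError):
    """Input grids do not share the required dimensions."""


class IntegrityError(DubscreenError, ValueError):
    """Input table violates a uniqueness or schema constraint."""


class SampleSizeError(DubscreenError, ValueError):
    """Too few observations for the requested statistic."""


class KneePointError(DubscreenError, RuntimeError):
    """No knee exists (collinear waterfall); use a fixed cutoff instead."""


class DegenerateControlError(DubscreenError, ValueError):
    """Control population is degenerate (e.g. nonpositive median)."""


class CoverageError(DubscreenError, ValueError):
    """Time series does not cover the required time window."""


class EmptyMaskError(DubscreenError, ValueError):
    """Nuclear mask is empty; colocalization is undefined."""


class DegenerateChannelError(DubscreenError, ValueError):
    """A channel is constant; automatic thresholding is undefined."""


class UndefinedCoefficientError(DubscreenError, ValueError):
    """No above-threshold pixels; Manders coefficient is undefined."""


class DegenerateSplitError(DubscreenError, ValueError):
    """Expression is constant; quartile groups cannot be formed."""


class PairingError(DubscreenError, ValueError):
    """Replicates cannot be paired across conditions."""
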