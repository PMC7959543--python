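"""Exception hierarchy shared across the pipeline."""


class FrontfishError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(FrontfishError):
    """An input object violates a documented invariant."""


class ConfigurationError(FrontfishError):
    """A configuration value is inconsistent with the data it refers to."""


class SegmentationError(FrontfishError):
    """Foreground segmentation produced no usable object."""


class GenerationError(FrontfishError):
    """Synthetic-scene generation failed (degenerate geometry)."""
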