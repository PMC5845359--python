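"""Exception hierarchy for the axontracer pipeline."""


class AxonTracerError(Exception):
    """Base class for all axontracer errors."""


class FolderContentError(AxonTracerError):
    """The analysis folder contains a file that is not an image."""


class FilenameError(AxonTracerError):
    """An image filename violates the numeric-id naming rules."""


class EmptyFolderError(AxonTracerError):
    """The analysis folder contains no images."""


class ImageFormatError(AxonTracerError):
    """A file could not be decoded as a supported image."""


class ChannelAssignmentError(AxonTracerError):
    """Channel roles collide or reference a missing channel."""


class ParameterError(AxonTracerError):
    """A detection or ROI parameter is out of its valid range."""


class PolygonError(AxonTracerError):
    """A manual-ROI polygon file is malformed or degenerate."""


class EmptyRoiSignal(AxonTracerError):
    """The ROI mask is empty; the image is reported with zero axon length."""


class DegenerateImageError(AxonTracerError):
    """The whole image qualifies as a tissue hole (no analyzable signal)."""


class NormalizationError(AxonTracerError):
    """The normalization reference region has non-positive mean intensity."""


class FixtureError(AxonTracerError):
    """Synthetic fixture generation could not satisfy its constraints."""
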