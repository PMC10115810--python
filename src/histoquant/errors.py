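"""Exception hierarchy shared across the toolkit."""


class HistoquantError(Exception):
    """Base class for all toolkit errors."""


class FormatError(HistoquantError):
    """Input file exists but has an unsupported layout (e.g. multi-channel TIFF)."""


class EmptyRegionError(HistoquantError):
    """A region outline does not overlap the raster it is applied to."""


class DegenerateHistogramError(HistoquantError):
    """Auto-thresholding was asked to split a constant (single-valued) image."""


class DegenerateCorrelationError(HistoquantError):
    """Correlation requested on constant or too-short paired samples."""


class SamplingError(HistoquantError):
    """ROI sampling cannot place a box of the requested size in the region."""


class ModelStateError(HistoquantError):
    """A classifier was used before being trained."""
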