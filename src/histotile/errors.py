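"""Exception hierarchy for the histotile toolkit."""


class HistotileError(Exception):
    """Base class for all histotile errors."""


class SlideReadError(HistotileError, IOError):
    """Slide file missing or unreadable."""


class MetadataError(HistotileError):
    """Required slide metadata (e.g. microns-per-pixel) is absent."""


class InsufficientMagnificationError(HistotileError):
    """The slide lacks a pyramid level fine enough for the requested tile size.

    Callers may catch this and skip the slide.
    """


class BoundsError(HistotileError):
    """Requested region falls outside the slide's physical extent."""


class SpecError(HistotileError):
    """Invalid synthetic-slide specification."""


class DegenerateHistogramError(HistotileError):
    """Otsu threshold undefined: constant image or everything excluded."""


class CompositionError(HistotileError):
    """QC mask steps disagree on shape."""


class ROIError(HistotileError):
    """Invalid region-of-interest polygon."""


class StainFitError(HistotileError):
    """Stain normalizer could not be fit to the reference image."""


class DuplicateRecordError(HistotileError):
    """A (slide_id, x, y) key occurs twice in a tile store."""


class StoreError(HistotileError):
    """Corrupt or inconsistent tile store."""


class SchemaError(HistotileError):
    """Annotations table is missing required columns."""


class BalancingError(HistotileError):
    """Balanced sampling impossible (e.g. an empty class)."""


class AggregationError(HistotileError):
    """Tile-to-group mapping incomplete during prediction aggregation."""


class ConsistencyError(HistotileError):
    """Predictions and tile grid disagree."""


class RenderError(HistotileError):
    """A tile referenced by a mosaic cell cannot be resolved."""


class ConfigError(HistotileError):
    """Run configuration violates the schema."""
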