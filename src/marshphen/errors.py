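"""Exception hierarchy shared across the pipeline."""


class MarshPhenError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MarshPhenError):
    """Invalid scene, filter, fit or run configuration."""


class UndefinedIndexError(MarshPhenError):
    """A spectral index is undefined (zero denominator)."""


class EmptyInputError(MarshPhenError):
    """An operation received an empty series or table."""


class SampleShortageError(MarshPhenError):
    """A class has fewer pixels than the requested sample count."""


class SchemaError(MarshPhenError):
    """Tabular/raster inputs do not match the expected schema."""


class UnfitPixelError(MarshPhenError):
    """A pixel has too few observations for curve fitting."""


class DegenerateLabelsError(MarshPhenError):
    """Classification requested on fewer than two classes."""
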