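"""Exception hierarchy shared across the pipeline stages.

Recoverable per-cell failures (axis ambiguity, zero anchor, ...) are caught
by the pipeline and logged as skip reasons; everything else is fatal.
"""


class PhagenucError(Exception):
    """Base class for all package errors."""


class ConfigError(PhagenucError):
    """Invalid configuration (bad fractions, unknown preset, ...)."""


class GeometryError(PhagenucError):
    """A cell footprint does not fit inside the image."""


class OverlapError(PhagenucError):
    """Cells could not be placed without overlap within the attempt budget."""


class DegenerateHistogramError(PhagenucError):
    """Otsu thresholding of a (near-)constant intensity collection."""


class NoCellsError(PhagenucError):
    """Segmentation found no component within the area limits."""


class AxisAmbiguousError(PhagenucError):
    """Mask is too isotropic for a long axis to be defined."""


class ProfileError(PhagenucError):
    """Axis too short (or otherwise unusable) for profile extraction."""


class NormalizationError(PhagenucError):
    """Anchor intensity is not positive; the profile cannot be normalized."""


class ClassificationError(PhagenucError):
    """Localization score is undefined (non-positive end intensity)."""


class EnsembleError(PhagenucError):
    """Profiles with mismatched sampling cannot be averaged."""


class EmptyPopulationError(PhagenucError):
    """A population-level summary was requested for zero cells."""


class MaskError(PhagenucError):
    """Nucleus masking produced an empty mask."""
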