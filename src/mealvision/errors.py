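"""Exception hierarchy for the meal-measurement pipeline.

Card-related failures are deliberately recoverable: the orchestration layer
catches them and falls back to standard-serving volumes instead of aborting,
mirroring how a deployed assessment system must behave when the reference
card is missing from a photo.
"""


class MealVisionError(Exception):
    """Base class for all package errors."""


class SceneError(MealVisionError):
    """Invalid synthetic scene specification (bad shape parameters, overlap)."""


class CardOutOfView(MealVisionError):
    """The reference card is not fully inside the camera frustum."""


class CardNotFound(MealVisionError):
    """No plausible card quadrilateral detected in the image."""


class PoseUnsolvable(MealVisionError):
    """Card corners are degenerate; planar pose cannot be recovered."""


class AlignmentImpossible(MealVisionError):
    """No valid depth under the card region; metric alignment impossible."""


class RectificationFailed(MealVisionError):
    """Too few or degenerate correspondences for stereo rectification."""


class EmptyItem(MealVisionError):
    """A segmentation mask selects no valid depth pixels."""


class EmptyAfterRules(MealVisionError):
    """All points of an item were discarded by the height plausibility rules."""


class InsufficientPoints(MealVisionError):
    """Too few points remain for a meaningful volume integration."""


class MissingServing(MealVisionError):
    """Standard-serving fallback requested for a category with no serving entry."""


class MissingNutrientEntry(MealVisionError):
    """Category present in neither the primary nor the secondary nutrient table."""


class InvalidBarcode(MealVisionError):
    """EAN-13 string fails its checksum."""


class UnknownCategory(MealVisionError):
    """Label absent from the food taxonomy."""
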