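"""Flash/no-flash ambient subtraction in linear camera space.

Subtracting the no-flash (ambient-only) linear RGB from the flash
(ambient + screen) linear RGB leaves the signal as it would have been
recorded under the screen alone, because sensor response is linear and
illuminant contributions add.  Triplets whose post-subtraction signal is
too weak -- any channel below 1% of the normalized range -- are discarded:
either the screen did not illuminate the eye enough, or the ambient light
changed between the two captures and the subtraction is spurious.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .raw_frames import LinearRGB

__all__ = [
    "DEFAULT_THRESHOLD_FRAC",
    "FlashPairRGB",
    "SubtractionResult",
    "SubjectUnmeasurableError",
    "exposure_normalize",
    "subtract_pair",
    "aggregate_subject",
]

DEFAULT_THRESHOLD_FRAC = 0.01  # 1% of the normalized (bit-depth) range


class SubjectUnmeasurableError(ValueError):
    """Raised when no valid post-subtraction triplet remains for a subject."""


@dataclass(frozen=True)
class FlashPairRGB:
    """ROI-median linear RGB from one flash/no-flash capture pair."""

    flash_rgb: LinearRGB
    noflash_rgb: LinearRGB
    exposure_flash: float
    exposure_noflash: float

    def __post_init__(self) -> None:
        if self.exposure_flash <= 0 or self.exposure_noflash <= 0:
            raise ValueError("exposure times must be positive")


@dataclass(frozen=True)
class SubtractionResult:
    """Estimated flash-only linear RGB for one pair, with validity.

    ``reject_reason`` is one of None, "below_threshold", "negative_channel"
    or "saturated".  Invalidity is data, not an exception: rejected pairs
    are counted and reported, and a subject is only an error when no valid
    pair remains.
    """

    flash_only_rgb: LinearRGB
    valid: bool
    reject_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.valid and self.reject_reason is not None:
            raise ValueError("a valid result cannot carry a reject reason")
        if not self.valid and self.reject_reason is None:
            raise ValueError("an invalid result must carry a reject reason")


def exposure_normalize(pair: FlashPairRGB) -> FlashPairRGB:
    """Scale the no-flash RGB to the flash frame's exposure time.

    Linear sensor response means signal is proportional to exposure, so
    multiplying the ambient-only values by ``t_flash / t_noflash`` makes
    the two frames directly subtractable.  Identity when exposures match.
    """
    k = pair.exposure_flash / pair.exposure_noflash
    if k == 1.0:
        return pair
    return FlashPairRGB(
        flash_rgb=pair.flash_rgb,
        noflash_rgb=pair.noflash_rgb.scaled(k),
        exposure_flash=pair.exposure_flash,
        exposure_noflash=pair.exposure_flash,
    )


def subtract_pair(
    pair: FlashPairRGB,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
) -> SubtractionResult:
    """Channel-wise flash minus no-flash, with the weak-signal filter.

    The pair must already be exposure-normalized (and neither frame
    saturated; the caller checks saturation because it needs the mosaic).
    A triplet is rejected whole if any channel is negative (ambient
    increased between captures -- the subtraction is spurious) or falls
    below ``threshold_frac`` of the normalized range (flash signal too
    weak); a partial triplet has no meaningful chromaticity.
    """
    if pair.exposure_flash != pair.exposure_noflash:
        raise ValueError("pair must be exposure-normalized before subtraction")
    diff = pair.flash_rgb.as_array() - pair.noflash_rgb.as_array()
    rgb = LinearRGB(*diff)
    if np.any(diff < 0):
        return SubtractionResult(rgb, valid=False, reject_reason="negative_channel")
    if np.any(diff < threshold_frac):
        return SubtractionResult(rgb, valid=False, reject_reason="below_threshold")
    return SubtractionResult(rgb, valid=True)


def aggregate_subject(results: Iterable[SubtractionResult]) -> LinearRGB:
    """Per-channel median over the valid post-subtraction triplets.

    Multiple pairs and multiple ROIs per pair all enter as independent
    triplets.  If every triplet was rejected the subject is unmeasurable
    (this mirrors real screening sessions where no usable pair could be
    captured) and :class:`SubjectUnmeasurableError` is raised.
    """
    valid = [r.flash_only_rgb.as_array() for r in results if r.valid]
    if not valid:
        raise SubjectUnmeasurableError(
            "no valid post-subtraction triplet; subject is unmeasurable"
        )
    med = np.median(np.vstack(valid), axis=0)
    return LinearRGB(*med)
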