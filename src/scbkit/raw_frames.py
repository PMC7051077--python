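"""Raw Bayer-mosaic frame handling: loading, linearization and CFA-direct
ROI statistics.

Frames are single-plane 16-bit mosaics (TIFF or PNG) with a JSON metadata
sidecar.  Processing is deliberately minimal: black-level subtraction and
scaling to the hardware saturation level only -- no demosaicing, white
balance or tone mapping, so values stay in the camera's linear space where
flash/no-flash subtraction is valid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np

__all__ = [
    "BAYER_PATTERNS",
    "RawFrame",
    "ROIMask",
    "LinearRGB",
    "load_raw_frame",
    "save_raw_frame",
    "linearize",
    "extract_roi_rgb",
    "saturation_flag",
    "channel_map",
]

BAYER_PATTERNS = ("RGGB", "BGGR", "GRBG", "GBRG")
FRAME_ROLES = ("flash", "noflash")

SIDECAR_KEYS = (
    "bayer_pattern",
    "black_level",
    "white_level",
    "bit_depth",
    "exposure_time_s",
    "frame_role",
)


class LinearRGB(NamedTuple):
    """Linear camera-space RGB, normalized so 1.0 is hardware saturation.

    Values are non-negative for measured frames; intermediate subtraction
    results may carry negative channels (they are flagged invalid rather
    than clipped).
    """

    r: float
    g: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)

    def scaled(self, k: float) -> "LinearRGB":
        return LinearRGB(self.r * k, self.g * k, self.b * k)


@dataclass
class RawFrame:
    """A single raw capture: CFA mosaic plus the sensor metadata needed to
    linearize it."""

    mosaic: np.ndarray
    bayer_pattern: str
    black_level: int
    white_level: int
    bit_depth: int
    exposure_time: float
    frame_role: str = "flash"

    def __post_init__(self) -> None:
        self.mosaic = np.asarray(self.mosaic)
        if self.mosaic.ndim != 2:
            raise ValueError("mosaic must be a 2-D array")
        h, w = self.mosaic.shape
        if h % 2 or w % 2:
            raise ValueError(f"mosaic dimensions must be even (full Bayer quads), got {h}x{w}")
        if self.bayer_pattern not in BAYER_PATTERNS:
            raise ValueError(f"unknown Bayer pattern {self.bayer_pattern!r}")
        if self.frame_role not in FRAME_ROLES:
            raise ValueError(f"frame_role must be one of {FRAME_ROLES}")
        max_dn = 2**self.bit_depth - 1
        if self.mosaic.min() < 0 or self.mosaic.max() > max_dn:
            raise ValueError(
                f"mosaic values must lie in [0, {max_dn}] for {self.bit_depth}-bit data"
            )
        if not (0 <= self.black_level < self.white_level <= max_dn):
            raise ValueError("require 0 <= black_level < white_level <= 2^bit_depth - 1")
        if self.exposure_time <= 0:
            raise ValueError("exposure_time must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mosaic.shape


@dataclass(frozen=True)
class ROIMask:
    """A set of (row, col) mosaic coordinates, 0-based.

    Coordinates address raw CFA sites (no demosaic), so a mask generally
    mixes R, G and B samples; :func:`extract_roi_rgb` sorts them by Bayer
    site.  Duplicate coordinates collapse (set semantics).
    """

    pixel_set: frozenset
    label: str = ""

    def __post_init__(self) -> None:
        px = frozenset((int(r), int(c)) for r, c in self.pixel_set)
        object.__setattr__(self, "pixel_set", px)
        if not px:
            raise ValueError("ROI mask must be non-empty")

    @classmethod
    def from_coords(cls, coords: Iterable, label: str = "") -> "ROIMask":
        return cls(pixel_set=frozenset((int(r), int(c)) for r, c in coords), label=label)

    @classmethod
    def from_json(cls, path: str | Path, label: str | None = None) -> "ROIMask":
        """Load a mask stored as a JSON list of [row, col] pairs."""
        p = Path(path)
        coords = json.loads(p.read_text())
        return cls.from_coords(coords, label=label if label is not None else p.stem)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(sorted(map(list, self.pixel_set))))

    def check_bounds(self, frame: RawFrame) -> None:
        h, w = frame.shape
        for r, c in self.pixel_set:
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"ROI coordinate ({r}, {c}) outside {h}x{w} frame")

    def __len__(self) -> int:
        return len(self.pixel_set)


def channel_map(pattern: str) -> dict[tuple[int, int], str]:
    """Map (row parity, col parity) -> channel letter for a Bayer pattern."""
    if pattern not in BAYER_PATTERNS:
        raise ValueError(f"unknown Bayer pattern {pattern!r}")
    letters = pattern  # e.g. "RGGB" reads row-major over the 2x2 quad
    return {
        (0, 0): letters[0],
        (0, 1): letters[1],
        (1, 0): letters[2],
        (1, 1): letters[3],
    }


def _read_mosaic(image_path: Path) -> np.ndarray:
    suffix = image_path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(image_path)
    elif suffix == ".png":
        import imageio.v3 as iio

        arr = iio.imread(image_path)
    else:
        raise ValueError(f"unsupported image format {suffix!r} (use TIFF or PNG)")
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError("raw mosaic must be a single-plane (grayscale) image")
    return arr


def load_raw_frame(image_path: str | Path, sidecar_path: str | Path) -> RawFrame:
    """Load a mosaic image and its JSON metadata sidecar into a RawFrame.

    The sidecar must declare every metadata field; missing keys are an
    error rather than a default, because silent defaults (wrong black
    level, wrong Bayer phase) corrupt colour downstream.
    """
    meta = json.loads(Path(sidecar_path).read_text())
    missing = [k for k in SIDECAR_KEYS if k not in meta]
    if missing:
        raise ValueError(f"sidecar {sidecar_path} missing metadata fields: {missing}")
    mosaic = _read_mosaic(Path(image_path))
    return RawFrame(
        mosaic=mosaic,
        bayer_pattern=str(meta["bayer_pattern"]),
        black_level=int(meta["black_level"]),
        white_level=int(meta["white_level"]),
        bit_depth=int(meta["bit_depth"]),
        exposure_time=float(meta["exposure_time_s"]),
        frame_role=str(meta["frame_role"]),
    )


def save_raw_frame(frame: RawFrame, image_path: str | Path, sidecar_path: str | Path) -> None:
    """Write a RawFrame as a 16-bit image plus JSON sidecar (inverse of
    :func:`load_raw_frame`)."""
    image_path = Path(image_path)
    mosaic = frame.mosaic.astype(np.uint16)
    suffix = image_path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(image_path, mosaic)
    elif suffix == ".png":
        import imageio.v3 as iio

        iio.imwrite(image_path, mosaic)
    else:
        raise ValueError(f"unsupported image format {suffix!r} (use TIFF or PNG)")
    meta = {
        "bayer_pattern": frame.bayer_pattern,
        "black_level": int(frame.black_level),
        "white_level": int(frame.white_level),
        "bit_depth": int(frame.bit_depth),
        "exposure_time_s": float(frame.exposure_time),
        "frame_role": frame.frame_role,
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=1))


def linearize(frame: RawFrame) -> np.ndarray:
    """Black-subtract and normalize the mosaic to [0, 1].

    ``out = clip(DN - black, 0) / (white - black)``; black maps to 0,
    hardware saturation to 1.  DNs below black are sensor noise and clip
    to 0 to keep the signal in the linear range the subtraction assumes.
    """
    dn = frame.mosaic.astype(float)
    scale = float(frame.white_level - frame.black_level)
    return np.clip(dn - frame.black_level, 0.0, None) / scale


def _roi_site_values(frame: RawFrame, roi: ROIMask) -> dict[str, np.ndarray]:
    roi.check_bounds(frame)
    cmap = channel_map(frame.bayer_pattern)
    lin = linearize(frame)
    buckets: dict[str, list[float]] = {"R": [], "G": [], "B": []}
    for r, c in roi.pixel_set:
        buckets[cmap[(r % 2, c % 2)]].append(lin[r, c])
    return {k: np.asarray(v) for k, v in buckets.items()}


def extract_roi_rgb(frame: RawFrame, roi: ROIMask) -> LinearRGB:
    """Median linear RGB over an ROI, taken directly from CFA sites.

    Each channel's median is computed over the linearized samples whose
    Bayer site matches that channel; the two green sites of the quad are
    pooled into one sample set.  The median makes the estimate robust to
    stray eyelash/vessel pixels inside a sclera ROI.
    """
    sites = _roi_site_values(frame, roi)
    empty = [k for k in ("R", "G", "B") if sites[k].size == 0]
    if empty:
        raise ValueError(f"ROI contains no samples for channel(s): {', '.join(empty)}")
    return LinearRGB(
        float(np.median(sites["R"])),
        float(np.median(sites["G"])),
        float(np.median(sites["B"])),
    )


def saturation_flag(frame: RawFrame, roi: ROIMask) -> bool:
    """True iff any ROI sample reached the hardware saturation level.

    Saturated regions break the linearity that ambient subtraction relies
    on, so a flagged pair must be discarded.
    """
    roi.check_bounds(frame)
    rows, cols = zip(*roi.pixel_set)
    return bool(np.any(frame.mosaic[list(rows), list(cols)] >= frame.white_level))
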