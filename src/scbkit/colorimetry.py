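"""CIE 1931 colorimetry: spectra, standard-observer integration, device
characterization and the Jaundice Eye Colour Index (JECI).

The pipeline works in two colour spaces.  Camera-space linear RGB triplets
(black-subtracted, saturation-normalized) are mapped to CIE XYZ through a
3x3 matrix characterized for the screen illuminant.  XYZ is then reduced to
chromaticity ``(x, y, z) = (X, Y, Z) / (X + Y + Z)``, which is invariant to
any scalar on the signal (exposure, screen radiance, phone--eye distance).
JECI measures yellowness as the chromaticity-z deficit relative to the D65
white point: ``JECI = z_D65 - z``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "TristimulusXYZ",
    "Chromaticity",
    "CharacterizationMatrix",
    "D65_CHROMATICITY",
    "D65_Z",
    "default_grid",
    "standard_observer",
    "spectrum_to_xyz",
    "fit_characterization",
    "rgb_to_xyz",
    "xyz_to_chromaticity",
    "jeci",
]

# CIE D65 white-point chromaticity (CIE 15). z_D65 defines the JECI zero.
D65_X = 0.31272
D65_Y = 0.32903
D65_Z = 1.0 - D65_X - D65_Y

CMF_WAVELENGTH_MIN = 380.0
CMF_WAVELENGTH_MAX = 780.0


def default_grid(step: float = 5.0) -> np.ndarray:
    """Uniform wavelength grid in nm covering the visible range 380-780."""
    return np.arange(CMF_WAVELENGTH_MIN, CMF_WAVELENGTH_MAX + step / 2, step)


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectral function on a strictly increasing nm grid.

    Used for illuminant power distributions E(lambda) (relative units),
    surface reflectances S(lambda) (dimensionless, in [0, 1]) and camera
    sensitivities Q_k(lambda) (relative units).  Values must be
    non-negative; reflectance bounds are enforced by the callers that
    construct reflectances.
    """

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)
        if wl.ndim != 1 or v.shape != wl.shape:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2 or not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("spectral values must be finite and non-negative")

    def scaled(self, k: float) -> "Spectrum":
        return Spectrum(self.wavelengths, self.values * float(k))

    def same_grid(self, other: "Spectrum") -> bool:
        return self.wavelengths.shape == other.wavelengths.shape and np.allclose(
            self.wavelengths, other.wavelengths
        )


class TristimulusXYZ(NamedTuple):
    """CIE XYZ tristimulus values on a relative (unnormalized) scale."""

    X: float
    Y: float
    Z: float

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


@dataclass(frozen=True)
class Chromaticity:
    """Normalized CIE xyz chromaticity; coordinates sum to one."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        s = self.x + self.y + self.z
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"chromaticity coordinates must sum to 1, got {s!r}")
        if not (0 <= self.x <= 1 and 0 <= self.y <= 1 and 0 <= self.z <= 1):
            raise ValueError("chromaticity coordinates must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    def xy_distance(self, other: "Chromaticity") -> float:
        """Euclidean distance in the (x, y) plane."""
        return float(np.hypot(self.x - other.x, self.y - other.y))


D65_CHROMATICITY = Chromaticity(D65_X, D65_Y, D65_Z)


# ---------------------------------------------------------------------------
# CIE 1931 2-degree colour-matching functions
# ---------------------------------------------------------------------------

# Piecewise-Gaussian analytic fit of the CIE 1931 2-degree standard observer
# (Wyman, Sloan & Shirley, JCGT 2013).  Each lobe has separate left/right
# widths; coefficients reproduce the tabulated observer to within ~1% which
# translates to < 0.01 chromaticity error for smooth spectra.
_XBAR_LOBES = ((1.056, 599.8, 37.9, 31.0), (0.362, 442.0, 16.0, 26.7), (-0.065, 501.1, 20.4, 26.2))
_YBAR_LOBES = ((0.821, 568.8, 46.9, 40.5), (0.286, 530.9, 16.3, 31.1))
_ZBAR_LOBES = ((1.217, 437.0, 11.8, 36.0), (0.681, 459.0, 26.0, 13.8))


def _piecewise_gauss(wl: np.ndarray, mu: float, s_left: float, s_right: float) -> np.ndarray:
    sigma = np.where(wl < mu, s_left, s_right)
    t = (wl - mu) / sigma
    return np.exp(-0.5 * t * t)


def _cmf(wl: np.ndarray, lobes) -> np.ndarray:
    out = np.zeros_like(wl, dtype=float)
    for a, mu, s1, s2 in lobes:
        out += a * _piecewise_gauss(wl, mu, s1, s2)
    # The xbar fit has a small negative lobe; clip so sensitivities stay
    # physical (the residual is < 2e-3 near 500 nm).
    return np.clip(out, 0.0, None)


def standard_observer(grid: Sequence[float] | np.ndarray | None = None):
    """Colour-matching functions (xbar, ybar, zbar) sampled on ``grid``.

    Parameters
    ----------
    grid
        Wavelengths in nm, within [380, 780].  Defaults to a 5 nm grid.

    Returns
    -------
    tuple of three :class:`Spectrum`, the x, y and z matching functions.
    """
    wl = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if wl.min() < CMF_WAVELENGTH_MIN - 1e-9 or wl.max() > CMF_WAVELENGTH_MAX + 1e-9:
        raise ValueError("grid must lie within 380-780 nm")
    return (
        Spectrum(wl, _cmf(wl, _XBAR_LOBES)),
        Spectrum(wl, _cmf(wl, _YBAR_LOBES)),
        Spectrum(wl, _cmf(wl, _ZBAR_LOBES)),
    )


def spectrum_to_xyz(
    illuminant: Spectrum,
    reflectance: Spectrum,
    cmfs: tuple[Spectrum, Spectrum, Spectrum] | None = None,
) -> TristimulusXYZ:
    """Integrate E(lambda) * S(lambda) against the observer functions.

    Trapezoidal integration on the common grid; the result is on a relative
    scale (no normalization to Y = 100), which is all chromaticity needs.
    """
    if not illuminant.same_grid(reflectance):
        raise ValueError("illuminant and reflectance must share a wavelength grid")
    if cmfs is None:
        cmfs = standard_observer(illuminant.wavelengths)
    signal = illuminant.values * reflectance.values
    out = []
    for cmf in cmfs:
        if not cmf.same_grid(illuminant):
            raise ValueError("colour-matching functions must share the spectrum grid")
        out.append(float(np.trapezoid(signal * cmf.values, illuminant.wavelengths)))
    return TristimulusXYZ(*out)


# ---------------------------------------------------------------------------
# Device characterization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CharacterizationMatrix:
    """3x3 linear map from camera linear RGB to CIE XYZ.

    The matrix is optimal only for scenes lit by the illuminant it was
    trained under (tagged in ``illuminant_tag``); after ambient subtraction
    the effective illuminant is always the screen, so a one-time screen
    characterization suffices.
    """

    M: np.ndarray
    illuminant_tag: str = "unspecified"
    residual_rms: float = 0.0
    per_sample_residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        object.__setattr__(self, "M", M)
        if M.shape != (3, 3) or not np.all(np.isfinite(M)):
            raise ValueError("characterization matrix must be a finite 3x3 matrix")

    def to_dict(self) -> dict:
        return {
            "matrix": self.M.tolist(),
            "illuminant_tag": self.illuminant_tag,
            "residual_rms": self.residual_rms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CharacterizationMatrix":
        return cls(
            M=np.asarray(d["matrix"], dtype=float),
            illuminant_tag=d.get("illuminant_tag", "unspecified"),
            residual_rms=float(d.get("residual_rms", 0.0)),
        )


def fit_characterization(
    training_rgb: Sequence,
    training_xyz: Sequence,
    illuminant_tag: str = "unspecified",
) -> CharacterizationMatrix:
    """Least-squares 3x3 RGB->XYZ transform from training pairs.

    Minimizes ``sum ||M rgb_i - xyz_i||^2`` (unweighted, in XYZ space).
    Requires at least three linearly independent RGB samples.
    """
    R = np.asarray([np.asarray(r, dtype=float) for r in training_rgb])
    X = np.asarray([np.asarray(x, dtype=float) for x in training_xyz])
    if R.shape != X.shape or R.ndim != 2 or R.shape[1] != 3:
        raise ValueError("training RGB and XYZ must be matching (n, 3) arrays")
    if R.shape[0] < 3 or np.linalg.matrix_rank(R) < 3:
        raise ValueError("need >= 3 linearly independent training samples")
    # Solve R @ M.T = X  (row-wise least squares).
    Mt, *_ = np.linalg.lstsq(R, X, rcond=None)
    M = Mt.T
    resid = R @ Mt - X
    per_sample = np.linalg.norm(resid, axis=1)
    rms = float(np.sqrt(np.mean(resid**2)))
    return CharacterizationMatrix(
        M=M,
        illuminant_tag=illuminant_tag,
        residual_rms=rms,
        per_sample_residuals=per_sample,
    )


def rgb_to_xyz(rgb, M: CharacterizationMatrix) -> TristimulusXYZ:
    """Apply the characterization matrix; negative XYZ is clipped to zero.

    Clipping is flagged with a :class:`UserWarning` because it indicates the
    input colour lies outside the gamut the matrix was trained on.
    """
    v = np.asarray(rgb, dtype=float)
    if v.shape != (3,) or not np.all(np.isfinite(v)):
        raise ValueError("rgb must be a finite 3-vector")
    xyz = M.M @ v
    if np.any(xyz < 0):
        warnings.warn("negative tristimulus values clipped to zero", stacklevel=2)
        xyz = np.clip(xyz, 0.0, None)
    return TristimulusXYZ(*xyz)


def xyz_to_chromaticity(xyz: TristimulusXYZ) -> Chromaticity:
    """Normalize XYZ by its sum (homogeneous -> intensity-independent)."""
    total = xyz.X + xyz.Y + xyz.Z
    if total <= 0:
        raise ValueError("cannot normalize non-positive tristimulus sum")
    # Renormalize explicitly so the sum-to-one invariant holds to machine
    # precision even after float division.
    x = xyz.X / total
    y = xyz.Y / total
    return Chromaticity(x, y, 1.0 - x - y)


def jeci(chrom: Chromaticity) -> float:
    """Jaundice Eye Colour Index: ``z_D65 - z``.

    Zero for a D65-chromaticity (neutral) surface, positive for yellow
    (blue-depleted) surfaces, strictly decreasing in z.
    """
    return D65_Z - chrom.z
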