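"""Spectral image-formation simulator: ground-truthed flash/no-flash pairs.

Renders the full physical chain the screening method assumes:

    signal_k = a * gain * exposure * integral E(lambda) S(lambda) Q_k(lambda) dlambda

with scene reflectances S (bilirubin-dependent sclera, yellowness-chart
patches), illuminants E (warm/cool/fluorescent ambient plus the phone
screen), Gaussian camera sensitivities Q_k, Bayer mosaicing, shot and read
noise, black level and integer quantization.  Because illuminant
contributions add linearly pre-noise, a rendered (ambient + screen) frame
minus a rendered (ambient) frame equals the screen-only rendering -- the
physical premise the flash/no-flash subtraction relies on -- which makes
every stage of the analysis pipeline testable against exact ground truth.

Bilirubin optics are modelled as a single Gaussian absorption band centred
at 460 nm under Beer-Lambert attenuation: bilirubin absorbs blue light,
which is why jaundiced sclerae look yellow.  The band parameters are
configurable; only the monotone TSB -> yellowness link matters for testing
the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .colorimetry import (
    Chromaticity,
    D65_X,
    D65_Y,
    Spectrum,
    default_grid,
    jeci,
    spectrum_to_xyz,
    standard_observer,
    xyz_to_chromaticity,
)
from .raw_frames import LinearRGB, RawFrame, channel_map

__all__ = [
    "CameraModel",
    "IlluminantPreset",
    "ScleraModel",
    "SimulatedPair",
    "CohortResult",
    "blackbody_spd",
    "gaussian_spectrum",
    "d65_like_illuminant",
    "illuminant_preset",
    "default_camera",
    "luther_camera",
    "calibrate_gain",
    "scale_preset_to_signal",
    "sclera_reflectance",
    "render_patch",
    "mosaic_and_quantize",
    "make_flash_pair",
    "make_jeci_chart",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# Spectra building blocks
# ---------------------------------------------------------------------------


def gaussian_spectrum(grid: np.ndarray, center: float, sd: float, peak: float = 1.0) -> np.ndarray:
    t = (np.asarray(grid, dtype=float) - center) / sd
    return peak * np.exp(-0.5 * t * t)


def blackbody_spd(temperature_k: float, grid: Optional[np.ndarray] = None) -> Spectrum:
    """Planck blackbody spectral power, normalized to 1 at 560 nm."""
    wl = default_grid() if grid is None else np.asarray(grid, dtype=float)
    c2 = 1.4388e7  # nm K, second radiation constant

    def planck(lam):
        return lam**-5 / np.expm1(c2 / (lam * temperature_k))

    return Spectrum(wl, planck(wl) / planck(np.array([560.0]))[0])


_D65_LIKE_CACHE: dict[bytes, Spectrum] = {}


def d65_like_illuminant(grid: Optional[np.ndarray] = None) -> Spectrum:
    """A smooth daylight-like (~6500 K) illuminant whose chromaticity under
    the analytic standard observer equals the D65 white point exactly.

    Built from a 6500 K blackbody multiplied by a two-parameter log-
    polynomial tilt, with the parameters solved so the illuminant's (x, y)
    lands on (0.31272, 0.32903).  Pinning the white point exactly makes
    yellowness-chart targets of JECI = 0 attainable by construction.
    """
    wl = default_grid() if grid is None else np.asarray(grid, dtype=float)
    key = wl.tobytes()
    if key in _D65_LIKE_CACHE:
        return _D65_LIKE_CACHE[key]
    base = blackbody_spd(6500.0, wl)
    cmfs = standard_observer(wl)
    u = (wl - 560.0) / 100.0
    ones = Spectrum(wl, np.ones_like(wl))

    def residual(c):
        spd = Spectrum(wl, base.values * np.exp(c[0] * u + c[1] * u * u))
        ch = xyz_to_chromaticity(spectrum_to_xyz(spd, ones, cmfs))
        return [ch.x - D65_X, ch.y - D65_Y]

    sol = optimize.root(residual, x0=[0.0, 0.0], tol=1e-14)
    if not sol.success:
        raise RuntimeError("failed to solve daylight-like illuminant tilt")
    spd = Spectrum(wl, base.values * np.exp(sol.x[0] * u + sol.x[1] * u * u))
    _D65_LIKE_CACHE[key] = spd
    return spd


@dataclass(frozen=True)
class IlluminantPreset:
    """A named illuminant: spectral power distribution plus a radiance
    scale relative to the preset's nominal level."""

    name: str
    spd: Spectrum
    radiance_scale: float = 1.0

    def effective_spd(self) -> Spectrum:
        return self.spd.scaled(self.radiance_scale)

    def rescaled(self, radiance_scale: float) -> "IlluminantPreset":
        return replace(self, radiance_scale=float(radiance_scale))


def _screen_white_spd(grid: np.ndarray) -> Spectrum:
    """Phone-screen white SPD balanced exactly to the D65 white point.

    Modelled as a high-CRI LCD backlight: a broad thermal-like base
    carrying most of the power plus R/G/B filter peaks whose weights are
    solved so the white lands exactly on (0.31272, 0.32903).  The broad
    base keeps metamerism against smooth daylight small, which is what a
    well-behaved screen illuminant should do.
    """
    base = blackbody_spd(6500.0, grid).values
    base = base / base.max()
    primaries = [
        gaussian_spectrum(grid, 610.0, 30.0),
        gaussian_spectrum(grid, 545.0, 45.0),
        gaussian_spectrum(grid, 455.0, 20.0),
    ]
    cmfs = standard_observer(grid)
    ones = Spectrum(grid, np.ones_like(grid))
    target = np.array([D65_X, D65_Y, 1.0 - D65_X - D65_Y])
    base_xyz = np.asarray(spectrum_to_xyz(Spectrum(grid, base), ones, cmfs))
    base_frac = 0.7  # fraction of total Y carried by the broad base
    V = np.column_stack(
        [spectrum_to_xyz(Spectrum(grid, p), ones, cmfs) for p in primaries]
    )
    scale = base_xyz[1] / (target[1] * base_frac)
    w = np.linalg.solve(V, target * scale - base_xyz)
    if np.any(w <= 0):
        raise RuntimeError("screen primary balance produced non-physical weights")
    spd = base + sum(wi * p for wi, p in zip(w, primaries))
    return Spectrum(grid, spd / spd.max())


def _cool_led_spd(grid: np.ndarray) -> Spectrum:
    """Cool-white (~6500 K) LED lamp: narrow blue pump plus a broad
    phosphor hump, with the ratio solved so x matches the D65 x
    coordinate.  Spectrally quite different from real daylight, which is
    exactly why a screen-trained characterization cannot be reused for
    ambient-lit scenes."""
    pump = gaussian_spectrum(grid, 452.0, 11.0)
    phosphor = gaussian_spectrum(grid, 558.0, 62.0)
    cmfs = standard_observer(grid)
    ones = Spectrum(grid, np.ones_like(grid))

    def x_err(ratio: float) -> float:
        spd = Spectrum(grid, pump + ratio * phosphor)
        return xyz_to_chromaticity(spectrum_to_xyz(spd, ones, cmfs)).x - D65_X

    ratio = optimize.brentq(x_err, 0.05, 20.0, xtol=1e-10)
    v = pump + ratio * phosphor
    return Spectrum(grid, v / v.max())


def _fluorescent_spd(grid: np.ndarray) -> Spectrum:
    """Spiky fluorescent approximation: phosphor base plus mercury-like
    emission lines at 436/546/611 nm."""
    base = 0.35 * gaussian_spectrum(grid, 580.0, 70.0)
    lines = (
        0.9 * gaussian_spectrum(grid, 436.0, 6.0)
        + 1.1 * gaussian_spectrum(grid, 546.0, 6.0)
        + 1.0 * gaussian_spectrum(grid, 611.0, 8.0)
    )
    v = base + lines
    return Spectrum(grid, v / v.max())


def illuminant_preset(name: str, grid: Optional[np.ndarray] = None) -> IlluminantPreset:
    """Construct a named illuminant preset on the given wavelength grid.

    Presets: ``warm_led_2700K`` (blackbody), ``cool_led_6500K``
    (blue-pump + phosphor LED), ``fluorescent`` (spiky), ``screen_white``
    (broadband-backed phone screen balanced exactly to D65).
    """
    wl = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if name == "warm_led_2700K":
        return IlluminantPreset(name, blackbody_spd(2700.0, wl))
    if name == "cool_led_6500K":
        return IlluminantPreset(name, _cool_led_spd(wl))
    if name == "fluorescent":
        return IlluminantPreset(name, _fluorescent_spd(wl))
    if name == "screen_white":
        return IlluminantPreset(name, _screen_white_spd(wl))
    raise ValueError(f"unknown illuminant preset {name!r}")


# ---------------------------------------------------------------------------
# Camera
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CameraModel:
    """Sensor model: Gaussian channel sensitivities plus the DN chain.

    ``gain`` converts exposure-weighted spectral integrals to normalized
    signal (1.0 = saturation above black).  Shot noise is Poisson on an
    electron count (``electrons_per_dn`` sets its magnitude); read noise
    is Gaussian in DN.
    """

    sensitivities: tuple[Spectrum, Spectrum, Spectrum]
    gain: float = 1.0
    bit_depth: int = 10
    black_level: int = 64
    white_level: int = 1023
    read_noise_sd: float = 1.0
    shot_noise: bool = True
    electrons_per_dn: float = 10.0

    def __post_init__(self) -> None:
        if self.white_level > 2**self.bit_depth - 1:
            raise ValueError("white_level exceeds bit depth")
        for q in self.sensitivities:
            if np.any(q.values < 0):
                raise ValueError("sensitivities must be non-negative")

    @property
    def grid(self) -> np.ndarray:
        return self.sensitivities[0].wavelengths

    def noiseless(self) -> "CameraModel":
        return replace(self, read_noise_sd=0.0, shot_noise=False)


def default_camera(grid: Optional[np.ndarray] = None, gain: float = 1.0) -> CameraModel:
    """A generic mobile-sensor model: Gaussian R/G/B sensitivities,
    10-bit output, black level 64, saturation at 1023."""
    wl = default_grid() if grid is None else np.asarray(grid, dtype=float)
    return CameraModel(
        sensitivities=(
            Spectrum(wl, gaussian_spectrum(wl, 600.0, 35.0)),
            Spectrum(wl, gaussian_spectrum(wl, 540.0, 35.0)),
            Spectrum(wl, gaussian_spectrum(wl, 465.0, 30.0)),
        ),
        gain=gain,
    )


def luther_camera(grid: Optional[np.ndarray] = None, gain: float = 1.0) -> CameraModel:
    """A camera whose sensitivities are exactly the standard-observer
    matching functions, so an error-free linear RGB->XYZ map exists."""
    wl = default_grid() if grid is None else np.asarray(grid, dtype=float)
    xbar, ybar, zbar = standard_observer(wl)
    return CameraModel(sensitivities=(xbar, ybar, zbar), gain=gain)


# ---------------------------------------------------------------------------
# Scene
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScleraModel:
    """Bilirubin-dependent sclera reflectance.

    ``S(lambda) = S0(lambda) * 10^(-eps(lambda) * tsb)`` with ``eps`` a
    Gaussian absorption band (peak optical density ``extinction_scale``
    per umol/L).  Defaults give a peak optical density of 0.5 at
    TSB = 500 umol/L -- a strong but unsaturated yellowing.
    """

    baseline_reflectance: Optional[Spectrum] = None
    bilirubin_band_center: float = 460.0
    bilirubin_band_width: float = 35.0
    extinction_scale: float = 1e-3
    baseline_level: float = 0.85
    blue_tint: float = 0.0

    def baseline(self, grid: Optional[np.ndarray] = None) -> Spectrum:
        if self.baseline_reflectance is not None:
            return self.baseline_reflectance
        wl = default_grid() if grid is None else np.asarray(grid, dtype=float)
        # optional mild blue tint: neonatal sclerae can be thin enough to
        # show a bluish cast
        v = self.baseline_level * (1.0 + self.blue_tint * (560.0 - wl) / 200.0)
        v = np.clip(v, 0.0, 1.0)
        return Spectrum(wl, v)


def sclera_reflectance(
    model: ScleraModel, tsb: float, grid: Optional[np.ndarray] = None
) -> Spectrum:
    """Reflectance of a sclera at the given TSB (umol/L).

    Higher TSB attenuates the blue band more, lowering chromaticity z and
    raising JECI monotonically.
    """
    if tsb < 0:
        raise ValueError("TSB must be non-negative")
    s0 = model.baseline(grid)
    wl = s0.wavelengths
    eps = model.extinction_scale * gaussian_spectrum(
        wl, model.bilirubin_band_center, model.bilirubin_band_width
    )
    values = s0.values * 10.0 ** (-eps * tsb)
    if np.any(values > 1.0):
        raise ValueError("reflectance exceeds 1; check baseline parameters")
    return Spectrum(wl, values)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render_patch(
    reflectance: Spectrum,
    illuminants: Sequence[IlluminantPreset],
    camera: CameraModel,
    exposure: float,
    geometry_a: float = 1.0,
) -> LinearRGB:
    """Expected (pre-noise) normalized linear RGB of a uniform patch.

    Per channel: ``a * gain * t * integral (sum_i E_i) S Q_k``.  Values
    above 1.0 indicate saturation; they are reported as-is here and only
    clipped during mosaicing, so callers can detect clipping.
    """
    if exposure <= 0 or geometry_a < 0:
        raise ValueError("exposure must be positive and geometry non-negative")
    wl = reflectance.wavelengths
    e_total = np.zeros_like(wl)
    for ill in illuminants:
        spd = ill.effective_spd()
        if not spd.same_grid(reflectance):
            raise ValueError("illuminant and reflectance grids differ")
        e_total = e_total + spd.values
    out = []
    for q in camera.sensitivities:
        if not q.same_grid(reflectance):
            raise ValueError("camera sensitivity grid differs from scene grid")
        integral = np.trapezoid(e_total * reflectance.values * q.values, wl)
        out.append(geometry_a * camera.gain * exposure * integral)
    return LinearRGB(*out)


def calibrate_gain(
    camera: CameraModel,
    screen: IlluminantPreset,
    exposure: float,
    target: float = 0.45,
) -> CameraModel:
    """Set the camera gain so a perfect white patch under the screen alone
    reaches ``target`` on its brightest channel."""
    wl = camera.grid
    white = Spectrum(wl, np.ones_like(wl))
    ref = render_patch(white, [screen], replace(camera, gain=1.0), exposure)
    return replace(camera, gain=target / max(ref))


def scale_preset_to_signal(
    preset: IlluminantPreset,
    camera: CameraModel,
    exposure: float,
    target: float,
) -> IlluminantPreset:
    """Rescale a preset's radiance so a white patch renders with its
    brightest channel at ``target`` (used to set ambient/screen ratios)."""
    wl = camera.grid
    white = Spectrum(wl, np.ones_like(wl))
    ref = render_patch(white, [preset.rescaled(1.0)], camera, exposure)
    return preset.rescaled(target / max(ref))


def mosaic_and_quantize(
    expected_rgb,
    camera: CameraModel,
    shape: tuple[int, int] = (8, 8),
    seed: int | np.random.Generator = 0,
    exposure: float = 1 / 30,
    frame_role: str = "flash",
    bayer_pattern: str = "RGGB",
) -> RawFrame:
    """Sample a Bayer mosaic from expected per-pixel RGB and digitize it.

    ``expected_rgb`` is either a single LinearRGB (uniform patch) or an
    (H, W, 3) array of normalized expected values.  Noise (optional
    Poisson shot + Gaussian read), black level, clipping to the hardware
    saturation level and integer rounding follow; deterministic for a
    fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(expected_rgb, LinearRGB) or (
        np.ndim(expected_rgb) == 1 and len(expected_rgb) == 3
    ):
        field_rgb = np.broadcast_to(
            np.asarray(expected_rgb, dtype=float), shape + (3,)
        )
    else:
        field_rgb = np.asarray(expected_rgb, dtype=float)
        shape = field_rgb.shape[:2]
    if np.any(field_rgb < 0):
        raise ValueError("expected values must be non-negative")
    h, w = shape
    cmap = channel_map(bayer_pattern)
    chan_index = {"R": 0, "G": 1, "B": 2}
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    site = np.empty((h, w), dtype=int)
    for (rp, cp), letter in cmap.items():
        mask = (rows % 2 == rp) & (cols % 2 == cp)
        site[mask] = chan_index[letter]
    values = np.take_along_axis(field_rgb, site[..., None], axis=2)[..., 0]
    span = camera.white_level - camera.black_level
    signal_dn = values * span
    if camera.shot_noise:
        electrons = rng.poisson(signal_dn * camera.electrons_per_dn)
        signal_dn = electrons / camera.electrons_per_dn
    if camera.read_noise_sd > 0:
        signal_dn = signal_dn + rng.normal(0.0, camera.read_noise_sd, size=signal_dn.shape)
    dn = np.rint(camera.black_level + signal_dn)
    dn = np.clip(dn, 0, camera.white_level).astype(np.uint16)
    return RawFrame(
        mosaic=dn,
        bayer_pattern=bayer_pattern,
        black_level=camera.black_level,
        white_level=camera.white_level,
        bit_depth=camera.bit_depth,
        exposure_time=exposure,
        frame_role=frame_role,
    )


@dataclass(frozen=True)
class SimulatedPair:
    """A rendered flash/no-flash pair with its ground truth."""

    flash_frame: RawFrame
    noflash_frame: RawFrame
    truth_chromaticity_flash_only: Chromaticity
    truth_tsb: Optional[float] = None
    seed: int = 0


def screen_only_chromaticity(
    reflectance: Spectrum, screen: IlluminantPreset
) -> Chromaticity:
    """Ground-truth chromaticity of a surface under the screen alone."""
    cmfs = standard_observer(reflectance.wavelengths)
    return xyz_to_chromaticity(spectrum_to_xyz(screen.effective_spd(), reflectance, cmfs))


def make_flash_pair(
    reflectance: Spectrum,
    ambient: IlluminantPreset,
    screen: IlluminantPreset,
    camera: CameraModel,
    exposure: float = 1 / 30,
    geometry_a: float = 1.0,
    seed: int = 0,
    shape: tuple[int, int] = (8, 8),
    truth_tsb: Optional[float] = None,
    exposure_noflash: Optional[float] = None,
) -> SimulatedPair:
    """Render a flash (ambient + screen) and no-flash (ambient only) pair
    of the same static uniform patch, with exact ground truth.

    The truth chromaticity is that of the patch under the screen alone,
    which is what ambient subtraction plus the screen-trained
    characterization is meant to recover.
    """
    t_nf = exposure if exposure_noflash is None else exposure_noflash
    rng = np.random.default_rng(seed)
    flash_rgb = render_patch(reflectance, [ambient, screen], camera, exposure, geometry_a)
    noflash_rgb = render_patch(reflectance, [ambient], camera, t_nf, geometry_a)
    flash = mosaic_and_quantize(
        flash_rgb, camera, shape=shape, seed=rng, exposure=exposure, frame_role="flash"
    )
    noflash = mosaic_and_quantize(
        noflash_rgb, camera, shape=shape, seed=rng, exposure=t_nf, frame_role="noflash"
    )
    return SimulatedPair(
        flash_frame=flash,
        noflash_frame=noflash,
        truth_chromaticity_flash_only=screen_only_chromaticity(reflectance, screen),
        truth_tsb=truth_tsb,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Yellowness chart
# ---------------------------------------------------------------------------


def make_jeci_chart(
    targets: Sequence[float],
    grid: Optional[np.ndarray] = None,
    luminance: float = 0.92,
) -> list[tuple[Spectrum, Chromaticity]]:
    """Synthetic yellowness test chart: one patch per target JECI value.

    Each patch is a flat white of reflectance ``luminance`` attenuated by
    a Gaussian blue absorption band whose strength is root-found so the
    patch's chromaticity under the daylight-like (exact-D65) illuminant
    has exactly the target JECI.  Target 0 is the plain white patch.
    """
    wl = default_grid() if grid is None else np.asarray(grid, dtype=float)
    illum = d65_like_illuminant(wl)
    cmfs = standard_observer(wl)
    band = gaussian_spectrum(wl, 460.0, 35.0)

    def patch(strength: float) -> Spectrum:
        return Spectrum(wl, luminance * 10.0 ** (-strength * band))

    def achieved(strength: float) -> float:
        return jeci(xyz_to_chromaticity(spectrum_to_xyz(illum, patch(strength), cmfs)))

    out = []
    j_max = achieved(5.0)
    for target in targets:
        if target < 0 or target > min(0.12, j_max):
            raise ValueError(f"JECI target {target} unattainable for this chart model")
        if target == 0:
            strength = 0.0
        else:
            strength = optimize.brentq(
                lambda c: achieved(c) - target, 0.0, 5.0, xtol=1e-12
            )
        refl = patch(strength)
        truth = xyz_to_chromaticity(spectrum_to_xyz(illum, refl, cmfs))
        out.append((refl, truth))
    return out


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

NOISE_LEVELS = {
    # (read_noise_sd DN, electrons_per_dn, shot_noise)
    "none": (0.0, 10.0, False),
    "low": (0.2, 100.0, True),
    "default": (1.0, 10.0, True),
}


@dataclass
class CohortResult:
    """A simulated study cohort: subject truth table plus rendered pairs."""

    subjects: pd.DataFrame
    pairs: dict[str, list[SimulatedPair]]
    camera: CameraModel
    screen: IlluminantPreset
    seed: int


def simulate_cohort(
    n: int,
    seed: int = 0,
    grid: Optional[np.ndarray] = None,
    noise: str = "default",
    ambient_names: Sequence[str] = ("warm_led_2700K", "cool_led_6500K", "fluorescent"),
    tsb_median: float = 180.0,
    tsb_log_sigma: float = 0.5,
    tsb_range: tuple[float, float] = (30.0, 500.0),
    pairs_per_subject: tuple[int, int] = (1, 3),
    ambient_signal_range: tuple[float, float] = (0.05, 0.35),
    screen_signal: float = 0.45,
    exposure: float = 1 / 30,
    shape: tuple[int, int] = (8, 8),
    biological_sigma: float = 0.12,
) -> CohortResult:
    """Simulate a screening-study cohort of ``n`` subjects.

    TSB is drawn lognormally (median ~180 umol/L, clipped to 30-500),
    matching the skewed severity distribution of a neonatal unit.  Each
    subject gets a random ambient (warm LED / cool LED / fluorescent, at
    a random intensity relative to the screen) and 1-3 flash/no-flash
    pairs, with the screen-at-eye radiance and shading varying per pair
    the way phone-to-eye distance varies between captures.  Biological
    scatter (per-subject bilirubin-deposition efficiency and a mild
    baseline tint) decouples sclera colour from TSB the way real subjects
    differ, so recovered correlations are high but not unity.

    Returns per-subject ground truth (TSB, screen-only chromaticity,
    JECI) alongside the rendered frames; everything is deterministic for
    a fixed seed.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if noise not in NOISE_LEVELS:
        raise ValueError(f"noise must be one of {sorted(NOISE_LEVELS)}")
    wl = default_grid() if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    read_sd, epd, shot = NOISE_LEVELS[noise]

    screen = illuminant_preset("screen_white", wl)
    camera = replace(
        default_camera(wl), read_noise_sd=read_sd, electrons_per_dn=epd, shot_noise=shot
    )
    camera = calibrate_gain(camera, screen, exposure, target=screen_signal)
    screen = scale_preset_to_signal(screen, camera, exposure, screen_signal)
    ambient_pool = [
        scale_preset_to_signal(illuminant_preset(name, wl), camera, exposure, 1.0)
        for name in ambient_names
    ]

    rows = []
    pairs: dict[str, list[SimulatedPair]] = {}
    for i in range(n):
        subject_id = f"sim{i:04d}"
        tsb = float(
            np.clip(
                np.exp(np.log(tsb_median) + tsb_log_sigma * rng.standard_normal()),
                *tsb_range,
            )
        )
        # biological scatter: deposition efficiency and baseline tint
        deposition = float(np.exp(biological_sigma * rng.standard_normal()))
        tint = float(rng.uniform(-0.01, 0.03))
        sclera = ScleraModel(blue_tint=tint)
        refl = sclera_reflectance(sclera, tsb * deposition, wl)

        ambient_idx = int(rng.integers(len(ambient_pool)))
        ambient_level = float(rng.uniform(*ambient_signal_range))
        ambient = ambient_pool[ambient_idx].rescaled(ambient_level)

        n_pairs = int(rng.integers(pairs_per_subject[0], pairs_per_subject[1] + 1))
        subject_pairs = []
        for _ in range(n_pairs):
            # phone-eye distance varies between captures: it scales the
            # screen radiance at the eye but not the ambient
            distance_scale = float(rng.uniform(0.6, 1.0))
            geometry = float(rng.uniform(0.85, 1.15))
            pair_seed = int(rng.integers(2**31 - 1))
            subject_pairs.append(
                make_flash_pair(
                    refl,
                    ambient,
                    screen.rescaled(screen.radiance_scale * distance_scale),
                    camera,
                    exposure=exposure,
                    geometry_a=geometry,
                    seed=pair_seed,
                    shape=shape,
                    truth_tsb=tsb,
                )
            )
        pairs[subject_id] = subject_pairs
        truth = screen_only_chromaticity(refl, screen)
        rows.append(
            {
                "subject_id": subject_id,
                "tsb_umol_per_L": tsb,
                "truth_x": truth.x,
                "truth_y": truth.y,
                "truth_z": truth.z,
                "truth_jeci": jeci(truth),
                "ambient": ambient.name,
                "ambient_signal": ambient_level,
                "n_pairs": n_pairs,
            }
        )
    return CohortResult(
        subjects=pd.DataFrame(rows), pairs=pairs, camera=camera, screen=screen, seed=seed
    )
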