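"""Seed-deterministic synthetic hand hypercubes with known vein masks.

The generator emulates the statistical structure a vein-segmentation pipeline
assumes in reflectance imagery of the back of a hand over 400-1000 nm: two
spectral classes (skin and vein, the vein darker across the visible range and
showing an extra near-infrared absorption dip), spatially coherent vessel
geometry, a smooth multiplicative illumination field, and additive detector
noise.  Every output is a pure function of its :class:`SyntheticConfig`,
including the seed.

Spectra are piecewise-analytic: a linear baseline plus Gaussian bumps/dips,
clipped to [0, 1].  Vessels are cubic-smoothed random walks spanning the
image, dilated to the configured width.  None of this models tissue optics;
it reproduces the class separability and nuisance structure the classifier
has to cope with, not radiometric truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import binary_dilation

from .envi import Hypercube

__all__ = [
    "SpectralProfile",
    "SyntheticConfig",
    "default_skin_profile",
    "default_vein_profile",
    "eval_profile",
    "make_vein_mask",
    "render_cube",
    "generate_image",
    "generate_dataset",
]


@dataclass(frozen=True)
class SpectralProfile:
    """Analytic reflectance profile: linear baseline plus Gaussian terms.

    ``intercept`` is the reflectance at 400 nm, ``slope`` the change per nm;
    each Gaussian is ``(center_nm, width_nm, amplitude)`` added to the
    baseline.  Evaluated values are clipped to [0, 1].
    """

    intercept: float
    slope: float = 0.0
    gaussians: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        for center, width, _amp in self.gaussians:
            if width <= 0:
                raise ValueError(f"gaussian width must be positive, got {width}")


def default_skin_profile() -> SpectralProfile:
    """Bright, gently rising skin reflectance with a broad visible bump."""
    return SpectralProfile(intercept=0.30, slope=4.5e-4, gaussians=((560.0, 60.0, 0.10),))


def default_vein_profile() -> SpectralProfile:
    """Darker vein reflectance with a deoxygenated-haemoglobin dip near 760 nm."""
    return SpectralProfile(
        intercept=0.20,
        slope=4.0e-4,
        gaussians=((560.0, 60.0, 0.03), (760.0, 40.0, -0.04)),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic scene family.

    Defaults are the desk-scale study conditions: 64x64 pixels, 64 bands over
    400-1000 nm, three vessels of width 5 px, +/-10% smooth illumination and
    noise sigma 0.01 reflectance units.
    """

    rows: int = 64
    cols: int = 64
    bands: int = 64
    wavelength_range: tuple[float, float] = (400.0, 1000.0)
    skin_profile: SpectralProfile = field(default_factory=default_skin_profile)
    vein_profile: SpectralProfile = field(default_factory=default_vein_profile)
    n_veins: int = 3
    vein_width: int = 5
    illumination_strength: float = 0.1
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bands < 2:
            raise ValueError("bands must be >= 2")
        if self.n_veins < 0:
            raise ValueError("n_veins must be >= 0")
        if self.vein_width < 1:
            raise ValueError("vein_width must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 <= self.illumination_strength < 1:
            raise ValueError("illumination_strength must be in [0, 1)")
        lo, hi = self.wavelength_range
        if hi <= lo:
            raise ValueError("wavelength_range must be increasing")

    @property
    def wavelengths(self) -> np.ndarray:
        lo, hi = self.wavelength_range
        return np.linspace(lo, hi, self.bands)


def eval_profile(profile: SpectralProfile, wavelengths: np.ndarray) -> np.ndarray:
    """Evaluate a profile on a wavelength grid (nm), clipped to [0, 1]."""
    wl = np.asarray(wavelengths, dtype=float)
    value = profile.intercept + profile.slope * (wl - 400.0)
    for center, width, amp in profile.gaussians:
        value = value + amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return np.clip(value, 0.0, 1.0)


def _disk(radius: int) -> np.ndarray:
    if radius < 1:
        return np.ones((1, 1), dtype=bool)
    dy, dx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return dy * dy + dx * dx <= radius * radius


def make_vein_mask(
    rows: int,
    cols: int,
    n_veins: int,
    vein_width: int,
    seed: int,
    centerline_rows: list[int] | None = None,
) -> np.ndarray:
    """Union of smoothed random vessel paths dilated to ``vein_width``.

    Each vessel is a cubic-spline-smoothed random walk spanning the full
    image width (or height, chosen at random), dilated by a disk of radius
    ``vein_width // 2``.  Deterministic per seed.

    ``centerline_rows`` is a test hook that bypasses randomness: each listed
    row becomes a straight horizontal centerline across all columns.
    """
    if rows < 8 or cols < 8:
        raise ValueError("mask must be at least 8x8")
    if vein_width >= min(rows, cols):
        raise ValueError(f"vein_width {vein_width} too large for {rows}x{cols} image")

    mask = np.zeros((rows, cols), dtype=bool)
    radius = vein_width // 2

    if centerline_rows is not None:
        for r in centerline_rows:
            mask[r, :] = True
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_veins):
            transpose = bool(rng.integers(0, 2))
            span, lateral = (cols, rows) if not transpose else (rows, cols)
            n_ctrl = max(4, span // 16)
            x_ctrl = np.linspace(0, span - 1, n_ctrl)
            # random-walk control points, kept away from the border
            steps = rng.normal(0.0, lateral / 8.0, size=n_ctrl)
            y_ctrl = np.clip(
                rng.uniform(0.15, 0.85) * lateral + np.cumsum(steps),
                radius + 1,
                lateral - radius - 2,
            )
            y = CubicSpline(x_ctrl, y_ctrl)(np.arange(span))
            y = np.clip(np.round(y).astype(int), 0, lateral - 1)
            line = np.zeros((lateral, span), dtype=bool)
            line[y, np.arange(span)] = True
            mask |= line.T if transpose else line

    if radius >= 1:
        mask = binary_dilation(mask, structure=_disk(radius))

    frac = mask.mean()
    if n_veins >= 1 and centerline_rows is None and not 0 < frac < 0.5:
        raise RuntimeError(f"degenerate vein geometry: vein fraction {frac:.3f}")
    return mask.astype(np.uint8)


def _illumination_field(rows: int, cols: int, strength: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field in [1-strength, 1+strength].

    A random quadratic surface, affinely rescaled to the target range; mimics
    uneven line-light illumination without high-frequency content.
    """
    if strength == 0:
        return np.ones((rows, cols))
    y, x = np.mgrid[0:rows, 0:cols]
    y = y / max(rows - 1, 1) - 0.5
    x = x / max(cols - 1, 1) - 0.5
    c = rng.normal(size=6)
    surface = c[0] * x + c[1] * y + c[2] * x * y + c[3] * x * x + c[4] * y * y + 0.1 * c[5]
    lo, hi = surface.min(), surface.max()
    if hi - lo < 1e-12:
        return np.ones((rows, cols))
    unit = (surface - lo) / (hi - lo)  # [0, 1]
    return 1.0 - strength + 2.0 * strength * unit


def render_cube(mask: np.ndarray, config: SyntheticConfig) -> tuple[Hypercube, np.ndarray]:
    """Render a hypercube from a vein mask and a config.

    Pixel spectrum = class signature x illumination(r, c) + N(0, sigma^2),
    clipped to [0, 1].  The render RNG is derived from ``config.seed`` and is
    independent of the one used for vein geometry.
    """
    mask = np.asarray(mask)
    if mask.shape != (config.rows, config.cols):
        raise ValueError(f"mask shape {mask.shape} does not match config {config.rows}x{config.cols}")
    wl = config.wavelengths
    skin = eval_profile(config.skin_profile, wl)
    vein = eval_profile(config.vein_profile, wl)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    illum = _illumination_field(config.rows, config.cols, config.illumination_strength, rng)
    signatures = np.where(mask[:, :, None].astype(bool), vein, skin)
    data = signatures * illum[:, :, None]
    if config.noise_sigma > 0:
        data = data + rng.normal(0.0, config.noise_sigma, size=data.shape)
        data = np.clip(data, 0.0, 1.0)
    cube = Hypercube(
        data=data.astype(np.float32),
        wavelengths=wl,
        meta={"interleave": "bil", "description": "synthetic hand scene"},
    )
    return cube, mask.astype(np.uint8)


def generate_image(config: SyntheticConfig) -> tuple[Hypercube, np.ndarray]:
    """Generate one (cube, mask) pair from a config: geometry then render."""
    mask = make_vein_mask(
        config.rows, config.cols, config.n_veins, config.vein_width, seed=config.seed
    )
    return render_cube(mask, config)


def generate_dataset(config: SyntheticConfig, n_images: int) -> list[tuple[Hypercube, np.ndarray]]:
    """Generate ``n_images`` pairs; image i uses seed ``config.seed + i``."""
    return [generate_image(replace(config, seed=config.seed + i)) for i in range(n_images)]
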