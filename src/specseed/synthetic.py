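"""Synthetic two-class NIR reflectance spectra and reference cubes.

The generator emulates the statistical structure of mean seed spectra from a
NIR line-scan camera: a smooth reflectance curve near 0.45 that declines with
wavelength, absorption troughs at the protein/starch/water overtone
wavelengths (959.3, 996.9, 1159.1, 1239.1 and 1331.5 nm), a small additive
class-mean offset confined to a block of informative bands, and three nuisance
terms per sample — multiplicative scatter, a linear baseline tilt and white
noise.  Because the class effect is planted at known band indices, wavelength
selectors can be scored on exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import morphology as _morphology

from .cube import HyperCube, RoiMask
from .dataset import DEFECTIVE, HEALTHY, SpectraDataset
from .grid import WavelengthGrid

#: Absorption-feature centers (nm): overtone bands of protein, soluble sugar,
#: water, carbohydrate and starch visible in mean maize-seed spectra.
DEFAULT_FEATURE_CENTERS = (959.3, 996.9, 1159.1, 1239.1, 1331.5)
#: Gaussian trough widths in nm (within 15-40 nm).
DEFAULT_FEATURE_WIDTHS = (16.0, 18.0, 30.0, 26.0, 32.0)
#: Trough depths in reflectance units.
DEFAULT_FEATURE_DEPTHS = (0.012, 0.010, 0.018, 0.022, 0.020)

# Named RNG substreams: one per random artifact so that increasing n extends a
# stream without reshuffling draws in the others.
_STREAM_SPECTRA, _STREAM_GAINS, _STREAM_TILTS, _STREAM_NOISE = 11, 12, 13, 14


def default_informative_bands(grid: WavelengthGrid, n_bands: int = 12) -> np.ndarray:
    """A block of contiguous band indices centered between 1239 and 1331 nm."""
    n_bands = min(n_bands, grid.n_bands)
    center = grid.nearest_index((1239.1 + 1331.5) / 2.0)
    lo = max(0, center - n_bands // 2)
    hi = min(grid.n_bands, lo + n_bands)
    return np.arange(hi - n_bands, hi)


@dataclass
class SyntheticConfig:
    """Study conditions for the two-class spectra generator.

    Defaults: 200 samples per class on the 254-band grid, class-mean offset
    0.02 reflectance at 12 contiguous informative bands, multiplicative
    scatter sd 0.02, baseline tilt sd 1e-5 per nm, white noise sd 0.004.
    """

    n_per_class: int = 200
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    class_offset: float = 0.02
    feature_centers: Sequence[float] = DEFAULT_FEATURE_CENTERS
    feature_widths: Sequence[float] = DEFAULT_FEATURE_WIDTHS
    feature_depths: Sequence[float] = DEFAULT_FEATURE_DEPTHS
    informative_bands: np.ndarray | None = None
    scatter_sd: float = 0.02
    slope_sd: float = 1e-5
    noise_sd: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("class_offset", "scatter_sd", "slope_sd", "noise_sd"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        for name in ("scatter_sd", "slope_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.informative_bands is None:
            self.informative_bands = default_informative_bands(self.grid)
        self.informative_bands = np.asarray(self.informative_bands, dtype=int)
        if self.informative_bands.size and (
            self.informative_bands.min() < 0
            or self.informative_bands.max() >= self.grid.n_bands
        ):
            raise ValueError("informative_bands out of range")


def base_curve(grid: WavelengthGrid, config: SyntheticConfig | None = None) -> np.ndarray:
    """Noise-free class-independent reflectance curve.

    A declining sigmoid from ~0.55 down to ~0.40 across the grid, minus
    Gaussian troughs at the absorption-feature centers.
    """
    wl = grid.values
    centers = DEFAULT_FEATURE_CENTERS if config is None else config.feature_centers
    widths = DEFAULT_FEATURE_WIDTHS if config is None else config.feature_widths
    depths = DEFAULT_FEATURE_DEPTHS if config is None else config.feature_depths
    curve = 0.40 + 0.15 / (1.0 + np.exp((wl - 1150.0) / 180.0))
    for c, w, d in zip(centers, widths, depths):
        curve = curve - d * np.exp(-0.5 * ((wl - c) / w) ** 2)
    return curve


def generate_dataset(config: SyntheticConfig) -> SpectraDataset:
    """Draw a balanced two-class dataset under the configured conditions.

    Each spectrum is ``gain * (base + class_effect) + tilt * (wl - wl_mid)
    + noise`` with per-sample ``gain ~ 1 + N(0, scatter_sd)``,
    ``tilt ~ N(0, slope_sd)`` (units: reflectance per nm) and i.i.d. white
    noise.  The defective class sits ``class_offset`` *below* the healthy
    class at the informative bands, mirroring the lower reflectance of
    damaged kernels.  Bit-reproducible for a fixed seed.
    """
    grid = config.grid
    n, L = config.n_per_class, grid.n_bands
    base = base_curve(grid, config)
    effect = np.zeros(L)
    effect[config.informative_bands] = config.class_offset

    clean = np.empty((2 * n, L))
    clean[:n] = base  # healthy
    clean[n:] = base - effect  # defective

    rng_gain = np.random.default_rng([config.seed, _STREAM_GAINS])
    rng_tilt = np.random.default_rng([config.seed, _STREAM_TILTS])
    rng_noise = np.random.default_rng([config.seed, _STREAM_NOISE])

    gains = 1.0 + rng_gain.normal(0.0, config.scatter_sd, size=2 * n)
    tilts = rng_tilt.normal(0.0, config.slope_sd, size=2 * n)
    noise = rng_noise.normal(0.0, config.noise_sd, size=(2 * n, L))

    wl_centered = grid.values - grid.values.mean()
    X = gains[:, None] * clean + tilts[:, None] * wl_centered[None, :] + noise

    y = np.array([HEALTHY] * n + [DEFECTIVE] * n)
    ids = np.array(
        [f"H{i + 1:04d}" for i in range(n)] + [f"D{i + 1:04d}" for i in range(n)]
    )
    return SpectraDataset(X, y, grid, ids)


@dataclass
class ReferenceScene:
    """A synthetic acquisition: raw counts, references, and oracle truth."""

    raw: HyperCube
    white: HyperCube
    dark: HyperCube
    true_mask: RoiMask
    planted_spectra: np.ndarray  # n_objects x L reflectance, label order


class SceneLayoutError(ValueError):
    """Requested objects cannot be placed without overlap."""


def generate_reference_cube(
    shape: tuple[int, int],
    grid: WavelengthGrid,
    n_objects: int,
    seed: int = 0,
    layout: tuple[int, int] | None = None,
    reflectance: float | None = None,
    noise_sd: float = 0.0,
) -> ReferenceScene:
    """Synthesize raw/white/dark cubes whose calibration recovers planted truth.

    Bright elliptical objects (seeds) are placed on a regular ``layout`` of
    grid cells over a dark background; white counts follow a smooth per-band
    illumination profile and dark counts are constant, so inverting
    ``Re = (Ir-Id)/(Iw-Id)`` recovers the planted reflectances exactly when
    ``noise_sd`` is zero.  ``reflectance`` fixes every object to one flat
    level; otherwise objects get scaled copies of the base curve.
    """
    if n_objects < 0:
        raise ValueError("n_objects must be >= 0")
    rows, cols = shape
    L = grid.n_bands
    if layout is None:
        lay_r = int(np.ceil(np.sqrt(n_objects))) if n_objects else 1
        lay_c = int(np.ceil(n_objects / lay_r)) if n_objects else 1
    else:
        lay_r, lay_c = layout
    if n_objects > lay_r * lay_c:
        raise SceneLayoutError(
            f"{n_objects} objects do not fit a {lay_r}x{lay_c} layout"
        )
    cell_r, cell_c = rows / lay_r, cols / lay_c
    if n_objects and (cell_r < 4 or cell_c < 4):
        raise SceneLayoutError("cells too small: objects would overlap or vanish")

    rng = np.random.default_rng([seed, _STREAM_SPECTRA])
    base = base_curve(grid)
    if reflectance is not None:
        planted = np.full((n_objects, L), float(reflectance))
    else:
        scale = 0.9 + 0.2 * rng.random(n_objects)
        planted = scale[:, None] * base[None, :]

    background = 0.02
    refl = np.full((rows, cols, L), background)
    mask = np.zeros((rows, cols), dtype=int)
    rr, cc = np.mgrid[0:rows, 0:cols]
    footprint = np.ones((3, 3), dtype=bool)
    k = 0
    for i in range(lay_r):
        for j in range(lay_c):
            if k >= n_objects:
                break
            cy, cx = (i + 0.5) * cell_r, (j + 0.5) * cell_c
            ay, ax = 0.30 * cell_r, 0.30 * cell_c
            inside = ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0
            # regularize so the object is invariant under 3x3 opening/closing
            # (jagged single-pixel tips of a discrete ellipse are not)
            inside = _morphology.closing(_morphology.opening(inside, footprint),
                                         footprint)
            if not inside.any():
                raise SceneLayoutError(
                    "cells too small: objects vanish under regularization"
                )
            mask[inside] = k + 1
            refl[inside] = planted[k]
            k += 1

    wl = grid.values
    white_profile = 3000.0 * (0.85 + 0.15 * np.sin((wl - wl[0]) / 250.0))
    dark_level = 120.0
    white = np.broadcast_to(white_profile, (rows, cols, L)).copy()
    dark = np.full((rows, cols, L), dark_level)
    raw = dark + refl * (white - dark)
    if noise_sd > 0:
        rng_noise = np.random.default_rng([seed, _STREAM_NOISE])
        raw = raw + rng_noise.normal(0.0, noise_sd, size=raw.shape)

    return ReferenceScene(
        raw=HyperCube(raw, grid, "raw"),
        white=HyperCube(white, grid, "raw"),
        dark=HyperCube(dark, grid, "raw"),
        true_mask=RoiMask(mask),
        planted_spectra=planted,
    )
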