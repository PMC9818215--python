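"""Hyperspectral cubes: reflectance calibration, seed segmentation, ROI spectra.

A line-scan NIR camera yields a rows x cols x bands cube of sensor counts.
Counts are converted to relative reflectance against white (~100 %) and dark
(shutter closed) reference cubes,

    Re = (Ir - Id) / (Iw - Id),

seeds are segmented from the dark background on a single band (or the band
mean), and the per-band mean over each seed's pixels is the sample spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .dataset import SpectraDataset
from .grid import WavelengthGrid


class CalibrationError(ValueError):
    """White reference does not exceed dark reference somewhere."""


@dataclass
class HyperCube:
    """rows x cols x bands array of sensor counts or reflectance."""

    data: np.ndarray
    grid: WavelengthGrid
    kind: Literal["raw", "reflectance"] = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (rows x cols x bands)")
        if self.data.shape[2] != self.grid.n_bands:
            raise ValueError(
                f"cube has {self.data.shape[2]} bands, grid has {self.grid.n_bands}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class CalibrationPair:
    """White (~100 % target) and dark (shutter closed) reference cubes.

    References may be full cubes or per-band vectors broadcastable against
    the raw cube.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)


@dataclass
class RoiMask:
    """Integer label image: 0 = background, k = seed k (8-connected)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


def calibrate_reflectance(raw: HyperCube, cal: CalibrationPair) -> HyperCube:
    """Convert sensor counts to relative reflectance, Re = (Ir-Id)/(Iw-Id)."""
    denom = cal.white - cal.dark
    bad = np.broadcast_to(denom <= 0, raw.data.shape)
    if bad.any():
        raise CalibrationError(
            f"white reference does not exceed dark reference at "
            f"{int(bad.sum())} cube positions"
        )
    re = (raw.data - cal.dark) / denom
    return HyperCube(re, raw.grid, kind="reflectance")


def segment_seeds(
    cube: HyperCube,
    band_for_threshold: int | Literal["mean"] = "mean",
    threshold_rule: float | Literal["otsu"] = "otsu",
    min_area: int = 20,
) -> RoiMask:
    """Threshold a single band (or the band mean), clean up, label seeds.

    Binarization is followed by a morphological opening then closing with a
    3x3 square element; 8-connected components below ``min_area`` pixels are
    dropped and survivors are labeled in raster order of their first pixel.
    """
    if cube.kind != "reflectance":
        raise ValueError("segmentation expects a calibrated reflectance cube")
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    if band_for_threshold == "mean":
        gray = cube.data.mean(axis=2)
    else:
        gray = cube.data[:, :, int(band_for_threshold)]

    if threshold_rule == "otsu":
        if np.ptp(gray) == 0:
            return RoiMask(np.zeros(gray.shape, dtype=int))
        thr = threshold_otsu(gray)
    else:
        thr = float(threshold_rule)
    binary = gray > thr

    footprint = np.ones((3, 3), dtype=bool)
    binary = morphology.opening(binary, footprint)
    binary = morphology.closing(binary, footprint)

    labels = measure.label(binary, connectivity=2)
    sizes = np.bincount(labels.ravel())
    for lab in np.flatnonzero(sizes < min_area):
        if lab:
            labels[labels == lab] = 0
    return RoiMask(_relabel_raster_order(labels))


def _relabel_raster_order(labels: np.ndarray) -> np.ndarray:
    """Renumber components by the raster position of their first pixel."""
    out = np.zeros_like(labels)
    flat = labels.ravel()
    order: dict[int, int] = {}
    first = {}
    for lab in np.unique(flat):
        if lab == 0:
            continue
        first[lab] = np.flatnonzero(flat == lab)[0]
    for new, (lab, _) in enumerate(sorted(first.items(), key=lambda kv: kv[1]), 1):
        order[lab] = new
    for lab, new in order.items():
        out[labels == lab] = new
    return out


def extract_mean_spectra(cube: HyperCube, mask: RoiMask) -> SpectraDataset:
    """Per-seed mean spectrum: arithmetic mean over the ROI pixels, per band."""
    if mask.labels.shape != cube.data.shape[:2]:
        raise ValueError("mask shape must equal cube spatial shape")
    rows = []
    ids = []
    for k in range(1, mask.n_objects + 1):
        sel = mask.labels == k
        if not sel.any():
            warnings.warn(f"object label {k} is empty; skipped", stacklevel=2)
            continue
        rows.append(cube.data[sel].mean(axis=0))
        ids.append(f"obj{k:03d}")
    X = np.array(rows) if rows else np.empty((0, cube.grid.n_bands))
    y = np.array(["unlabeled"] * len(ids))
    return SpectraDataset(X, y, cube.grid, np.array(ids, dtype=object))


def crop_bands(ds: SpectraDataset, low_nm: float, high_nm: float) -> SpectraDataset:
    """Retain bands whose wavelength lies in [low_nm, high_nm]."""
    if not low_nm < high_nm:
        raise ValueError("low_nm must be < high_nm")
    keep = np.flatnonzero((ds.wavelengths >= low_nm) & (ds.wavelengths <= high_nm))
    if keep.size == 0:
        raise ValueError("band crop leaves no bands")
    return ds.select_bands(keep)


def drop_first_bands(ds: SpectraDataset, k: int) -> SpectraDataset:
    """Remove the first k (noisiest, shortest-wavelength) bands.

    Cropping the default 254-band grid by k=9 leaves the 245 analysis bands.
    """
    if not 0 <= k < ds.n_bands:
        raise ValueError("k must be in [0, n_bands)")
    return ds.select_bands(np.arange(k, ds.n_bands))
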