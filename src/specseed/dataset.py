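"""Tidy spectra tables: one row per sample, one column per wavelength.

The on-disk form is CSV with columns ``id``, ``label``, then one column per
band named by its wavelength in nm with one decimal (``"959.3"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import WavelengthGrid

HEALTHY = "healthy"
DEFECTIVE = "defective"


@dataclass
class SpectraDataset:
    """N x L reflectance matrix with class labels, ids and a wavelength grid."""

    X: np.ndarray
    y: np.ndarray
    grid: WavelengthGrid
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x bands)")
        self.y = np.asarray(self.y)
        if self.y.shape[0] != self.X.shape[0]:
            raise ValueError("row count of X must equal length of y")
        if self.X.shape[1] != self.grid.n_bands:
            raise ValueError(
                f"X has {self.X.shape[1]} bands but grid has {self.grid.n_bands}"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("reflectance values must be finite")
        if self.ids is None:
            self.ids = np.array([f"s{i:04d}" for i in range(self.X.shape[0])])
        else:
            self.ids = np.asarray(self.ids)
            if self.ids.shape[0] != self.X.shape[0]:
                raise ValueError("ids length must match number of samples")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.values

    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    def label_codes(self, positive_class: str = DEFECTIVE) -> np.ndarray:
        """Binary 0/1 coding with 1 for the positive (defective) class."""
        return (self.y == positive_class).astype(int)

    def select_bands(self, indices: Sequence[int]) -> "SpectraDataset":
        idx = np.asarray(indices, dtype=int)
        return SpectraDataset(self.X[:, idx], self.y, self.grid.subset(idx), self.ids)

    def select_rows(self, rows: Sequence[int]) -> "SpectraDataset":
        rows = np.asarray(rows, dtype=int)
        return SpectraDataset(self.X[rows], self.y[rows], self.grid, self.ids[rows])

    def with_X(self, X: np.ndarray) -> "SpectraDataset":
        """Same samples and grid, new (preprocessed) matrix."""
        return SpectraDataset(X, self.y, self.grid, self.ids)

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path) -> None:
        cols = [f"{w:.1f}" for w in self.grid.values]
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "label", self.y)
        df.insert(0, "id", self.ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraDataset":
        df = pd.read_csv(path)
        if "id" not in df.columns or "label" not in df.columns:
            raise ValueError("spectra CSV must have 'id' and 'label' columns")
        band_cols = [c for c in df.columns if c not in ("id", "label")]
        grid = WavelengthGrid(np.array([float(c) for c in band_cols]))
        return cls(
            df[band_cols].to_numpy(dtype=float),
            df["label"].to_numpy(),
            grid,
            df["id"].to_numpy(),
        )
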