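"""Wavelength grids for line-scan NIR hyperspectral instruments."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default acquisition range of the InGaAs line-scan camera, in nm.
DEFAULT_RANGE_NM = (866.4, 1701.0)
#: Default number of spectral bands across that range.
DEFAULT_N_BANDS = 254


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing vector of band-center wavelengths in nm."""

    values: np.ndarray = field(
        default_factory=lambda: np.linspace(*DEFAULT_RANGE_NM, DEFAULT_N_BANDS)
    )

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("wavelength grid must be a nonempty 1-D vector")
        if not np.all(np.isfinite(values)):
            raise ValueError("wavelength grid contains non-finite values")
        if np.any(np.diff(values) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "values", values)

    @property
    def n_bands(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n_bands

    @classmethod
    def default(cls, n_bands: int = DEFAULT_N_BANDS) -> "WavelengthGrid":
        """Evenly spaced grid over the camera's 866.4–1701 nm range."""
        return cls(np.linspace(*DEFAULT_RANGE_NM, n_bands))

    def subset(self, indices: np.ndarray) -> "WavelengthGrid":
        return WavelengthGrid(self.values[np.asarray(indices)])

    def nearest_index(self, nm: float) -> int:
        return int(np.argmin(np.abs(self.values - nm)))
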