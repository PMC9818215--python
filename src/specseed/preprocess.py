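"""Spectral pretreatments: Savitzky-Golay, detrend, MSC, z-score.

The pipeline order mirrors common chemometrics practice for NIR reflectance:
SG smoothing first, then one of two alternative branches (detrending or
multiplicative scatter correction), and z-score standardization at modeling
time with statistics fitted on the training partition only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .dataset import SpectraDataset


def savitzky_golay(ds: SpectraDataset, window: int = 11, polyorder: int = 1) -> SpectraDataset:
    """Sliding local least-squares polynomial smoothing per spectrum.

    Interior points use the centered window; within half a window of either
    edge the same-order polynomial is refit on the one-sided truncated
    window, which keeps the filter exact on straight lines everywhere.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    L = ds.n_bands
    if L < window:
        raise ValueError(f"spectrum length {L} shorter than window {window}")
    out = savgol_filter(ds.X, window, polyorder, axis=1, mode="interp")
    # Replace scipy's edge extrapolation with truncated-window refits.
    half = window // 2
    idx = np.arange(L, dtype=float)
    for i in list(range(half)) + list(range(L - half, L)):
        lo, hi = max(0, i - half), min(L, i + half + 1)
        t = idx[lo:hi] - i
        V = np.vander(t, polyorder + 1, increasing=True)  # column 0 = value at i
        coef, *_ = np.linalg.lstsq(V, ds.X[:, lo:hi].T, rcond=None)
        out[:, i] = coef[0]
    return ds.with_X(out)


def detrend(ds: SpectraDataset) -> SpectraDataset:
    """Subtract each spectrum's own OLS straight line over wavelength.

    The residual has zero mean and zero fitted slope per spectrum, removing
    additive baseline drift while keeping local absorption structure.
    """
    if ds.n_bands < 2:
        raise ValueError("detrending needs at least 2 bands")
    wl = ds.wavelengths
    A = np.column_stack([np.ones_like(wl), wl])
    coef, *_ = np.linalg.lstsq(A, ds.X.T, rcond=None)
    return ds.with_X(ds.X - (A @ coef).T)


@dataclass
class MSCTransformer:
    """Multiplicative scatter correction against a stored reference spectrum.

    Each spectrum x is regressed on the reference, x = a + b*ref, and
    corrected to (x - a)/b.  The reference defaults to the mean spectrum of
    the rows it was fitted on, so test data reuses the training reference.
    """

    reference: np.ndarray | None = None
    min_slope: float = 1e-8

    def fit(self, ds: SpectraDataset) -> "MSCTransformer":
        self.reference = ds.X.mean(axis=0)
        return self

    def transform(self, ds: SpectraDataset) -> SpectraDataset:
        if self.reference is None:
            raise RuntimeError("MSCTransformer must be fitted first")
        ref = np.asarray(self.reference, dtype=float)
        if ref.shape[0] != ds.n_bands:
            raise ValueError("reference length does not match band count")
        ref_c = ref - ref.mean()
        denom = float(ref_c @ ref_c)
        Xc = ds.X - ds.X.mean(axis=1, keepdims=True)
        b = (Xc @ ref_c) / denom
        a = ds.X.mean(axis=1) - b * ref.mean()
        out = ds.X.copy()
        ok = np.abs(b) >= self.min_slope
        if not ok.all():
            warnings.warn(
                f"MSC skipped for {int((~ok).sum())} row(s) with |slope| < "
                f"{self.min_slope}",
                stacklevel=2,
            )
        out[ok] = (ds.X[ok] - a[ok, None]) / b[ok, None]
        return ds.with_X(out)

    def fit_transform(self, ds: SpectraDataset) -> SpectraDataset:
        return self.fit(ds).transform(ds)


def msc(ds: SpectraDataset, reference: np.ndarray | None = None) -> SpectraDataset:
    """One-shot MSC; fits the reference on ``ds`` unless one is supplied."""
    t = MSCTransformer(reference=reference)
    if reference is None:
        t.fit(ds)
    return t.transform(ds)


@dataclass
class ZScoreScaler:
    """Per-band standardization with training statistics (population sd).

    Zero-variance bands are mapped to zeros with a warning.
    """

    mean_: np.ndarray | None = None
    sd_: np.ndarray | None = None

    def fit(self, ds: SpectraDataset) -> "ZScoreScaler":
        if ds.n_samples == 0:
            raise ValueError("cannot fit z-score on an empty dataset")
        self.mean_ = ds.X.mean(axis=0)
        self.sd_ = ds.X.std(axis=0, ddof=0)
        if np.any(self.sd_ == 0):
            warnings.warn(
                f"{int((self.sd_ == 0).sum())} zero-variance band(s) map to zeros",
                stacklevel=2,
            )
        return self

    def transform(self, ds: SpectraDataset) -> SpectraDataset:
        if self.mean_ is None or self.sd_ is None:
            raise RuntimeError("ZScoreScaler must be fitted first")
        sd = np.where(self.sd_ == 0, 1.0, self.sd_)
        out = (ds.X - self.mean_) / sd
        out[:, self.sd_ == 0] = 0.0
        return ds.with_X(out)


def zscore(
    train: SpectraDataset, test: SpectraDataset | None = None
) -> tuple[SpectraDataset, SpectraDataset | None]:
    """Standardize per band on training statistics; apply the same to test."""
    scaler = ZScoreScaler().fit(train)
    train_t = scaler.transform(train)
    test_t = scaler.transform(test) if test is not None else None
    return train_t, test_t


@dataclass
class PreprocessSpec:
    """Declarative pretreatment pipeline: SG -> (DE | MSC) before modeling."""

    sg_window: int = 11
    sg_polyorder: int = 1
    branch: str = "de"  # "de" | "msc" | "none"
    msc: MSCTransformer = field(default_factory=MSCTransformer)

    def fit_apply(self, train: SpectraDataset) -> SpectraDataset:
        out = savitzky_golay(train, self.sg_window, self.sg_polyorder)
        if self.branch == "de":
            out = detrend(out)
        elif self.branch == "msc":
            out = self.msc.fit_transform(out)
        elif self.branch != "none":
            raise ValueError(f"unknown branch {self.branch!r}")
        return out

    def apply(self, ds: SpectraDataset) -> SpectraDataset:
        out = savitzky_golay(ds, self.sg_window, self.sg_polyorder)
        if self.branch == "de":
            out = detrend(out)
        elif self.branch == "msc":
            out = self.msc.transform(out)
        return out
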