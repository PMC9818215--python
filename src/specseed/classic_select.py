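"""Classical wavelength selection: successive projections (SPA) and
competitive adaptive reweighted sampling (CARS).

Both selectors operate on an N x L spectra matrix with a 0/1-coded class
response and justify their subset with a criterion curve: cross-validated
RMSE of a multiple linear regression versus subset size for SPA, and
cross-validated RMSE of a PLS regression per Monte-Carlo sampling run for
CARS.  The selected subset minimizes the criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import json
import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold, LeaveOneOut, StratifiedKFold

from .dataset import SpectraDataset

_RANK_EPS = 1e-12


@dataclass
class SelectionResult:
    """Selected band indices plus the criterion curve that justified them."""

    indices: np.ndarray  # unique, ascending
    wavelengths_nm: np.ndarray
    criterion_curve: np.ndarray  # RMSE per size (SPA) / RMSECV per run (CARS)
    best_value: float
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return int(self.indices.size)

    def fraction_of(self, n_total: int | None = None) -> float:
        """Selected share of wavelengths as a percent (2 decimals)."""
        total = n_total if n_total is not None else self.meta.get("n_bands_total")
        if not total:
            raise ValueError("total band count unknown")
        return round(100.0 * self.n_selected / total, 2)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "indices": self.indices.tolist(),
            "wavelengths_nm": np.asarray(self.wavelengths_nm).round(4).tolist(),
            "criterion_curve": np.asarray(self.criterion_curve).tolist(),
            "best_value": float(self.best_value),
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        return cls(
            np.array(d["indices"], dtype=int),
            np.array(d["wavelengths_nm"]),
            np.array(d["criterion_curve"]),
            float(d["best_value"]),
            d.get("meta", {}),
        )


# --------------------------------------------------------------------- SPA

def spa_chain(X: np.ndarray, start_index: int, k: int) -> list[int]:
    """Greedy successive-projections chain of k column indices.

    Starting from ``start_index``, each step projects every unselected
    (mean-centered) column onto the orthogonal complement of the span of the
    selected columns and adds the column with maximal residual norm — the
    least collinear with everything already chosen.  Returns indices in
    selection order; the chain is cut short with a warning if all residual
    norms vanish (rank exhaustion).
    """
    X = np.asarray(X, dtype=float)
    N, L = X.shape
    if not 1 <= k <= min(N - 1, L):
        raise ValueError(f"k must be in [1, min(N-1, L)] = [1, {min(N - 1, L)}]")
    R = X - X.mean(axis=0)  # residuals after deflation by selected columns
    chain = [int(start_index)]
    for _ in range(k - 1):
        v = R[:, chain[-1]].copy()
        nv = v @ v
        if nv > _RANK_EPS:
            R = R - np.outer(v, (v @ R) / nv)
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        best = int(np.argmax(norms))
        if norms[best] < np.sqrt(_RANK_EPS):
            warnings.warn(
                f"rank exhausted after {len(chain)} of {k} variables", stacklevel=2
            )
            break
        chain.append(best)
    return chain


def _cv_rmse_mlr(X: np.ndarray, y: np.ndarray, folds: int, seed: int) -> float:
    """K-fold cross-validated RMSE of an intercept + MLR fit on X."""
    N = X.shape[0]
    folds = min(folds, N)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sse = 0.0
    for tr, te in kf.split(X):
        A = np.column_stack([np.ones(len(tr)), X[tr]])
        coef, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
        pred = np.column_stack([np.ones(len(te)), X[te]]) @ coef
        sse += float(((y[te] - pred) ** 2).sum())
    return float(np.sqrt(sse / N))


def spa_select(
    train: SpectraDataset,
    max_vars: int = 50,
    eval_folds: int = 5,
    seed: int = 0,
    positive_class: str = "defective",
) -> SelectionResult:
    """SPA over all start columns and sizes 1..max_vars, scored by CV-RMSE.

    For each candidate size k the best chain over all starting columns is
    kept (multiple linear regression on the subset, labels coded 0/1,
    K-fold CV-RMSE); the returned subset is the global RMSE minimum with
    ties broken toward the smaller k.  The criterion curve is best RMSE
    versus k, and meta reports the coefficient of determination R^2 of the
    winning subset under the same cross-validation.
    """
    X = train.X
    y = train.label_codes(positive_class).astype(float)
    N, L = X.shape
    if max_vars > min(N - 1, L):
        raise ValueError("max_vars must be <= min(N-1, L)")
    folds = eval_folds
    if N < folds:
        warnings.warn(f"fold count reduced to {N}", stacklevel=2)
        folds = N

    chains = []
    for start in range(L):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chains.append(spa_chain(X, start, max_vars))

    curve = np.full(max_vars, np.inf)
    best_subset_per_k: list[list[int] | None] = [None] * max_vars
    for k in range(1, max_vars + 1):
        for chain in chains:
            if len(chain) < k:
                continue
            subset = chain[:k]
            rmse = _cv_rmse_mlr(X[:, subset], y, folds, seed)
            if rmse < curve[k - 1]:
                curve[k - 1] = rmse
                best_subset_per_k[k - 1] = subset
    best_k = int(np.argmin(curve)) + 1  # argmin takes the first (smallest k) tie
    subset = sorted(best_subset_per_k[best_k - 1])

    # R^2 of the winning subset under the same CV
    rmse_best = curve[best_k - 1]
    r2 = 1.0 - (rmse_best**2) / float(np.var(y))
    return SelectionResult(
        indices=np.array(subset, dtype=int),
        wavelengths_nm=train.wavelengths[subset],
        criterion_curve=curve,
        best_value=float(rmse_best),
        meta={
            "algorithm": "spa",
            "max_vars": max_vars,
            "folds": folds,
            "seed": seed,
            "r2": float(r2),
            "n_bands_total": L,
        },
    )


# ------------------------------------------------------------------ RMSECV

def rmsecv(
    X_subset: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    max_pls_components: int = 10,
    n_components: int | str = "cv",
    seed: int = 0,
) -> float:
    """K-fold cross-validated RMSE of a PLS regression on the subset.

    The component count is capped at ``min(max_pls_components, n_vars,
    smallest-training-fold - 1)``; with ``n_components="cv"`` every count up
    to the cap is scored on the same folds and the minimum RMSE is returned
    (the usual chemometrics convention for reporting RMSECV).  Folds are
    stratified on the binary response so no fold is single-class;
    ``folds == N`` falls back to leave-one-out.
    """
    X = np.asarray(X_subset, dtype=float)
    y = np.asarray(y, dtype=float)
    N, nvar = X.shape
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if nvar == 0:
        raise ValueError("subset is empty")
    if folds >= N:
        splitter = LeaveOneOut()
        splits = list(splitter.split(X))
    else:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(skf.split(X, (y > np.median(y)).astype(int) if len(np.unique(y)) > 2 else y.astype(int)))
    min_train = min(len(tr) for tr, _ in splits)
    cap = max(1, min(max_pls_components, nvar, min_train - 1))
    comps = range(1, cap + 1) if n_components == "cv" else [min(int(n_components), cap)]

    best = np.inf
    for nc in comps:
        sse = 0.0
        for tr, te in splits:
            pls = PLSRegression(n_components=nc, scale=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pls.fit(X[tr], y[tr])
            pred = pls.predict(X[te]).ravel()
            sse += float(((y[te] - pred) ** 2).sum())
        best = min(best, np.sqrt(sse / N))
    return float(best)


# -------------------------------------------------------------------- CARS

def cars_schedule(L: int, n_mc: int) -> np.ndarray:
    """Retained-band counts per run under the exponential decay schedule.

    The retention ratio is r_i = a * exp(-b*i) with a, b fixed so that run 1
    keeps all L bands and run n_mc keeps 2: b = ln(L/2)/(n_mc-1), a = e^b.
    """
    i = np.arange(1, n_mc + 1, dtype=float)
    b = np.log(L / 2.0) / (n_mc - 1)
    a = np.exp(b)
    counts = np.round(a * np.exp(-b * i) * L).astype(int)
    return np.clip(counts, 2, L)


def cars_select(
    train: SpectraDataset,
    n_mc: int = 50,
    folds: int = 5,
    seed: int = 0,
    max_pls_components: int = 10,
    mc_row_fraction: float = 0.8,
    positive_class: str = "defective",
) -> SelectionResult:
    """Competitive adaptive reweighted sampling over ``n_mc`` Monte-Carlo runs.

    Each run fits PLS on a random 80 % row sample restricted to the currently
    retained bands, weights every retained band by its normalized absolute
    PLS regression coefficient, enforces the exponentially decreasing
    retention schedule, draws the new retained set by weighted sampling
    without replacement, and records the RMSECV of that set.  The final
    subset is the retained set of the run with minimal RMSECV.
    """
    if n_mc < 2:
        raise ValueError("n_mc must be >= 2")
    X = train.X
    y = train.label_codes(positive_class).astype(float)
    N, L = X.shape
    rng = np.random.default_rng(seed)
    counts = cars_schedule(L, n_mc)

    retained = np.arange(L)
    curve = np.empty(n_mc)
    history: list[np.ndarray] = []
    for i in range(n_mc):
        rows = rng.choice(N, size=max(2, int(round(mc_row_fraction * N))), replace=False)
        ncomp = max(1, min(max_pls_components, retained.size, rows.size - 1))
        pls = PLSRegression(n_components=ncomp, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls.fit(X[np.ix_(rows, retained)], y[rows])
        w = np.abs(pls.coef_).ravel()
        w = np.maximum(w, 1e-12)
        w = w / w.sum()

        keep = min(counts[i], retained.size)
        keep = max(keep, 2)
        drawn = rng.choice(retained.size, size=keep, replace=False, p=w)
        retained = np.sort(retained[drawn])
        history.append(retained.copy())
        curve[i] = rmsecv(
            X[:, retained], y, folds=folds,
            max_pls_components=max_pls_components, seed=seed,
        )

    best_run = int(np.argmin(curve))
    subset = history[best_run]
    return SelectionResult(
        indices=subset,
        wavelengths_nm=train.wavelengths[subset],
        criterion_curve=curve,
        best_value=float(curve[best_run]),
        meta={
            "algorithm": "cars",
            "n_mc": n_mc,
            "folds": folds,
            "seed": seed,
            "best_run": best_run,
            "retained_counts": [int(h.size) for h in history],
            "schedule": counts.tolist(),
            "n_bands_total": L,
        },
    )
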