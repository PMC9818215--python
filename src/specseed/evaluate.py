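"""Baselines, splits, confusion-matrix metrics and model benchmarking.

Accuracy, sensitivity and specificity come from the binary confusion matrix:

    AC = (TP+TN)/(TP+FP+TN+FN),  SE = TP/(TP+FN),  SP = TN/(TN+FP),

reported in percent with two decimals (half-up).  The positive class
defaults to "defective" (worm-eaten); the convention is a flag because the
choice only swaps SE and SP.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import json
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC

from .dataset import DEFECTIVE, SpectraDataset
from .preprocess import PreprocessSpec, zscore

BASELINE_NAMES = ("LDA", "RF", "SVM")


def split_train_test(
    ds: SpectraDataset, ratio: float = 0.7, seed: int = 0
) -> tuple[SpectraDataset, SpectraDataset]:
    """Random split by seeded permutation: floor(ratio*N) train, rest test.

    A draw that leaves either partition single-class is resampled with a
    warning (it would make sensitivity or specificity undefined).
    """
    N = ds.n_samples
    if N < 10:
        raise ValueError("need at least 10 samples to split")
    if not 0 < ratio < 1:
        raise ValueError("ratio must be strictly between 0 and 1")
    n_train = int(np.floor(ratio * N))
    rng = np.random.default_rng(seed)
    for attempt in range(100):
        perm = rng.permutation(N)
        tr, te = perm[:n_train], perm[n_train:]
        if len(np.unique(ds.y[tr])) > 1 and len(np.unique(ds.y[te])) > 1:
            if attempt:
                warnings.warn(
                    f"resampled split {attempt} time(s) to avoid a "
                    "single-class partition", stacklevel=2,
                )
            return ds.select_rows(np.sort(tr)), ds.select_rows(np.sort(te))
    raise RuntimeError("could not draw a two-class split")


def fit_baseline(name: str, train: SpectraDataset, positive_class: str = DEFECTIVE):
    """Fit one of the reference classifiers at its fixed hyperparameters.

    LDA: SVD solver, rank tolerance 1e-4.  SVM: RBF kernel, C=10,
    gamma=0.004.  RF: Gini impurity, 15 trees, random_state=2,
    max_features=6 (clipped to the band count when fewer).
    Features are expected standardized.
    """
    y = train.label_codes(positive_class)
    if name == "LDA":
        clf = LinearDiscriminantAnalysis(solver="svd", tol=1e-4)
    elif name == "SVM":
        clf = SVC(kernel="rbf", C=10, gamma=0.004)
    elif name == "RF":
        max_features = min(6, train.n_bands)
        if max_features < 6:
            warnings.warn(
                f"max_features clipped to {max_features}", stacklevel=2
            )
        clf = RandomForestClassifier(
            criterion="gini", n_estimators=15, random_state=2,
            max_features=max_features,
        )
    else:
        raise ValueError(f"unknown baseline {name!r}; choose from {BASELINE_NAMES}")
    clf.fit(train.X, y)
    return clf


def svm_grid_search(
    train: SpectraDataset,
    folds: int = 10,
    positive_class: str = DEFECTIVE,
) -> tuple[float, float]:
    """Verification mode: grid-search (C, gamma) over 1e-5..1e5, K-fold CV."""
    grid = {"C": np.logspace(-5, 5, 11), "gamma": np.logspace(-5, 5, 11)}
    search = GridSearchCV(SVC(kernel="rbf"), grid, cv=folds)
    search.fit(train.X, train.label_codes(positive_class))
    return float(search.best_params_["C"]), float(search.best_params_["gamma"])


@dataclass
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class Metrics:
    """AC/SE/SP in percent (2 decimals, half-up); missing -> nan."""

    ac: float
    se: float
    sp: float


def _pct(num: int, den: int) -> float:
    if den == 0:
        return float("nan")
    return float(
        Decimal(100.0 * num / den).quantize(Decimal("0.01"), ROUND_HALF_UP)
    )


def confusion_and_metrics(
    y_true: Sequence, y_pred: Sequence, positive_class=DEFECTIVE
) -> tuple[ConfusionMatrix, Metrics]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    cm = ConfusionMatrix(
        TP=int(np.sum(pos_t & pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
    )
    if cm.TP + cm.FN == 0 or cm.TN + cm.FP == 0:
        warnings.warn("empty positive or negative class: metric undefined",
                      stacklevel=2)
    metrics = Metrics(
        ac=_pct(cm.TP + cm.TN, cm.total),
        se=_pct(cm.TP, cm.TP + cm.FN),
        sp=_pct(cm.TN, cm.TN + cm.FP),
    )
    return cm, metrics


@dataclass
class TTestResult:
    t: float
    p: float
    degenerate: bool = False


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Classical paired t on the differences, two-sided p.

    Zero-variance differences leave t undefined; the result is flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        return TTestResult(float("nan"), float("nan"), degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return TTestResult(float(t), float(p), degenerate=False)


@dataclass
class EvaluationReport:
    """Per model x preprocessing x selector rows of AC/SE/SP and runtime."""

    rows: list[dict] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.rows, indent=2, default=str))


def evaluate_split(
    clf,
    train: SpectraDataset,
    test: SpectraDataset,
    positive_class: str = DEFECTIVE,
) -> dict:
    """AC/SE/SP on both partitions for a fitted sklearn-style classifier."""
    out = {}
    for split_name, part in (("train", train), ("test", test)):
        pred = clf.predict(part.X)
        truth = part.label_codes(positive_class)
        names = np.array(["neg", "pos"])
        _, m = confusion_and_metrics(names[truth], names[pred], "pos")
        out[split_name] = m
    return out


def benchmark(
    ds: SpectraDataset,
    branches: Iterable[str] = ("de", "msc"),
    selectors: Iterable[str] = ("none", "spa", "cars", "cnn-fes"),
    models: Iterable[str] = BASELINE_NAMES,
    ratio: float = 0.7,
    seed: int = 0,
    positive_class: str = DEFECTIVE,
    selector_kwargs: dict | None = None,
    atm_config=None,
    fes_config=None,
) -> EvaluationReport:
    """Full factorial run: preprocessing branch x selector x model.

    Each cell splits with the same seed, preprocesses (SG then DE or MSC,
    fit on train), selects wavelengths on the training partition,
    standardizes, fits, and reports AC/SE/SP on both partitions plus the
    fit runtime.  Stage failures are recorded and the run continues.
    """
    from .classic_select import cars_select, spa_select  # local: avoid cycle
    from . import cnn_fes as fes_mod
    from . import cnn_atm as atm_mod

    selector_kwargs = selector_kwargs or {}
    report = EvaluationReport()
    train_raw, test_raw = split_train_test(ds, ratio=ratio, seed=seed)

    for branch in branches:
        spec = PreprocessSpec(branch=branch)
        train_pp = spec.fit_apply(train_raw)
        test_pp = spec.apply(test_raw)
        for selector in selectors:
            try:
                if selector == "none":
                    sel_idx = np.arange(train_pp.n_bands)
                elif selector == "spa":
                    kw = selector_kwargs.get("spa", {})
                    sel_idx = spa_select(train_pp, seed=seed, **kw).indices
                elif selector == "cars":
                    kw = selector_kwargs.get("cars", {})
                    sel_idx = cars_select(train_pp, seed=seed, **kw).indices
                elif selector == "cnn-fes":
                    cfg = fes_config or fes_mod.FESConfig(seed=seed)
                    tr_std, _ = zscore(train_pp)
                    rep = fes_mod.permutation_importance(
                        tr_std, cfg, positive_class=positive_class
                    )
                    sel_idx = fes_mod.select_top(rep, cfg.top_fraction).indices
                else:
                    raise ValueError(f"unknown selector {selector!r}")
                if len(sel_idx) == 0:
                    raise RuntimeError("selector returned no bands")
            except Exception as exc:  # record and continue
                for model in models:
                    report.rows.append({
                        "branch": branch, "selector": selector, "model": model,
                        "error": f"selection failed: {exc}",
                    })
                continue

            train_sel = train_pp.select_bands(sel_idx)
            test_sel = test_pp.select_bands(sel_idx)
            train_std, test_std = zscore(train_sel, test_sel)
            for model in models:
                row = {
                    "branch": branch, "selector": selector, "model": model,
                    "n_bands": int(len(sel_idx)),
                }
                try:
                    t0 = time.perf_counter()
                    if model == "CNN-ATM":
                        cfg = atm_config or atm_mod.ATMConfig(seed=seed)
                        atm, _ = atm_mod.train_atm(
                            train_std, cfg, positive_class=positive_class
                        )
                        elapsed = time.perf_counter() - t0
                        for split_name, part in (("train", train_std),
                                                 ("test", test_std)):
                            pred, _ = atm_mod.predict(
                                atm, part, positive_class=positive_class
                            )
                            _, m = confusion_and_metrics(
                                part.y, pred, positive_class
                            )
                            row[f"{split_name}_ac"] = m.ac
                            row[f"{split_name}_se"] = m.se
                            row[f"{split_name}_sp"] = m.sp
                    else:
                        clf = fit_baseline(model, train_std, positive_class)
                        elapsed = time.perf_counter() - t0
                        res = evaluate_split(
                            clf, train_std, test_std, positive_class
                        )
                        for split_name, m in res.items():
                            row[f"{split_name}_ac"] = m.ac
                            row[f"{split_name}_se"] = m.se
                            row[f"{split_name}_sp"] = m.sp
                    row["fit_seconds"] = round(elapsed, 3)
                except Exception as exc:
                    row["error"] = str(exc)
                report.rows.append(row)
    return report
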