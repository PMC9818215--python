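"""End-to-end study protocols on synthetic spectra.

Two reference experiments are defined once here so that scripts and tests
exercise identical conditions:

* ``fes_recovery_experiment`` — can the CNN feature selector recover the
  planted informative bands?  Runs at a desk scale (128-band grid, 100
  samples per class, 30 epochs) chosen so a single-CPU run finishes in
  minutes; the network's kernel counts scale with the band count, all other
  hyperparameters are the training-protocol defaults.
* ``atm_accuracy_experiment`` — test-set accuracy of the attention
  classifier at the full study scale (254-band grid cropped to 245 bands,
  200 samples per class, 7:3 split); 60 epochs by default, since training
  accuracy saturates within the first ~20.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cnn_atm import ATMConfig, predict, train_atm
from .cnn_fes import FESConfig, permutation_importance, select_top
from .cube import drop_first_bands
from .dataset import SpectraDataset
from .evaluate import confusion_and_metrics, fit_baseline, split_train_test
from .grid import WavelengthGrid
from .preprocess import PreprocessSpec, detrend, zscore
from .synthetic import SyntheticConfig, generate_dataset


def make_study_dataset(
    seed: int, n_bands: int = 254, n_per_class: int = 200
) -> SpectraDataset:
    """Synthetic two-class dataset under the default study conditions."""
    cfg = SyntheticConfig(
        n_per_class=n_per_class, grid=WavelengthGrid.default(n_bands), seed=seed
    )
    return generate_dataset(cfg)


@dataclass
class RecoveryResult:
    selected: np.ndarray
    planted: np.ndarray
    recovered_fraction: float
    n_selected: int


def fes_recovery_experiment(
    seed: int,
    n_bands: int = 128,
    n_per_class: int = 100,
    epochs: int = 30,
) -> RecoveryResult:
    """Train the CNN feature selector and score planted-band recovery.

    Pipeline: generate -> 7:3 split -> detrend -> z-score -> permutation
    importance (1 true + 5 null trainings) -> top-10 % selection.
    Detrending (without smoothing) removes the baseline tilt and most of
    the multiplicative-scatter variance while keeping the planted support
    identifiable at band resolution — a smoothing window would smear the
    class effect onto neighboring bands and blur the ground truth the
    experiment scores against.  Returns the fraction of planted informative
    bands present in the selected subset.
    """
    synth_cfg = SyntheticConfig(
        n_per_class=n_per_class, grid=WavelengthGrid.default(n_bands), seed=seed
    )
    ds = generate_dataset(synth_cfg)
    train, _ = split_train_test(ds, ratio=0.7, seed=seed)
    train_std, _ = zscore(detrend(train))

    fes_cfg = FESConfig(epochs=epochs, seed=seed)
    report = permutation_importance(train_std, fes_cfg)
    sel = select_top(report, fes_cfg.top_fraction)

    planted = synth_cfg.informative_bands
    recovered = np.intersect1d(sel.indices, planted).size / planted.size
    return RecoveryResult(
        selected=sel.indices,
        planted=planted,
        recovered_fraction=float(recovered),
        n_selected=sel.n_selected,
    )


@dataclass
class AccuracyResult:
    test_ac: float
    test_se: float
    test_sp: float
    train_ac: float
    history: dict


def atm_accuracy_experiment(
    seed: int,
    n_bands: int = 254,
    n_per_class: int = 200,
    epochs: int = 60,
    branch: str = "de",
    crop_first: int = 9,
    use_attention: bool = True,
) -> AccuracyResult:
    """Attention-classifier accuracy on a full-scale synthetic study.

    Generate -> drop the first ``crop_first`` noisy bands -> 7:3 split ->
    SG + branch preprocessing -> z-score -> train -> AC/SE/SP on the test
    partition (percent).  ``use_attention=False`` runs the gate-ablated
    network for comparison.
    """
    ds = make_study_dataset(seed, n_bands=n_bands, n_per_class=n_per_class)
    if crop_first:
        ds = drop_first_bands(ds, crop_first)
    train, test = split_train_test(ds, ratio=0.7, seed=seed)
    spec = PreprocessSpec(branch=branch)
    train_pp = spec.fit_apply(train)
    test_pp = spec.apply(test)
    train_std, test_std = zscore(train_pp, test_pp)

    cfg = ATMConfig(epochs=epochs, seed=seed, use_attention=use_attention)
    model, history = train_atm(train_std, cfg, test=test_std)

    out = {}
    for name, part in (("train", train_std), ("test", test_std)):
        pred, _ = predict(model, part)
        _, m = confusion_and_metrics(part.y, pred)
        out[name] = m
    return AccuracyResult(
        test_ac=out["test"].ac,
        test_se=out["test"].se,
        test_sp=out["test"].sp,
        train_ac=out["train"].ac,
        history=history,
    )


def baseline_accuracies(
    seed: int,
    n_bands: int = 254,
    n_per_class: int = 200,
    branch: str = "de",
    crop_first: int = 9,
) -> dict[str, float]:
    """Test-set AC (percent) of LDA/RF/SVM under the same pipeline."""
    ds = make_study_dataset(seed, n_bands=n_bands, n_per_class=n_per_class)
    if crop_first:
        ds = drop_first_bands(ds, crop_first)
    train, test = split_train_test(ds, ratio=0.7, seed=seed)
    spec = PreprocessSpec(branch=branch)
    train_pp = spec.fit_apply(train)
    test_pp = spec.apply(test)
    train_std, test_std = zscore(train_pp, test_pp)
    out = {}
    for name in ("LDA", "RF", "SVM"):
        clf = fit_baseline(name, train_std)
        pred_codes = clf.predict(test_std.X)
        names = np.array(["healthy", "defective"])
        _, m = confusion_and_metrics(test_std.y, names[pred_codes])
        out[name] = m.ac
    return out
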