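"""CNN-based wavelength selection with label-permutation importance.

A feature-weight (FW) gate — a trainable per-band score vector whose softmax
multiplies the input spectrum — feeds a two-block 1-D CNN classifier.  The
training loss is cross-entropy plus ``lambda_reg * sum(c_k^2)`` over the FW
coefficients, so the gate only concentrates mass on bands that pay for
themselves in classification accuracy.  Importance is made robust against
bands that merely co-adapt to noise by an Altmann-style permutation scheme:
the network is retrained from scratch on several label-shuffled copies of
the data, the 75 % quantile of the null coefficients per band gives S2, and
the score

    IS_k = log(1e-10 + S1_k / S2_k)

compares the true-label coefficient S1 with that null; IS < 0 marks band k
as not informative for the task.  The selected subset is the top fraction of
bands by IS, minus any negative-scoring ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .classic_select import SelectionResult
from .dataset import SpectraDataset
from .nn.core import (
    Conv1D,
    Dense,
    Dropout,
    ExpandDims,
    Flatten,
    FWGate,
    MaxPool1D,
    Network,
    ReLU,
    fit_network,
    softmax,
)

#: Conv kernel counts / widths at the reference band count of 245.
_REF_L = 245
_REF_KERNELS = (127, 245)
_REF_WIDTHS = (64, 32)


@dataclass
class FESConfig:
    """Training protocol of the feature-selection network."""

    epochs: int = 100
    batch_size: int = 4
    lambda_reg: float = 0.15
    weight_decay: float = 0.1
    lr0: float = 0.001
    adam_beta1: float = 0.9
    lr_decay: float = 1e-4
    n_label_shuffles: int = 5
    quantile: float = 0.75
    top_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.n_label_shuffles < 1:
            raise ValueError("n_label_shuffles must be >= 1")


@dataclass
class ImportanceReport:
    """Per-band importances: true-label S1, null S2, and score IS."""

    S1: np.ndarray
    S2: np.ndarray
    IS: np.ndarray
    IF_history: np.ndarray  # (n_label_shuffles, L) null coefficients
    wavelengths_nm: np.ndarray
    selected: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        payload = {
            "wavelengths_nm": np.round(self.wavelengths_nm, 4).tolist(),
            "S1": self.S1.tolist(),
            "S2": self.S2.tolist(),
            "IS": self.IS.tolist(),
            "IF_history": self.IF_history.tolist(),
            "selected": None if self.selected is None else self.selected.tolist(),
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def fes_kernel_spec(L: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Kernel counts and widths for band count L.

    Counts are literal (127, 245) at L=245 and scale proportionally
    otherwise; widths 64/32 are clipped so each conv layer keeps a positive
    output length.
    """
    if L == _REF_L:
        counts = _REF_KERNELS
    else:
        counts = (
            max(1, round(_REF_KERNELS[0] * L / _REF_L)),
            max(2, round(_REF_KERNELS[1] * L / _REF_L)),
        )
    w1 = min(_REF_WIDTHS[0], L)
    len1 = L - w1 + 1  # conv1 out
    len1p = max(1, len1 - 1)  # pool
    w2 = min(_REF_WIDTHS[1], len1p)
    if w1 < _REF_WIDTHS[0] or w2 < _REF_WIDTHS[1]:
        warnings.warn(
            f"kernel widths clipped to ({w1}, {w2}) for L={L}", stacklevel=2
        )
    return counts, (w1, w2)


def build_fes_network(L: int, config: FESConfig, rng: np.random.Generator) -> Network:
    """FW gate -> Conv/pool x2 -> Flatten -> Dense(10) -> Dropout -> Dense(2)."""
    (n1, n2), (w1, w2) = fes_kernel_spec(L)
    len1 = max(1, (L - w1 + 1) - 1) if (L - w1 + 1) >= 2 else 1
    len2c = len1 - w2 + 1
    len2 = max(1, len2c - 1) if len2c >= 2 else max(1, len2c)
    flat = len2 * n2
    drop_rng = np.random.default_rng([config.seed, 7])
    return Network(
        [
            FWGate(L, lambda_reg=config.lambda_reg),
            ExpandDims(),
            Conv1D(1, n1, w1, rng),
            ReLU(),
            MaxPool1D(),
            Conv1D(n1, n2, w2, rng),
            ReLU(),
            MaxPool1D(),
            Flatten(),
            Dense(flat, 10, rng),
            Dropout(0.25, drop_rng),
            Dense(10, 2, rng),
        ]
    )


def fes_loss(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    coefficients: np.ndarray,
    lambda_reg: float,
) -> float:
    """Composite loss: mean cross-entropy + lambda * sum of squared FW coefficients."""
    y_true = np.asarray(y_true, dtype=float)
    p = np.clip(np.asarray(y_pred, dtype=float), 1e-12, 1.0)
    n = y_true.shape[0]
    ce = -float(np.sum(y_true * np.log(p))) / n
    reg = float(lambda_reg) * float(np.sum(np.asarray(coefficients) ** 2))
    return ce + reg


def _one_hot(codes: np.ndarray) -> np.ndarray:
    out = np.zeros((codes.size, 2))
    out[np.arange(codes.size), codes] = 1.0
    return out


@dataclass
class FESModel:
    network: Network
    config: FESConfig
    wavelengths_nm: np.ndarray

    @property
    def fw_gate(self) -> FWGate:
        return self.network.layers[0]


def fw_forward(x: np.ndarray, gate: FWGate) -> np.ndarray:
    """Gate a batch (or single) spectrum: softmax(scores) * x."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    c = gate.coefficients
    out = x * c[None, :]
    return out[0] if out.shape[0] == 1 else out


def fw_forward_selfproduct(x: np.ndarray) -> np.ndarray:
    """Non-trainable gating variant: softmax(x * x) ⊙ x per spectrum.

    Reads the gate's pre-activation as the elementwise self-product of the
    input instead of a learned score vector; offered for comparison, not
    used in training (a fixed gate leaves nothing for the loss to
    regularize).
    """
    x = np.asarray(x, dtype=float)
    x2 = np.atleast_2d(x)
    e = np.exp(x2 * x2 - (x2 * x2).max(axis=1, keepdims=True))
    c = e / e.sum(axis=1, keepdims=True)
    out = c * x2
    return out[0] if x.ndim == 1 else out


def train_fes(
    train: SpectraDataset,
    config: FESConfig,
    labels: np.ndarray | None = None,
    positive_class: str = "defective",
) -> tuple[FESModel, np.ndarray, dict[str, np.ndarray]]:
    """Train the selection network; returns (model, IF per band, history).

    ``train.X`` is expected standardized (z-score).  IF is the trained FW
    softmax coefficient per band at the final epoch — the only per-band
    quantity the composite loss regularizes.  ``labels`` overrides the
    dataset labels (used for the permutation null).
    """
    X = train.X
    codes = (
        train.label_codes(positive_class)
        if labels is None
        else (np.asarray(labels) == positive_class).astype(int)
    )
    y = _one_hot(codes)
    rng_init = np.random.default_rng([config.seed, 1])
    rng_batch = np.random.default_rng([config.seed, 2])
    net = build_fes_network(train.n_bands, config, rng_init)
    gate: FWGate = net.layers[0]
    history = fit_network(
        net,
        X,
        y,
        epochs=config.epochs,
        batch_size=config.batch_size,
        lr0=config.lr0,
        beta1=config.adam_beta1,
        lr_decay=config.lr_decay,
        weight_decay=config.weight_decay,
        rng=rng_batch,
        extra_loss=gate.regularizer,
    )
    model = FESModel(net, config, train.wavelengths.copy())
    return model, gate.coefficients, history


def _match_null_amplitude(IF_history: np.ndarray, S1: np.ndarray) -> np.ndarray:
    """Rescale each null run's deviation from uniform to the true run's.

    Gate movement scales with how long the cross-entropy stays informative,
    which differs sharply between true-label runs (fast convergence) and
    label-shuffled runs (slow memorization).  Matching the deviation norms
    preserves each null run's per-band *shape* — the structural bias the
    null is meant to calibrate away — at the true run's amplitude, so the
    S1/S2 ratio compares like with like.
    """
    L = S1.size
    u = 1.0 / L
    d_true = np.linalg.norm(S1 - u)
    out = np.empty_like(IF_history)
    for j, IF in enumerate(IF_history):
        d = np.linalg.norm(IF - u)
        scale = d_true / d if d > 0 else 0.0
        out[j] = np.maximum(u + (IF - u) * scale, 1e-3 * u)
    return out


def permutation_importance(
    train: SpectraDataset,
    config: FESConfig,
    positive_class: str = "defective",
    null_quantile_mode: str = "matched",
) -> ImportanceReport:
    """True-label vs label-shuffled importance of every band.

    S1 comes from one training on the true labels; each of the
    ``n_label_shuffles`` null runs retrains from scratch (fresh
    initialization) on a shuffled copy of the labels.  S2 is the per-band
    75 % quantile (linear interpolation) across the null runs; by default
    the null coefficient vectors are first amplitude-matched to the true
    run (``null_quantile_mode="matched"``), with the raw per-band quantile
    (``"perband"``) and a single quantile pooled across bands and runs
    (``"pooled"``) available as alternatives.
    """
    _, S1, _ = train_fes(train, config, positive_class=positive_class)

    y = train.y.copy()
    nulls = []
    for j in range(config.n_label_shuffles):
        rng = np.random.default_rng([config.seed, 100 + j])
        shuffled = rng.permutation(y)
        tries = 0
        while np.array_equal(shuffled, y) and len(np.unique(y)) > 1:
            shuffled = rng.permutation(y)
            tries += 1
            if tries > 100:  # pragma: no cover - pathological tiny input
                raise RuntimeError("could not produce a changed label shuffle")
        null_cfg = replace(config, seed=int(np.random.default_rng(
            [config.seed, 200 + j]).integers(2**31)))
        _, IF, _ = train_fes(train, null_cfg, labels=shuffled,
                             positive_class=positive_class)
        nulls.append(IF)
    IF_history = np.array(nulls)
    if null_quantile_mode == "pooled":
        S2 = np.full(
            train.n_bands,
            np.quantile(IF_history, config.quantile, method="linear"),
        )
    elif null_quantile_mode == "perband":
        S2 = np.quantile(IF_history, config.quantile, axis=0, method="linear")
    elif null_quantile_mode == "matched":
        matched = _match_null_amplitude(IF_history, S1)
        S2 = np.quantile(matched, config.quantile, axis=0, method="linear")
    else:
        raise ValueError(f"unknown null_quantile_mode {null_quantile_mode!r}")
    IS = importance_score(S1, S2)
    return ImportanceReport(
        S1=S1,
        S2=S2,
        IS=IS,
        IF_history=IF_history,
        wavelengths_nm=train.wavelengths.copy(),
        meta={"seed": config.seed, "n_label_shuffles": config.n_label_shuffles,
              "quantile": config.quantile,
              "null_quantile_mode": null_quantile_mode},
    )


def importance_score(S1: np.ndarray, S2: np.ndarray) -> np.ndarray:
    """IS = log(1e-10 + S1/S2), natural log, floored at log(1e-10)."""
    S1 = np.asarray(S1, dtype=float)
    S2 = np.asarray(S2, dtype=float)
    return np.log(1e-10 + S1 / S2)


def select_top(
    report: ImportanceReport, top_fraction: float = 0.10
) -> SelectionResult:
    """Keep the floor(top_fraction * L) highest-IS bands, drop negatives.

    Ties at the cutoff go to the lower band index.  All-negative IS yields
    an empty selection with a warning.
    """
    IS = report.IS
    L = IS.size
    n_keep = int(np.floor(top_fraction * L))
    order = np.lexsort((np.arange(L), -IS))  # IS desc, index asc on ties
    top = order[:n_keep]
    kept = np.sort(top[IS[top] >= 0])
    if kept.size == 0:
        warnings.warn("all importance scores negative: empty selection",
                      stacklevel=2)
    report.selected = kept
    return SelectionResult(
        indices=kept,
        wavelengths_nm=report.wavelengths_nm[kept],
        criterion_curve=IS,
        best_value=float(IS.max()) if L else float("nan"),
        meta={
            "algorithm": "cnn-fes",
            "top_fraction": top_fraction,
            "n_bands_total": L,
            **report.meta,
        },
    )
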