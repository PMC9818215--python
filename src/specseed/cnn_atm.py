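"""Attention CNN classifier for 1-D reflectance spectra.

An attention-score (AS) block — squeeze-excitation over the L band-channels
with bottleneck ratio r = 8 and no biases — rescales each band by a sigmoid
gate in (0, 1), and the reweighted spectrum passes through three 1-D conv
blocks (16/64/128 kernels of width 3, ELU, max-pool 2 stride 1) to a softmax
over the two classes.  Trained with Adam (beta1 = 0.9, initial rate 1e-3,
inverse-time decay) on cross-entropy plus L2 on the conv kernels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import SpectraDataset
from .nn.core import (
    Conv1D,
    ELU,
    Dense,
    ExpandDims,
    Flatten,
    MaxPool1D,
    Network,
    SEGate,
    fit_network,
)

_CONV_FILTERS = (16, 64, 128)
_CONV_WIDTH = 3


@dataclass
class ATMConfig:
    """Training protocol of the attention classifier."""

    epochs: int = 200
    batch_size: int = 32
    weight_decay: float = 0.008
    lr0: float = 0.001
    adam_beta1: float = 0.9
    lr_decay: float = 1e-4
    r: int = 8
    use_attention: bool = True  # False: ablation, gate replaced by identity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


def as_forward(x: np.ndarray, gate: SEGate) -> np.ndarray:
    """Apply the attention gate to a batch (or single) spectrum."""
    x2 = np.atleast_2d(np.asarray(x, dtype=np.float32))
    out = gate.forward(x2, train=False)
    return out[0] if np.asarray(x).ndim == 1 else out


def atm_layer_lengths(L: int, n_blocks: int = 3) -> list[int]:
    """Sequence lengths through the conv stack (conv width 3, pool 2/1)."""
    lengths = [L]
    cur = L
    for _ in range(n_blocks):
        cur = cur - (_CONV_WIDTH - 1)  # conv
        lengths.append(cur)
        if cur >= 2:
            cur = cur - 1  # pool
        lengths.append(cur)
    return lengths


def build_atm_network(L: int, config: ATMConfig, rng: np.random.Generator) -> Network:
    """AS gate -> three conv/pool blocks -> flatten -> softmax(2)."""
    if L < 3:
        raise ValueError("need at least 3 bands")
    n_blocks = 3
    while n_blocks > 1 and L - 3 * n_blocks < 0:
        n_blocks -= 1
    if n_blocks < 3:
        warnings.warn(
            f"conv depth reduced to {n_blocks} block(s) for L={L}", stacklevel=2
        )
    layers: list = []
    if config.use_attention:
        layers.append(SEGate(L, r=config.r, rng=rng))
    layers.append(ExpandDims())
    in_ch = 1
    cur = L
    for b in range(n_blocks):
        layers += [Conv1D(in_ch, _CONV_FILTERS[b], _CONV_WIDTH, rng), ELU(),
                   MaxPool1D()]
        in_ch = _CONV_FILTERS[b]
        cur = cur - 2
        cur = cur - 1 if cur >= 2 else cur
    layers += [Flatten(), Dense(cur * in_ch, 2, rng)]
    return Network(layers)


@dataclass
class ATMModel:
    network: Network
    config: ATMConfig
    wavelengths_nm: np.ndarray

    @property
    def as_gate(self) -> SEGate:
        first = self.network.layers[0]
        if not isinstance(first, SEGate):
            raise AttributeError("model was built without the attention gate")
        return first

    # -------------------------------------------------------------- persist
    def save(self, path: str | Path) -> None:
        """Portable archive: weights npz + sidecar JSON with config/grid."""
        path = Path(path)
        arrays = {
            f"p{i}": p.value for i, p in enumerate(self.network.params())
        }
        np.savez(path, **arrays)
        meta = {
            "config": self.config.__dict__,
            "wavelengths_nm": self.wavelengths_nm.tolist(),
        }
        Path(str(path) + ".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "ATMModel":
        path = Path(path)
        meta = json.loads(Path(str(path) + ".json").read_text())
        config = ATMConfig(**meta["config"])
        wl = np.array(meta["wavelengths_nm"])
        net = build_atm_network(wl.size, config, np.random.default_rng(0))
        npz_path = path if path.suffix == ".npz" else Path(str(path) + ".npz")
        with np.load(npz_path) as data:
            for i, p in enumerate(net.params()):
                p.value = data[f"p{i}"]
        return cls(net, config, wl)


def _one_hot(codes: np.ndarray) -> np.ndarray:
    out = np.zeros((codes.size, 2))
    out[np.arange(codes.size), codes] = 1.0
    return out


def train_atm(
    train: SpectraDataset,
    config: ATMConfig,
    test: SpectraDataset | None = None,
    positive_class: str = "defective",
) -> tuple[ATMModel, dict[str, np.ndarray]]:
    """Train the classifier on standardized spectra.

    History records per-epoch mean training loss and, when a test set is
    given, per-epoch train/test accuracy and loss.
    """
    y = _one_hot(train.label_codes(positive_class))
    rng_init = np.random.default_rng([config.seed, 1])
    rng_batch = np.random.default_rng([config.seed, 2])
    net = build_atm_network(train.n_bands, config, rng_init)
    eval_sets = {}
    if test is not None:
        eval_sets["test"] = (
            test.X.astype(np.float32),
            _one_hot(test.label_codes(positive_class)),
        )
    history = fit_network(
        net,
        train.X,
        y,
        epochs=config.epochs,
        batch_size=config.batch_size,
        lr0=config.lr0,
        beta1=config.adam_beta1,
        lr_decay=config.lr_decay,
        weight_decay=config.weight_decay,
        rng=rng_batch,
        eval_sets=eval_sets,
    )
    return ATMModel(net, config, train.wavelengths.copy()), history


def predict(
    model: ATMModel, ds: SpectraDataset, positive_class: str = "defective"
) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and softmax probabilities for standardized spectra."""
    if ds.n_bands != model.wavelengths_nm.size or not np.allclose(
        ds.wavelengths, model.wavelengths_nm
    ):
        expected = ", ".join(f"{w:.1f}" for w in model.wavelengths_nm[:8])
        raise ValueError(
            f"band mismatch: model expects {model.wavelengths_nm.size} bands "
            f"starting [{expected}, ...]"
        )
    probs = model.network.predict_proba(ds.X.astype(np.float32))
    codes = probs.argmax(axis=1)
    names = np.array(["healthy" if positive_class == "defective" else "defective",
                      positive_class])
    return names[codes], probs
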