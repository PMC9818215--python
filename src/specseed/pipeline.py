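"""YAML-configured end-to-end runner: extract -> preprocess -> select ->
train -> evaluate, with every artifact stamped by the config hash."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classic_select import cars_select, spa_select
from .cnn_atm import ATMConfig, predict as atm_predict, train_atm
from .cnn_fes import FESConfig, permutation_importance, select_top
from .cube import calibrate_reflectance, drop_first_bands, extract_mean_spectra, segment_seeds
from .dataset import SpectraDataset
from .envi import read_envi
from .evaluate import confusion_and_metrics, fit_baseline, split_train_test
from .grid import WavelengthGrid
from .preprocess import PreprocessSpec, zscore
from .synthetic import SyntheticConfig, generate_dataset


@dataclass
class RunConfig:
    """Validated run description; exactly one data source."""

    source: dict
    preprocess: dict = field(default_factory=lambda: {"branch": "de"})
    crop: dict = field(default_factory=dict)
    selector: dict = field(default_factory=lambda: {"algo": "none"})
    model: dict = field(default_factory=lambda: {"name": "SVM"})
    seed: int = 0
    split_ratio: float = 0.7
    outdir: str = "runs"

    def __post_init__(self) -> None:
        keys = [k for k in ("synthetic", "spectra_csv", "cube") if k in self.source]
        if len(keys) != 1:
            raise ValueError(
                "config must name exactly one data source: synthetic | "
                "spectra_csv | cube"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(
            {
                "source": self.source, "preprocess": self.preprocess,
                "crop": self.crop, "selector": self.selector,
                "model": self.model, "seed": self.seed,
                "split_ratio": self.split_ratio,
            },
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _load_source(cfg: RunConfig) -> SpectraDataset:
    src = cfg.source
    if "synthetic" in src:
        params = dict(src["synthetic"])
        n_bands = params.pop("n_bands", None)
        if n_bands is not None:
            params["grid"] = WavelengthGrid.default(int(n_bands))
        params.setdefault("seed", cfg.seed)
        return generate_dataset(SyntheticConfig(**params))
    if "spectra_csv" in src:
        return SpectraDataset.from_csv(src["spectra_csv"])
    cube_cfg = src["cube"]
    raw = read_envi(cube_cfg["raw"])
    white = read_envi(cube_cfg["white"])
    dark = read_envi(cube_cfg["dark"])
    from .cube import CalibrationPair

    refl = calibrate_reflectance(raw, CalibrationPair(white.data, dark.data))
    mask = segment_seeds(refl, min_area=int(cube_cfg.get("min_area", 20)))
    ds = extract_mean_spectra(refl, mask)
    labels_csv = cube_cfg.get("labels")
    if labels_csv:
        import pandas as pd

        lab = pd.read_csv(labels_csv)
        ds.y = lab["label"].to_numpy()[: ds.n_samples]
    return ds


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute all stages; returns a dict of artifact paths.

    Artifacts: spectra CSV, selection JSON, model archive, evaluation JSON,
    and a timestamped JSON-lines log carrying versions, seeds and the
    config hash.
    """
    outdir = Path(config.outdir) / time.strftime("%Y%m%d-%H%M%S")
    outdir.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    log_path = outdir / "run.log.jsonl"
    artifacts: dict[str, Path] = {"log": log_path}

    def log(stage: str, **kv) -> None:
        entry = {
            "ts": time.strftime("%Y-%m-%dT%H:%M:%S"), "stage": stage,
            "config_hash": digest, "version": __version__, **kv,
        }
        with log_path.open("a") as fh:
            fh.write(json.dumps(entry, default=str) + "\n")

    log("start", seed=config.seed)

    ds = _load_source(config)
    if config.crop.get("drop_first"):
        ds = drop_first_bands(ds, int(config.crop["drop_first"]))
    spectra_path = outdir / "spectra.csv"
    ds.to_csv(spectra_path)
    artifacts["spectra"] = spectra_path
    log("extract", n_samples=ds.n_samples, n_bands=ds.n_bands)

    train, test = split_train_test(ds, ratio=config.split_ratio, seed=config.seed)
    spec = PreprocessSpec(
        branch=config.preprocess.get("branch", "de"),
        sg_window=int(config.preprocess.get("sg_window", 11)),
        sg_polyorder=int(config.preprocess.get("sg_polyorder", 1)),
    )
    train_pp = spec.fit_apply(train)
    test_pp = spec.apply(test)
    log("preprocess", branch=spec.branch)

    algo = config.selector.get("algo", "none")
    sel_params = {k: v for k, v in config.selector.items() if k != "algo"}
    if algo == "none":
        sel_idx = np.arange(train_pp.n_bands)
        sel_result = None
    elif algo == "spa":
        sel_result = spa_select(train_pp, seed=config.seed, **sel_params)
        sel_idx = sel_result.indices
    elif algo == "cars":
        sel_result = cars_select(train_pp, seed=config.seed, **sel_params)
        sel_idx = sel_result.indices
    elif algo == "cnn-fes":
        fes_cfg = FESConfig(seed=config.seed, **sel_params)
        tr_std, _ = zscore(train_pp)
        report = permutation_importance(tr_std, fes_cfg)
        sel_result = select_top(report, fes_cfg.top_fraction)
        sel_idx = sel_result.indices
        report.to_json(outdir / "importance.json")
        artifacts["importance"] = outdir / "importance.json"
    else:
        raise ValueError(f"unknown selector {algo!r}")
    if sel_result is not None:
        sel_path = outdir / "selection.json"
        sel_result.meta["config_hash"] = digest
        sel_result.to_json(sel_path)
        artifacts["selection"] = sel_path
    log("select", algo=algo, n_bands=int(len(sel_idx)))

    train_sel = train_pp.select_bands(sel_idx)
    test_sel = test_pp.select_bands(sel_idx)
    train_std, test_std = zscore(train_sel, test_sel)

    model_name = config.model.get("name", "SVM")
    model_params = {k: v for k, v in config.model.items() if k != "name"}
    eval_rows = {}
    if model_name == "CNN-ATM":
        atm_cfg = ATMConfig(seed=config.seed, **model_params)
        model, history = train_atm(train_std, atm_cfg, test=test_std)
        model_path = outdir / "model.npz"
        model.save(model_path)
        artifacts["model"] = model_path
        hist_path = outdir / "history.csv"
        import pandas as pd

        pd.DataFrame({k: v for k, v in history.items()}).to_csv(
            hist_path, index=False
        )
        artifacts["history"] = hist_path
        for name, part in (("train", train_std), ("test", test_std)):
            pred, _ = atm_predict(model, part)
            _, m = confusion_and_metrics(part.y, pred)
            eval_rows[name] = {"ac": m.ac, "se": m.se, "sp": m.sp}
    else:
        clf = fit_baseline(model_name, train_std)
        import pickle

        model_path = outdir / "model.pkl"
        model_path.write_bytes(pickle.dumps(clf))
        artifacts["model"] = model_path
        names = np.array(["healthy", "defective"])
        for name, part in (("train", train_std), ("test", test_std)):
            pred = names[clf.predict(part.X)]
            _, m = confusion_and_metrics(part.y, pred)
            eval_rows[name] = {"ac": m.ac, "se": m.se, "sp": m.sp}
    log("train", model=model_name)

    eval_path = outdir / "evaluation.json"
    eval_path.write_text(json.dumps(
        {"config_hash": digest, "model": model_name, "selector": algo,
         "n_bands": int(len(sel_idx)), "metrics": eval_rows}, indent=2,
    ))
    artifacts["evaluation"] = eval_path
    log("evaluate", **{f"{k}_ac": v["ac"] for k, v in eval_rows.items()})
    return artifacts
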