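"""Desk-scale capability benchmarks: everything runs in minutes on one CPU.

Two seeded end-to-end checks of the full pipeline (synthetic data ->
preprocessing -> network -> SGD training -> metrics):

* :func:`overfit_smoke` — memorisation capacity: the width-reduced model,
  dropout disabled, must drive its training L1 on 8 fixed images far below
  the first-epoch L1 within 300 steps.
* :func:`desk_capability` — generalisation: trained on 200 synthetic
  ear-field images (128 px, clipped-Gaussian counts, mean 20, sd 8,
  range [0, 45]) the model must beat the predict-the-training-mean
  baseline's MAE on 50 held-out images; reported as the median over seeds.

The 1/16-width model, 16-epoch schedule (SGD lr 0.01, momentum 0.9,
MultiStepLR at epochs 12/15, gamma 0.1, global gradient-norm clip 1.0) and
dataset sizes are the package's fixed desk-scale protocol.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from tempfile import TemporaryDirectory

import numpy as np

from .data import PreprocessSpec, load_arrays, load_manifest
from .model import ModelConfig, assemble_model
from .synthetic import SynthConfig, generate_dataset
from .training import TrainConfig, evaluate, train

#: preprocessing for from-scratch synthetic runs: centre to [-1, 1]
DESK_PREPROCESS = PreprocessSpec(size=128, mean=(0.5, 0.5, 0.5),
                                 std=(0.5, 0.5, 0.5))


def desk_synth_config(seed: int) -> SynthConfig:
    """The desk-scale ear-field condition: 128 px, counts ~ N(20, 8) in [0, 45]."""
    return SynthConfig.ear_field(image_size=128, count_mean=20.0, count_sd=8.0,
                                 count_min=0, count_max=45, seed=seed)


def desk_train_config(seed: int, epochs: int = 32) -> TrainConfig:
    # decay at 3/4 and 15/16 of the run, e.g. (24, 30) for 32 epochs
    milestones = (3 * epochs // 4, 15 * epochs // 16)
    return TrainConfig(epochs=epochs, batch_size=16, lr=0.01, momentum=0.9,
                       milestones=milestones, gamma=0.1, clip_norm=1.0,
                       seed=seed)


def _desk_arrays(n: int, data_seed: int,
                 workdir: str | Path | None = None) -> tuple[np.ndarray, np.ndarray]:
    cfg = desk_synth_config(data_seed)
    if workdir is None:
        with TemporaryDirectory() as tmp:
            generate_dataset(n, cfg, tmp)
            refs = load_manifest(Path(tmp) / "manifest.csv")
            return load_arrays(refs, DESK_PREPROCESS)
    generate_dataset(n, cfg, workdir)
    refs = load_manifest(Path(workdir) / "manifest.csv")
    return load_arrays(refs, DESK_PREPROCESS)


@dataclass
class OverfitResult:
    first_epoch_l1: float
    final_l1: float

    @property
    def ratio(self) -> float:
        return self.final_l1 / self.first_epoch_l1


def overfit_smoke(seed: int = 1, n_images: int = 8,
                  steps: int = 300) -> OverfitResult:
    """Train on `n_images` fixed images for `steps` full-batch steps,
    dropout disabled, and report first-epoch vs final training L1."""
    x, y = _desk_arrays(n_images, data_seed=seed * 1000 + 17)
    model_cfg = ModelConfig.tiny(seed=seed)
    model_cfg.head.dropout = 0.0
    model = assemble_model(model_cfg)
    cfg = desk_train_config(seed + 1, epochs=steps)
    cfg.batch_size = n_images
    cfg.milestones = (2 * steps // 3, 7 * steps // 8)
    result = train(model, (x, y), (x, y), cfg)
    l1 = [h["train_l1"] for h in result.history]
    return OverfitResult(first_epoch_l1=l1[0], final_l1=l1[-1])


@dataclass
class CapabilityResult:
    baseline_mae: float         # predict-the-training-mean on the test set
    model_maes: list[float]     # one per seed
    seeds: list[int]

    @property
    def median_mae(self) -> float:
        return float(np.median(self.model_maes))

    @property
    def median_improvement_pct(self) -> float:
        return 100.0 * (self.baseline_mae - self.median_mae) / self.baseline_mae


def desk_capability(seeds: tuple[int, ...] = (1, 2, 3), n_train: int = 200,
                    n_test: int = 50, epochs: int = 32,
                    verbose: bool = False) -> CapabilityResult:
    """Train one model per seed on the desk-scale condition and compare the
    held-out MAE with the constant training-mean predictor."""
    base_seed = seeds[0] * 7919
    x, y = _desk_arrays(n_train + n_test, data_seed=base_seed)
    xtr, ytr = x[:n_train], y[:n_train]
    xte, yte = x[n_train:], y[n_train:]
    baseline = float(np.mean(np.abs(yte - ytr.mean())))
    maes = []
    for seed in seeds:
        model = assemble_model(ModelConfig.tiny(seed=seed))
        result = train(model, (xtr, ytr), (xte, yte),
                       desk_train_config(seed + 100, epochs=epochs),
                       verbose=verbose)
        maes.append(evaluate(model, (xte, yte)).mae)
    return CapabilityResult(baseline_mae=baseline, model_maes=maes,
                            seeds=list(seeds))
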