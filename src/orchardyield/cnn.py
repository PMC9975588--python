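"""CNN yield regressor: architectures, tuning, cross-validation, ablation.

The network regresses per-tree fresh yield (kg) directly on the raw
multispectral reflectance block. Two architectures are provided:

* a *tunable* family — 3-4 convolutional blocks of
  ``conv -> BN -> pool -> conv -> BN -> pool -> ReLU`` followed by the
  attention head (global average pooling -> dense -> dropout -> dense(1)),
  searched by Bayesian (GP expected-improvement) optimization over filter
  counts, pool type, dense width, dropout and learning rate;
* the *final* fixed architecture — eight 3x3 convolutional layers, each
  followed by batch normalization and ReLU, with a max-pooling layer
  after every two convolutions, then global average pooling, a 100-unit
  dense layer and a single linear output.

Training is MSE/Adam, evaluated by seeded k-fold cross-validation; the
band-ablation harness retrains the same architecture on every requested
spectral-band subset.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from orchardyield.blocks import TreeBlockSet
from orchardyield.evaluation import EvalReport, regression_metrics
from orchardyield.nn import (
    AvgPool2D,
    BatchNorm,
    Conv2D,
    Dense,
    Dropout,
    GlobalAvgPool,
    MaxPool2D,
    ReLU,
    Sequential,
)
from orchardyield.tuning import Dim, GPOptimizer

logger = logging.getLogger("orchardyield")

FILTER_RANGE = (16, 128)
DENSE_RANGE = (30, 100)
LR_RANGE = (1e-4, 1e-2)
DROPOUT_RANGE = (0.0, 0.5)


@dataclass
class ArchConfig:
    """A point in the tunable-architecture search space."""

    n_conv_blocks: int = 3
    filters1: int = 32
    filters2: int = 64
    pool_type: str = "max"
    dense_units: int = 64
    dropout_rate: float = 0.2
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_conv_blocks not in (3, 4):
            raise ValueError("n_conv_blocks must be 3 or 4")
        for name in ("filters1", "filters2"):
            v = getattr(self, name)
            if not FILTER_RANGE[0] <= v <= FILTER_RANGE[1]:
                raise ValueError(f"{name}={v} outside {FILTER_RANGE}")
        if self.pool_type not in ("max", "avg"):
            raise ValueError("pool_type must be 'max' or 'avg'")
        if not DENSE_RANGE[0] <= self.dense_units <= DENSE_RANGE[1]:
            raise ValueError(f"dense_units={self.dense_units} outside {DENSE_RANGE}")
        if not DROPOUT_RANGE[0] <= self.dropout_rate <= DROPOUT_RANGE[1]:
            raise ValueError("dropout_rate outside [0, 0.5]")
        if not LR_RANGE[0] <= self.learning_rate <= LR_RANGE[1]:
            raise ValueError("learning_rate outside [1e-4, 1e-2]")


@dataclass
class CVResult:
    """Per-fold metrics plus the fold assignment that produced them."""

    folds: list[EvalReport]
    fold_assignments: np.ndarray
    histories: list[dict] = field(default_factory=list)

    def _agg(self, attr: str) -> tuple[float, float]:
        vals = np.array([getattr(f, attr) for f in self.folds], dtype=float)
        return float(np.nanmean(vals)), float(np.nanstd(vals, ddof=1))

    @property
    def mean_r2(self) -> float:
        return self._agg("r2")[0]

    @property
    def sd_r2(self) -> float:
        return self._agg("r2")[1]

    @property
    def mean_rmse(self) -> float:
        return self._agg("rmse_kg")[0]

    def summary(self) -> pd.DataFrame:
        rows = [f.as_dict() | {"fold": i} for i, f in enumerate(self.folds)]
        return pd.DataFrame(rows)


def _pool(pool_type: str, ceil_mode: bool):
    return (MaxPool2D if pool_type == "max" else AvgPool2D)(ceil_mode=ceil_mode)


def build_cnn(arch: ArchConfig, input_shape: tuple, seed: int = 0) -> Sequential:
    """Build a tunable-family model for ``input_shape`` (H, W, bands).

    Each conv block is conv -> BN -> pool -> conv -> BN -> pool -> ReLU;
    pooling uses ceil ("same"-edge) semantics so that deep configurations
    remain valid on 21x21 inputs. The head is GAP -> dense -> dropout ->
    dense(1). Identical (arch, seed) pairs give identical initial weights.
    """
    layers = []
    for _ in range(arch.n_conv_blocks):
        layers += [
            Conv2D(arch.filters1),
            BatchNorm(),
            _pool(arch.pool_type, ceil_mode=True),
            Conv2D(arch.filters2),
            BatchNorm(),
            _pool(arch.pool_type, ceil_mode=True),
            ReLU(),
        ]
    layers += [
        GlobalAvgPool(),
        Dense(arch.dense_units),
        ReLU(),
        Dropout(arch.dropout_rate),
        Dense(1),
    ]
    try:
        return Sequential(layers, input_shape, seed=seed, lr=arch.learning_rate)
    except ValueError as exc:
        raise ValueError(
            f"architecture infeasible for input {input_shape}: {exc}"
        ) from exc


#: default filter widths of the eight convolutional layers (doubling after
#: pooling); the layer counts, not the widths, define the architecture.
FINAL_FILTERS = (16, 16, 32, 32, 64, 64, 64, 64)


def build_final_architecture(
    input_shape: tuple = (21, 21, 4),
    seed: int = 0,
    filters: tuple = FINAL_FILTERS,
    dense_units: int = 100,
    learning_rate: float = 1e-3,
) -> Sequential:
    """The final optimized architecture.

    Eight 3x3 convolutional layers, each followed by batch normalization
    and ReLU; a max-pooling layer after every two convolutions (four in
    total, floor/valid edge semantics: 21 -> 10 -> 5 -> 2 -> 1, and
    61 -> 30 -> 15 -> 7 -> 3); then global average pooling, a
    ``dense_units``-neuron dense layer and a single linear output.
    """
    if len(filters) != 8:
        raise ValueError("final architecture has exactly 8 conv layers")
    layers = []
    for i, f in enumerate(filters):
        layers += [Conv2D(f), BatchNorm(), ReLU()]
        if i % 2 == 1:
            layers.append(MaxPool2D(ceil_mode=False))
    layers += [GlobalAvgPool(), Dense(dense_units), Dense(1)]
    return Sequential(layers, input_shape, seed=seed, lr=learning_rate)


DEFAULT_SEARCH_SPACE = (
    Dim("n_conv_blocks", "cat", choices=(3, 4)),
    Dim("filters1", "logint", *FILTER_RANGE),
    Dim("filters2", "logint", *FILTER_RANGE),
    Dim("pool_type", "cat", choices=("max", "avg")),
    Dim("dense_units", "int", *DENSE_RANGE),
    Dim("dropout_rate", "float", *DROPOUT_RANGE),
    Dim("learning_rate", "logfloat", *LR_RANGE),
)


def tune_hyperparameters(
    blocks: TreeBlockSet,
    space=DEFAULT_SEARCH_SPACE,
    max_trials: int = 50,
    batch_size: int = 128,
    epochs: int = 100,
    seed: int = 0,
    val_fraction: float = 0.2,
) -> tuple[ArchConfig, list[tuple[ArchConfig, float]]]:
    """Bayesian architecture search minimizing held-out validation MSE.

    A single stratification-free random split reserves ``val_fraction`` of
    the labelled trees for validation across all trials. Returns the
    best configuration and the full trial log.
    """
    if max_trials < 1:
        raise ValueError("max_trials must be >= 1")
    data = blocks.labelled()
    if len(data) < 2 * batch_size:
        logger.warning(
            "only %d labelled trees for tuning (batch size %d); "
            "results may be unstable",
            len(data),
            batch_size,
        )
    rng = np.random.default_rng(seed)
    n = len(data)
    order = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    x_tr, y_tr = data.blocks[tr_idx], data.yields_kg[tr_idx]
    x_val, y_val = data.blocks[val_idx], data.yields_kg[val_idx]
    input_shape = data.blocks.shape[1:]

    trial_log: list[tuple[ArchConfig, float]] = []

    def objective(params: dict) -> float:
        arch = ArchConfig(**params)
        model = build_cnn(arch, input_shape, seed=seed)
        model.fit(
            x_tr, y_tr, epochs=epochs, batch_size=batch_size, seed=seed
        )
        val_mse = float(np.mean((model.predict(x_val) - y_val) ** 2))
        trial_log.append((arch, val_mse))
        logger.info("trial %d: val MSE %.3f (%s)", len(trial_log), val_mse, arch)
        return val_mse

    opt = GPOptimizer(space, seed=seed)
    best_params, _ = opt.minimize(objective, max_trials)
    return ArchConfig(**best_params), trial_log


def _make_builder(arch):
    """Normalize the model spec: None -> final architecture, ArchConfig ->
    tunable family, callable -> itself."""
    if arch is None:
        return lambda shape, seed: build_final_architecture(shape, seed=seed)
    if isinstance(arch, ArchConfig):
        return lambda shape, seed: build_cnn(arch, shape, seed=seed)
    if callable(arch):
        return arch
    raise TypeError("arch must be None, an ArchConfig, or a builder callable")


def kfold_assignments(n: int, k: int, seed: int) -> np.ndarray:
    """Seeded random k-fold partition; fold sizes differ by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"n={n} smaller than k={k}")
    rng = np.random.default_rng(seed)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    folds = np.repeat(np.arange(k), sizes)
    rng.shuffle(folds)
    return folds


def cross_validate(
    blocks: TreeBlockSet,
    arch=None,
    k: int = 5,
    seed: int = 0,
    epochs: int = 100,
    batch_size: int = 128,
    return_predictions: bool = False,
):
    """k-fold cross-validation of a CNN on labelled tree blocks.

    For each fold a fresh model (same seed-derived initialization) is
    trained on the other k-1 folds and evaluated on the held-out fold.
    A fold with constant observed yields gets an undefined (NaN) R^2 and
    is flagged in the log. With ``return_predictions`` the out-of-fold
    prediction for every tree is also returned, aligned to ``tree_ids``.
    """
    data = blocks.labelled()
    builder = _make_builder(arch)
    folds = kfold_assignments(len(data), k, seed)
    input_shape = data.blocks.shape[1:]
    reports, histories = [], []
    oof = np.full(len(data), np.nan)
    for fold in range(k):
        test = folds == fold
        model = builder(input_shape, seed + fold)
        hist = model.fit(
            data.blocks[~test],
            data.yields_kg[~test],
            epochs=epochs,
            batch_size=batch_size,
            seed=seed + fold,
        )
        pred = model.predict(data.blocks[test])
        oof[test] = pred
        rep = regression_metrics(data.yields_kg[test], pred)
        if np.isnan(rep.r2):
            logger.warning("fold %d: constant observed yields, R^2 undefined", fold)
        reports.append(rep)
        histories.append(hist)
        logger.info(
            "fold %d/%d: R2=%.3f RMSE=%.2f kg", fold + 1, k, rep.r2, rep.rmse_kg
        )
    result = CVResult(reports, folds, histories)
    if return_predictions:
        return result, pd.Series(oof, index=data.tree_ids)
    return result


def enumerate_band_subsets(
    bands: tuple[str, ...], include_full: bool = False
) -> list[tuple[str, ...]]:
    """All non-empty proper subsets of ``bands`` (optionally + full set).

    For the four canonical bands this yields the 14 reduced-model
    configurations (15 with the full set).
    """
    subsets = [
        combo
        for r in range(1, len(bands) + (1 if include_full else 0))
        for combo in itertools.combinations(bands, r)
    ]
    return subsets


def band_ablation(
    blocks: TreeBlockSet,
    subsets=None,
    arch=None,
    k: int = 5,
    seed: int = 0,
    epochs: int = 100,
    batch_size: int = 128,
) -> dict[tuple[str, ...], CVResult]:
    """Retrain and cross-validate the model on each spectral-band subset.

    ``subsets=None`` enumerates every non-empty proper subset of the
    stack's bands (14 reduced models for 4 bands); each subset's model has
    input depth equal to the subset size and is evaluated with the same
    fold protocol.
    """
    if subsets is None:
        subsets = enumerate_band_subsets(blocks.band_names)
    results: dict[tuple[str, ...], CVResult] = {}
    for sub in subsets:
        sub = tuple(sub)
        if not sub:
            raise ValueError("band subset must be non-empty")
        reduced = blocks.select_bands(sub)
        results[sub] = cross_validate(
            reduced, arch=arch, k=k, seed=seed, epochs=epochs, batch_size=batch_size
        )
        logger.info("bands %s: mean R2 %.3f", "+".join(sub), results[sub].mean_r2)
    return results
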