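"""Engineered-feature baseline regressors.

Comparison models fitted on the 46-column feature table with the same
seeded k-fold protocol as the CNN: bidirectional stepwise linear
regression (AIC), support-vector regression, random forest, gradient
boosting (XGBoost) and a dense neural network, each tuned by a seeded,
budget-limited random search over conventional hyperparameter spaces.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import ParameterSampler
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

from orchardyield.cnn import kfold_assignments
from orchardyield.evaluation import regression_metrics
from orchardyield.features import FeatureTable

logger = logging.getLogger("orchardyield")

MODEL_KINDS = ("stepwise_linear", "svr", "rf", "xgb", "dnn")
FEATURE_SETS = ("vi", "texture", "vi+texture", "reflectance_summary")


@dataclass
class BaselineSpec:
    """Which model on which feature set, with a tuning budget."""

    model_kind: str
    feature_set: str = "vi+texture"
    tuning_budget: int = 10

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(
                f"unknown model_kind {self.model_kind!r}; valid kinds: "
                + ", ".join(MODEL_KINDS)
            )
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(
                f"unknown feature_set {self.feature_set!r}; valid sets: "
                + ", ".join(FEATURE_SETS)
            )


class StepwiseLinearModel:
    """OLS with bidirectional stepwise selection by AIC."""

    def __init__(self, selected: list[str], result, trace: list[tuple[str, str, float]]):
        self.selected = selected
        self.result = result
        self.trace = trace

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        x = sm.add_constant(features[self.selected], has_constant="add")
        return np.asarray(self.result.predict(x))


def _drop_collinear(x: pd.DataFrame) -> pd.DataFrame:
    """Drop exact-duplicate / zero-variance columns, keeping the first."""
    keep, seen = [], set()
    for col in x.columns:
        v = x[col].to_numpy()
        if np.allclose(v, v[0]):
            logger.warning("dropping constant column %r", col)
            continue
        key = hashlib.sha1(np.round(v, 12).tobytes()).hexdigest()
        if key in seen:
            logger.warning("dropping duplicated column %r", col)
            continue
        seen.add(key)
        keep.append(col)
    return x[keep]


def stepwise_linear(
    features: pd.DataFrame, targets, max_steps: int = 100
) -> StepwiseLinearModel:
    """Bidirectional stepwise OLS starting from the intercept-only model.

    At each step the single add-or-remove move with the best AIC
    improvement is taken; the procedure stops when no move improves AIC.
    Duplicated or constant columns are dropped up front with a warning, so
    predictions are invariant to duplicating a predictor.
    """
    y = np.asarray(targets, dtype=float)
    x = _drop_collinear(features.copy())
    if len(x) <= 1:
        raise ValueError("need more observations than 1")
    candidates = list(x.columns)

    def _fit(cols: list[str]):
        design = sm.add_constant(x[cols] if cols else pd.DataFrame(index=x.index),
                                 has_constant="add")
        return sm.OLS(y, design).fit()

    selected: list[str] = []
    current = _fit(selected)
    trace: list[tuple[str, str, float]] = [("start", "", current.aic)]
    for _ in range(max_steps):
        moves = []
        for col in candidates:
            if col not in selected:
                res = _fit(selected + [col])
                moves.append(("add", col, res.aic))
        for col in selected:
            res = _fit([c for c in selected if c != col])
            moves.append(("drop", col, res.aic))
        if not moves:
            break
        action, col, aic = min(moves, key=lambda m: m[2])
        if aic >= current.aic - 1e-9:
            break
        selected = (
            selected + [col] if action == "add" else [c for c in selected if c != col]
        )
        current = _fit(selected)
        trace.append((action, col, current.aic))
    return StepwiseLinearModel(selected, current, trace)


# conventional published search spaces; budget-limited random search
_SEARCH_SPACES = {
    "svr": {
        "svr__C": np.logspace(-1, 3, 20),
        "svr__gamma": ["scale", "auto"],
        "svr__epsilon": [0.01, 0.1, 0.5, 1.0],
    },
    "rf": {
        "n_estimators": [100, 200, 500, 1000],
        "max_depth": [3, 5, 10, 20, None],
        "min_samples_leaf": [1, 2, 5],
        "max_features": [0.3, 0.6, 1.0],
    },
    "xgb": {
        "n_estimators": [100, 200, 500],
        "learning_rate": [0.01, 0.05, 0.1, 0.3],
        "max_depth": [3, 5, 7, 10],
        "subsample": [0.7, 1.0],
        "colsample_bytree": [0.7, 1.0],
    },
    "dnn": {
        "mlpregressor__hidden_layer_sizes": [
            (32,), (64,), (128,), (256,),
            (64, 32), (128, 64), (256, 128),
            (128, 64, 32), (256, 128, 64),
        ],
        "mlpregressor__alpha": [1e-5, 1e-4, 1e-3],
        "mlpregressor__learning_rate_init": [1e-3, 1e-2],
    },
}


def _estimator(kind: str, seed: int):
    if kind == "svr":
        return make_pipeline(StandardScaler(), SVR())
    if kind == "rf":
        return RandomForestRegressor(random_state=seed)
    if kind == "xgb":
        return XGBRegressor(random_state=seed, verbosity=0, n_jobs=1)
    if kind == "dnn":
        return make_pipeline(
            StandardScaler(),
            MLPRegressor(random_state=seed, max_iter=500),
        )
    raise ValueError(f"unknown model_kind {kind!r}")


def fit_tuned_model(
    spec: BaselineSpec, features: pd.DataFrame, targets, seed: int = 0
):
    """Fit one baseline with seeded random-search tuning.

    An inner 80/20 split selects the hyperparameters with lowest
    validation MSE within ``spec.tuning_budget`` samples; the winning
    configuration is refitted on all data. Deterministic under seed.
    """
    y = np.asarray(targets, dtype=float)
    bad = features.columns[~np.isfinite(features.to_numpy()).all(axis=0)]
    if len(bad):
        raise ValueError(f"non-finite feature columns: {', '.join(bad)}")
    if spec.model_kind == "stepwise_linear":
        return stepwise_linear(features, y)
    rng = np.random.default_rng(seed)
    n = len(features)
    order = rng.permutation(n)
    n_val = max(1, n // 5)
    val_idx, tr_idx = order[:n_val], order[n_val:]
    x_np = features.to_numpy()
    sampler = ParameterSampler(
        _SEARCH_SPACES[spec.model_kind],
        n_iter=spec.tuning_budget,
        random_state=seed,
    )
    best_params, best_mse = None, np.inf
    for params in sampler:
        est = _estimator(spec.model_kind, seed)
        est.set_params(**params)
        est.fit(x_np[tr_idx], y[tr_idx])
        mse = float(np.mean((est.predict(x_np[val_idx]) - y[val_idx]) ** 2))
        if mse < best_mse:
            best_params, best_mse = params, mse
    est = _estimator(spec.model_kind, seed)
    est.set_params(**best_params)
    est.fit(x_np, y)
    return est


def _feature_columns(table: FeatureTable, feature_set: str) -> list[str]:
    if feature_set == "vi":
        return table.vi_columns
    if feature_set == "texture":
        return table.texture_columns
    if feature_set == "vi+texture":
        return table.feature_columns
    if feature_set == "reflectance_summary":
        # per-band block-mean reflectance proxies: the GLCM mean features
        return [c for c in table.table.columns if c.startswith("tex_mean_")]
    raise ValueError(f"unknown feature_set {feature_set!r}")


def _fold_hash(folds: np.ndarray) -> str:
    return hashlib.sha1(folds.astype(np.int64).tobytes()).hexdigest()[:12]


def compare_models(
    features: FeatureTable,
    blocks=None,
    models: tuple[str, ...] = MODEL_KINDS,
    feature_sets: tuple[str, ...] = ("vi", "texture", "vi+texture"),
    k: int = 5,
    seed: int = 0,
    tuning_budget: int = 5,
    cnn_epochs: int = 25,
    cnn_arch=None,
) -> pd.DataFrame:
    """Cross-validated comparison of baselines (and optionally the CNN).

    Every model x feature-set cell is evaluated on the *identical* seeded
    fold partition (the fold hash is logged and asserted equal); the CNN,
    when tree blocks are supplied, uses the same partition on the same
    trees. Returns a long-format frame with mean +/- sd of R^2, RMSE and
    NRMSE per cell.
    """
    df = features.table.dropna(subset=["yield_kg"]).reset_index(drop=True)
    y = df["yield_kg"].to_numpy()
    n = len(df)
    folds = kfold_assignments(n, k, seed)
    ref_hash = _fold_hash(folds)
    rows = []
    for kind in models:
        for fset in feature_sets:
            cols = _feature_columns(features, fset)
            x = df[cols]
            fold_reports = []
            assert _fold_hash(folds) == ref_hash
            for fold in range(k):
                test = folds == fold
                spec = BaselineSpec(kind, fset, tuning_budget)
                model = fit_tuned_model(
                    spec, x[~test].reset_index(drop=True), y[~test], seed=seed
                )
                pred = (
                    model.predict(x[test].reset_index(drop=True))
                    if kind == "stepwise_linear"
                    else model.predict(x[test].to_numpy())
                )
                fold_reports.append(regression_metrics(y[test], pred))
            r2 = np.array([r.r2 for r in fold_reports])
            rmse = np.array([r.rmse_kg for r in fold_reports])
            nrmse = np.array([r.nrmse_pct for r in fold_reports])
            rows.append(
                {
                    "model": kind,
                    "feature_set": fset,
                    "mean_r2": float(np.nanmean(r2)),
                    "sd_r2": float(np.nanstd(r2, ddof=1)),
                    "mean_rmse_kg": float(rmse.mean()),
                    "sd_rmse_kg": float(rmse.std(ddof=1)),
                    "mean_nrmse_pct": float(nrmse.mean()),
                    "fold_hash": ref_hash,
                }
            )
            logger.info(
                "%s / %s: R2 %.3f +/- %.3f",
                kind,
                fset,
                rows[-1]["mean_r2"],
                rows[-1]["sd_r2"],
            )
    if blocks is not None:
        data = blocks.labelled()
        id_order = {t: i for i, t in enumerate(df["tree_id"])}
        keep = np.array([t in id_order for t in data.tree_ids])
        if keep.sum() != n:
            logger.warning(
                "CNN comparison uses %d/%d trees shared with the feature table",
                int(keep.sum()),
                n,
            )
        # align blocks to the feature-table row order so folds match
        sel = np.argsort([id_order[t] for t in data.tree_ids[keep]])
        sub_idx = np.nonzero(keep)[0][sel]
        from orchardyield.blocks import TreeBlockSet

        aligned = TreeBlockSet(
            data.blocks[sub_idx],
            data.tree_ids[sub_idx],
            data.yields_kg[sub_idx],
            data.radius_px,
            data.band_names,
        )
        cv = _cnn_with_folds(aligned, folds[: len(aligned)], cnn_arch, seed, cnn_epochs)
        r2 = np.array([r.r2 for r in cv.folds])
        rmse = np.array([r.rmse_kg for r in cv.folds])
        nrmse = np.array([r.nrmse_pct for r in cv.folds])
        rows.append(
            {
                "model": "cnn",
                "feature_set": "reflectance_blocks",
                "mean_r2": float(np.nanmean(r2)),
                "sd_r2": float(np.nanstd(r2, ddof=1)),
                "mean_rmse_kg": float(rmse.mean()),
                "sd_rmse_kg": float(rmse.std(ddof=1)),
                "mean_nrmse_pct": float(nrmse.mean()),
                "fold_hash": ref_hash,
            }
        )
    return pd.DataFrame(rows)


def _cnn_with_folds(blocks, folds, arch, seed, epochs):
    """Cross-validate the CNN on a caller-supplied fold assignment."""
    from orchardyield.cnn import CVResult, _make_builder

    builder = _make_builder(arch)
    data = blocks.labelled()
    input_shape = data.blocks.shape[1:]
    reports = []
    for fold in range(int(folds.max()) + 1):
        test = folds == fold
        model = builder(input_shape, seed + fold)
        model.fit(
            data.blocks[~test],
            data.yields_kg[~test],
            epochs=epochs,
            batch_size=128,
            seed=seed + fold,
        )
        pred = model.predict(data.blocks[test])
        reports.append(regression_metrics(data.yields_kg[test], pred))
    return CVResult(reports, folds)
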