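"""Accuracy metrics and within-field spatial-variability analysis.

Core metrics: R^2 (1 - SSres/SStot), RMSE (kg/tree), NRMSE (RMSE divided
by the mean observed yield, in percent), bias (mean predicted - observed)
and the interquartile range of predictions. Distribution agreement uses a
Welch two-sample two-tailed t-test. Spatial analyses: per-row statistics
(mean, SD, CV, IQR, boxplot quartiles), tree-by-tree profiles along
transects perpendicular to the row orientation, and a GeoJSON per-tree
yield map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from orchardyield.io import TreeInventory, write_point_layer

logger = logging.getLogger("orchardyield")


@dataclass
class EvalReport:
    """Accuracy metrics for one prediction set (or one CV fold)."""

    r2: float
    rmse_kg: float
    nrmse_pct: float
    bias_kg: float
    iqr_kg: float
    n: int
    t_test_p: float | None = None

    def as_dict(self) -> dict:
        return {
            "r2": self.r2,
            "rmse_kg": self.rmse_kg,
            "nrmse_pct": self.nrmse_pct,
            "bias_kg": self.bias_kg,
            "iqr_kg": self.iqr_kg,
            "n": self.n,
            "t_test_p": self.t_test_p,
        }


@dataclass
class TransectSpec:
    """A line segment perpendicular to the row orientation.

    Trees whose perpendicular distance to the line is at most
    ``half_width_m`` are captured, at most one (the nearest) per row.
    """

    start: tuple[float, float]
    end: tuple[float, float]
    half_width_m: float = 2.25

    def __post_init__(self) -> None:
        if np.hypot(
            self.end[0] - self.start[0], self.end[1] - self.start[1]
        ) <= 0:
            raise ValueError("transect must have positive length")


def regression_metrics(observed, predicted) -> EvalReport:
    """R^2, RMSE, NRMSE, bias and prediction IQR from paired samples.

    NRMSE is normalized by the mean observed yield. The IQR uses linearly
    interpolated quartiles. A constant observed vector leaves R^2
    undefined (NaN, with a warning), the other metrics intact.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(
            f"length mismatch: {obs.shape} observed vs {pred.shape} predicted"
        )
    if obs.size < 2:
        raise ValueError("need at least 2 paired samples")
    resid = pred - obs
    ss_res = float((resid**2).sum())
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot == 0:
        logger.warning("observed values constant: R^2 undefined")
        r2 = float("nan")
    else:
        r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt((resid**2).mean()))
    mean_obs = float(obs.mean())
    nrmse = rmse / mean_obs * 100.0 if mean_obs != 0 else float("nan")
    q75, q25 = np.percentile(pred, [75, 25])
    return EvalReport(
        r2=r2,
        rmse_kg=rmse,
        nrmse_pct=nrmse,
        bias_kg=float(resid.mean()),
        iqr_kg=float(q75 - q25),
        n=obs.size,
    )


def distribution_compare(observed, predicted) -> dict:
    """Summary statistics and a Welch two-tailed t-test between samples.

    Mirrors the predicted-vs-observed distribution comparison: means, SDs
    and IQRs for both samples plus the (symmetric) two-sample p-value.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size < 2 or pred.size < 2:
        raise ValueError("need at least 2 samples on each side")
    if np.allclose(obs, obs.mean()) and np.allclose(pred, pred.mean()) and np.isclose(
        obs.mean(), pred.mean()
    ):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(pred, obs, equal_var=False)
    def _summary(a):
        q75, q25 = np.percentile(a, [75, 25])
        return {
            "mean": float(a.mean()),
            "sd": float(a.std(ddof=1)),
            "iqr": float(q75 - q25),
            "n": int(a.size),
        }
    return {
        "observed": _summary(obs),
        "predicted": _summary(pred),
        "t_stat": float(t_stat),
        "p_value": float(p),
    }


def row_variability(
    inventory: TreeInventory, predictions: pd.Series | dict
) -> pd.DataFrame:
    """Per-row statistics of predicted (and observed, where present) yield.

    Returns a long-format frame with one record per (row_index, source)
    carrying mean, sd, cv_pct, iqr, the boxplot quartiles and the tree
    count; rows with fewer than 4 trees are flagged (``small_row``).
    """
    df = inventory.table.copy()
    pred = pd.Series(predictions)
    df["predicted_kg"] = df["tree_id"].map(pred)
    records = []
    for row_idx, grp in df.groupby("row_index"):
        for source, col in (("predicted", "predicted_kg"), ("observed", "yield_kg")):
            vals = grp[col].dropna().to_numpy()
            if vals.size == 0:
                continue
            q25, q50, q75 = np.percentile(vals, [25, 50, 75])
            mean = vals.mean()
            sd = vals.std(ddof=1) if vals.size > 1 else 0.0
            records.append(
                {
                    "row_index": row_idx,
                    "source": source,
                    "n_trees": vals.size,
                    "mean_kg": mean,
                    "sd_kg": sd,
                    "cv_pct": sd / mean * 100.0 if mean else np.nan,
                    "iqr_kg": q75 - q25,
                    "q25_kg": q25,
                    "median_kg": q50,
                    "q75_kg": q75,
                    "small_row": vals.size < 4,
                }
            )
    out = pd.DataFrame(records)
    n_small = int(out.loc[out["source"] == "predicted", "small_row"].sum())
    if n_small:
        logger.warning("%d row(s) have fewer than 4 trees", n_small)
    return out


def transect_profile(
    inventory: TreeInventory,
    predictions: pd.Series | dict,
    transect: TransectSpec,
) -> pd.DataFrame:
    """Per-row tree yields along a transect, ordered by position.

    For each orchard row the nearest tree within ``half_width_m`` of the
    transect line is captured; output rows are ordered by the projection
    distance along the line and pair the prediction with the observed
    yield where available.
    """
    df = inventory.table.copy()
    pred = pd.Series(predictions)
    df["predicted_kg"] = df["tree_id"].map(pred)
    p0 = np.asarray(transect.start, dtype=float)
    p1 = np.asarray(transect.end, dtype=float)
    u = p1 - p0
    length = np.hypot(*u)
    u = u / length
    rel = df[["x", "y"]].to_numpy() - p0
    along = rel @ u
    perp = np.abs(rel @ np.array([-u[1], u[0]]))
    df["along_m"] = along
    df["perp_m"] = perp
    captured = df[
        (perp <= transect.half_width_m) & (along >= 0) & (along <= length)
    ]
    if captured.empty:
        raise ValueError("transect captures no trees")
    picks = captured.loc[captured.groupby("row_index")["perp_m"].idxmin()]
    if len(picks) < 2:
        raise ValueError("transect must intersect at least 2 rows")
    out = picks.sort_values("along_m")[
        ["tree_id", "row_index", "along_m", "predicted_kg", "yield_kg"]
    ].rename(columns={"yield_kg": "observed_kg"})
    return out.reset_index(drop=True)


def random_transects(
    inventory: TreeInventory,
    n_transects: int = 3,
    half_width_m: float = 2.25,
    min_row_fraction: float = 0.8,
    seed: int = 0,
) -> list[TransectSpec]:
    """Seeded random transects perpendicular to the rows.

    Candidates are horizontal lines (rows run along y) at random y
    positions; a candidate is accepted when it crosses at least
    ``min_row_fraction`` of the rows.
    """
    rng = np.random.default_rng(seed)
    df = inventory.table
    n_rows = df["row_index"].nunique()
    x0, x1 = df["x"].min() - 1.0, df["x"].max() + 1.0
    ylo, yhi = df["y"].min(), df["y"].max()
    specs: list[TransectSpec] = []
    for _ in range(200):
        if len(specs) >= n_transects:
            break
        y = float(rng.uniform(ylo, yhi))
        spec = TransectSpec((x0, y), (x1, y), half_width_m)
        rel_rows = df[(df["y"] - y).abs() <= half_width_m]["row_index"].nunique()
        if rel_rows >= min_row_fraction * n_rows:
            specs.append(spec)
    if len(specs) < n_transects:
        logger.warning(
            "only %d/%d transects found crossing >=%.0f%% of rows",
            len(specs),
            n_transects,
            100 * min_row_fraction,
        )
    return specs


def yield_map(
    inventory: TreeInventory,
    predictions: pd.Series | dict,
    path,
    crowns=None,
) -> pd.DataFrame:
    """Write the per-tree predicted-yield GeoJSON point layer.

    Trees without a prediction are omitted (count logged). Returns the
    written table. When a crown map is given, each point also carries its
    crown polygon's major-axis length.
    """
    df = inventory.table.copy()
    pred = pd.Series(predictions)
    df["predicted_kg"] = df["tree_id"].map(pred)
    missing = int(df["predicted_kg"].isna().sum())
    if missing:
        logger.info("yield map: %d tree(s) without predictions omitted", missing)
    df = df[df["predicted_kg"].notna()]
    if df.empty:
        raise ValueError("no trees with predictions")
    axis_by_id = {}
    if crowns is not None:
        axis_by_id = {p.tree_id: p.major_axis_m for p in crowns.polygons}
    props = [
        {
            "tree_id": rec["tree_id"],
            "predicted_kg": float(rec["predicted_kg"]),
            "major_axis_m": axis_by_id.get(rec["tree_id"]),
        }
        for _, rec in df.iterrows()
    ]
    write_point_layer(zip(df["x"], df["y"]), props, path)
    return df
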