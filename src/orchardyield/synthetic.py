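"""Synthetic orchard generator.

Emulates the statistical structure of the target system — a mature almond
orchard imaged at 0.3 m in four spectral bands, with per-tree fresh-weight
harvest records — so every downstream stage (segmentation, block clipping,
feature extraction, CNN and baseline regression, evaluation) is testable
without proprietary data.

What is emulated
----------------
* planting geometry: parallel rows ~6 m apart, ~4.5 m in-row spacing, with
  small positional jitter;
* per-tree crown radius drawn from a truncated normal (crowns mostly below
  5 m diameter);
* a spatially autocorrelated latent *fertility* field (exponential-
  covariance Gaussian process sampled at tree centers, mapped through the
  normal CDF so the marginal is exactly uniform on [0, 1]);
* per-tree fresh yield linked to fertility, crown area, a fertility x
  area interaction, in-row crowding, and a signed within-crown vigor
  pattern, calibrated so the large-sample mean and CV match the
  configured targets (53.1 kg, CV 0.331 by default) with a configurable
  fraction of the yield variance carried by the imagery-visible signal;
* reflectance in which red-edge and NIR increase monotonically with
  fertility, the vigor pattern appears as a mean-preserving core-vs-ring
  red-edge contrast, crown-core NDVI exceeds 0.6, and soil NDVI stays
  below 0.3;
* sub-pixel registration error between recorded tree coordinates and
  true crown centers.

What is *not* emulated: shadows, radiative transfer, phenology, weather.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import norm, truncnorm

from orchardyield.io import CANONICAL_BANDS, BandStack, GeoTransform, TreeInventory

logger = logging.getLogger("orchardyield")

#: background soil reflectance per canonical band (NDVI ~ 0.15)
SOIL_SPECTRUM = {"green": 0.10, "red": 0.11, "red_edge": 0.13, "nir": 0.15}

#: crown-core reflectance at fertility f: base + gain * f. The fertility
#: signal loads mainly on the red edge (the canopy-volume proxy band) and
#: secondarily on NIR; the visible bands are nearly saturated (chlorophyll
#: absorption) and carry almost no fertility signal.
CROWN_BASE = {"green": 0.08, "red": 0.06, "red_edge": 0.22, "nir": 0.42}
CROWN_GAIN = {"green": 0.01, "red": -0.005, "red_edge": 0.20, "nir": 0.10}

_MIN_CROWN_RADIUS_M = 0.5


@dataclass
class OrchardParams:
    """Generator configuration.

    Defaults reflect the target orchard: 6 m row spacing, 4.5 m in-row
    spacing, 0.3 m pixels, mean fresh yield 53.1 kg/tree with CV 33.1%.
    ``signal_fraction`` is the share of yield variance carried by the
    imagery-visible signal (fertility + crown size); the remainder is
    independent noise.
    """

    n_rows: int = 10
    trees_per_row: int = 20
    row_spacing_m: float = 6.0
    tree_spacing_m: float = 4.5
    pixel_size_m: float = 0.3
    crown_radius_mean_m: float = 2.2
    crown_radius_sd_m: float = 0.4
    yield_mean_kg: float = 53.1
    yield_cv: float = 0.331
    fertility_corr_length_m: float = 30.0
    signal_fraction: float = 0.7
    fertility_share: float = 0.5
    interaction_share: float = 0.15
    competition_share: float = 0.15
    pattern_share: float = 0.30
    pattern_contrast: float = 0.05
    reflectance_noise_sd: float = 0.01
    jitter_sd_m: float = 0.2
    location_error_sd_m: float = 0.15
    margin_m: float = 4.0
    rotation_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.trees_per_row < 1:
            raise ValueError("n_rows and trees_per_row must be >= 1")
        if self.row_spacing_m <= 0 or self.tree_spacing_m <= 0:
            raise ValueError("spacings must be positive")
        for name in (
            "crown_radius_sd_m",
            "reflectance_noise_sd",
            "jitter_sd_m",
            "location_error_sd_m",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must be in [0, 1]")
        if not 0.0 <= self.fertility_share <= 1.0:
            raise ValueError("fertility_share must be in [0, 1]")
        if not 0.0 <= self.interaction_share <= 1.0:
            raise ValueError("interaction_share must be in [0, 1]")
        if not 0.0 <= self.competition_share <= 1.0:
            raise ValueError("competition_share must be in [0, 1]")
        if not 0.0 <= self.pattern_share <= 1.0:
            raise ValueError("pattern_share must be in [0, 1]")
        if self.interaction_share + self.competition_share + self.pattern_share > 1.0:
            raise ValueError(
                "interaction, competition and pattern shares must sum to <= 1"
            )


@dataclass
class GroundTruth:
    """Per-tree truth: position, crown radius, latent fertility, yield.

    Backed by a DataFrame with columns
    ``tree_id, x, y, row_index, crown_radius_m, fertility, yield_kg``.
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)


def _yield_link_coefficients(
    params: OrchardParams,
) -> tuple[float, ...]:
    """Analytic (a0, a1, a2, a3, a4, a5, noise_sd) for the yield link.

    yield = mu * (a0 + a1*F + a2*G + a3*(F - 1/2)*(G - E[G]) - a4*C
                  + a5*sqrt(3)*Q) + eps

    with F ~ U[0,1] (fertility), G = (R / r_mean)^2 (normalized crown
    area, independent of F), C the standardized in-row crowding index
    (crown overlap with adjacent trees along the row) and Q ~ U[-1,1] the
    signed within-crown vigor pattern (core-vs-ring red-edge contrast).
    The fertility x area interaction models per-area productivity scaling
    with canopy size; the competition term models yield loss from
    crowding; the pattern term models productivity differences between
    trees with vigorous versus declining crown interiors at equal average
    canopy vigor. All three are visible in the imagery's spatial
    arrangement but are conflated or destroyed by per-tree summary
    statistics. Coefficients are chosen so that E[yield] = mu and
    SD[yield] = mu * cv: ``signal_fraction`` of the variance sits in the
    deterministic term; within it ``interaction_share``,
    ``competition_share`` and ``pattern_share`` go to the structured
    terms and the rest is split ``fertility_share`` /
    (1 - fertility_share) between the main effects.
    """
    mu = params.yield_mean_kg
    sigma = mu * params.yield_cv
    var_f = 1.0 / 12.0
    r, s = params.crown_radius_mean_m, params.crown_radius_sd_m
    # normal moments; truncation at 0.5 m is negligible for default params
    e_g = 1.0 + (s / r) ** 2
    var_g = (4.0 * r**2 * s**2 + 2.0 * s**4) / r**4
    sig_var = params.signal_fraction * sigma**2
    main_var = (
        1.0
        - params.interaction_share
        - params.competition_share
        - params.pattern_share
    ) * sig_var
    a1 = np.sqrt(params.fertility_share * main_var / (var_f * mu**2))
    a2 = (
        np.sqrt((1.0 - params.fertility_share) * main_var / (var_g * mu**2))
        if var_g > 0
        else 0.0
    )
    a3 = (
        np.sqrt(params.interaction_share * sig_var / (var_f * var_g * mu**2))
        if var_g > 0
        else 0.0
    )
    a4 = np.sqrt(params.competition_share * sig_var) / mu
    a5 = np.sqrt(params.pattern_share * sig_var) / mu  # Q*sqrt(3) has var 1
    noise_sd = np.sqrt(1.0 - params.signal_fraction) * sigma
    # interaction, competition and pattern terms all have mean zero
    a0 = 1.0 - a1 * 0.5 - a2 * e_g
    return (
        float(a0), float(a1), float(a2), float(a3), float(a4), float(a5),
        float(noise_sd),
    )


def _competition_index(df: pd.DataFrame) -> np.ndarray:
    """Standardized in-row crowding index.

    For each tree, the summed crown overlap ``max(0, r_i + r_j - d_ij)``
    with its adjacent neighbors along the same row, residualized against
    the tree's own radius (linear and quadratic terms) and standardized to
    zero mean and unit variance over the orchard (all-zero when crowns
    never touch). The residualization makes the index the *extra* crowding
    beyond what the tree's own size explains, so it is uncorrelated with
    the crown-area yield term and the moment calibration stays exact;
    the standardization makes it a relative quantity independent of
    layout geometry.
    """
    c = np.zeros(len(df))
    pos = {tid: k for k, tid in enumerate(df["tree_id"])}
    for _, grp in df.groupby("row_index"):
        grp = grp.sort_values("y")
        idx = [pos[t] for t in grp["tree_id"]]
        xy = grp[["x", "y"]].to_numpy()
        r = grp["crown_radius_m"].to_numpy()
        d = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        overlap = np.clip(r[:-1] + r[1:] - d, 0.0, None)
        for k, o in enumerate(overlap):
            c[idx[k]] += o
            c[idx[k + 1]] += o
    if c.std() == 0:
        return np.zeros_like(c)
    r_own = df["crown_radius_m"].to_numpy()
    design = np.column_stack([np.ones_like(r_own), r_own, r_own**2])
    beta, *_ = np.linalg.lstsq(design, c, rcond=None)
    resid = c - design @ beta
    sd = resid.std()
    return resid / sd if sd > 0 else np.zeros_like(c)


def generate_layout(
    params: OrchardParams, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Lay out tree centers on the row grid and draw crown radii.

    Rows run along the y axis (one row per x position); centers receive
    Gaussian jitter of ``jitter_sd_m``. Crown radii come from a normal
    truncated below at 0.5 m. ``rotation_deg`` rotates the whole layout
    about its centroid (rendering is rotation-agnostic).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    i, j = np.meshgrid(
        np.arange(params.n_rows), np.arange(params.trees_per_row), indexing="ij"
    )
    i, j = i.ravel(), j.ravel()
    x = params.margin_m + i * params.row_spacing_m
    y = params.margin_m + j * params.tree_spacing_m
    if params.jitter_sd_m > 0:
        x = x + rng.normal(0.0, params.jitter_sd_m, x.size)
        y = y + rng.normal(0.0, params.jitter_sd_m, y.size)
    if params.rotation_deg:
        th = np.deg2rad(params.rotation_deg)
        cx, cy = x.mean(), y.mean()
        xr = cx + (x - cx) * np.cos(th) - (y - cy) * np.sin(th)
        yr = cy + (x - cx) * np.sin(th) + (y - cy) * np.cos(th)
        x, y = xr - xr.min() + params.margin_m, yr - yr.min() + params.margin_m
    if params.crown_radius_sd_m > 0:
        a = (_MIN_CROWN_RADIUS_M - params.crown_radius_mean_m) / params.crown_radius_sd_m
        radii = truncnorm.rvs(
            a,
            np.inf,
            loc=params.crown_radius_mean_m,
            scale=params.crown_radius_sd_m,
            size=x.size,
            random_state=rng,
        )
    else:
        radii = np.full(x.size, params.crown_radius_mean_m)
    table = pd.DataFrame(
        {
            "tree_id": [f"T{k:05d}" for k in range(x.size)],
            "x": x,
            "y": y,
            "row_index": i,
            "crown_radius_m": radii,
            "fertility": np.nan,
            "yield_kg": np.nan,
        }
    )
    return GroundTruth(table)


def generate_yield_surface(
    layout: GroundTruth,
    params: OrchardParams,
    seed: int | None = None,
    coefficients: tuple[float, ...] | None = None,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Fill fertility and yield into a layout.

    Fertility is an exponential-covariance Gaussian random field sampled at
    tree centers (range ``fertility_corr_length_m``) mapped through the
    standard normal CDF onto [0, 1]. Yield follows the calibrated link
    (see :func:`_yield_link_coefficients`) truncated below at 0 kg; the
    truncation rate is logged. ``coefficients`` overrides (a0, a1, a2,
    a3, a4, a5, noise_sd) for controlled experiments.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed if seed is None else seed)
    df = layout.table.copy()
    pts = df[["x", "y"]].to_numpy()
    n = len(df)
    d = cdist(pts, pts)
    cov = np.exp(-d / params.fertility_corr_length_m)
    cov[np.diag_indices(n)] += 1e-9
    z = np.linalg.cholesky(cov) @ rng.standard_normal(n)
    fert = norm.cdf(z)
    a0, a1, a2, a3, a4, a5, noise_sd = (
        coefficients if coefficients is not None else _yield_link_coefficients(params)
    )
    r, s = params.crown_radius_mean_m, params.crown_radius_sd_m
    e_g = 1.0 + (s / r) ** 2
    g = (df["crown_radius_m"].to_numpy() / r) ** 2
    comp = _competition_index(df)
    pattern = rng.uniform(-1.0, 1.0, n)
    y = params.yield_mean_kg * (
        a0
        + a1 * fert
        + a2 * g
        + a3 * (fert - 0.5) * (g - e_g)
        - a4 * comp
        + a5 * np.sqrt(3.0) * pattern
    )
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n)
    truncated = int((y < 0).sum())
    if truncated:
        logger.info("yield truncation at 0 kg applied to %d/%d trees", truncated, n)
    df["fertility"] = fert
    df["vigor_pattern"] = pattern
    df["yield_kg"] = np.clip(y, 0.0, None)
    return GroundTruth(df)


def render_reflectance(
    ground_truth: GroundTruth,
    params: OrchardParams,
    rng: np.random.Generator | None = None,
) -> BandStack:
    """Render the 4-band reflectance raster for a completed ground truth.

    Soil background everywhere; each crown is a radial-profile disk whose
    core spectrum interpolates between :data:`CROWN_BASE` and
    ``CROWN_BASE + CROWN_GAIN`` with fertility, falling off to soil with
    the squared radial weight ``w = 1 - (r/R)^2``. Red-edge and NIR
    reflectance therefore increase monotonically with fertility; crown-core
    NDVI exceeds 0.6 and soil NDVI stays below 0.3 by construction.

    The per-tree signed ``vigor_pattern`` latent Q (zero when the column
    is absent) adds a core-vs-ring contrast to the **red-edge band
    only**: ``Q * pattern_contrast * (1 - rho^2)(1 - 4.58 rho^2)`` with
    ``rho = r/R``. The second factor changes sign near rho = 0.47, so the
    mode's mean over the detected crown (rho < ~0.7) is approximately
    zero — average red-edge reflectance is nearly invariant to Q while
    the spatial pattern flips between vigorous-core and vigorous-ring.
    NDVI (red/NIR) is untouched, so segmentation is independent of Q.

    Overlapping crowns resolve per pixel to the tree with the larger
    radial weight. Additive Gaussian noise, clipped to [0, 1].
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    df = ground_truth.table
    if df["fertility"].isna().any():
        raise ValueError("ground truth incomplete: fertility missing")
    px = params.pixel_size_m
    width_m = df["x"].max() + params.margin_m
    height_m = df["y"].max() + params.margin_m
    n_cols = int(np.ceil(width_m / px))
    n_rows_px = int(np.ceil(height_m / px))
    min_span = 2 * (df["crown_radius_m"].max() + px)
    if n_cols * px < min_span or n_rows_px * px < min_span:
        raise ValueError("raster too small to contain the layout")
    transform = GeoTransform(0.0, n_rows_px * px, px)

    data = np.empty((n_rows_px, n_cols, 4))
    for b, name in enumerate(CANONICAL_BANDS):
        data[:, :, b] = SOIL_SPECTRUM[name]

    w_max = np.zeros((n_rows_px, n_cols))
    cols_x = (np.arange(n_cols) + 0.5) * px
    rows_y = transform.y_origin - (np.arange(n_rows_px) + 0.5) * px
    crown = np.array([CROWN_BASE[b] for b in CANONICAL_BANDS])
    gain = np.array([CROWN_GAIN[b] for b in CANONICAL_BANDS])
    soil = np.array([SOIL_SPECTRUM[b] for b in CANONICAL_BANDS])
    for _, tree in df.iterrows():
        r = tree["crown_radius_m"]
        c0 = max(0, int((tree["x"] - r) / px) - 1)
        c1 = min(n_cols, int((tree["x"] + r) / px) + 2)
        r0 = max(0, int((transform.y_origin - tree["y"] - r) / px) - 1)
        r1 = min(n_rows_px, int((transform.y_origin - tree["y"] + r) / px) + 2)
        if c0 >= c1 or r0 >= r1:
            continue
        dx = cols_x[c0:c1] - tree["x"]
        dy = rows_y[r0:r1] - tree["y"]
        d2 = dy[:, None] ** 2 + dx[None, :] ** 2
        w = np.clip(1.0 - d2 / r**2, 0.0, 1.0)
        spectrum = crown + gain * tree["fertility"]
        win = data[r0:r1, c0:c1]
        better = w > w_max[r0:r1, c0:c1]
        wv = np.where(better, w, 0.0)[:, :, None]
        win[:] = np.where(
            better[:, :, None], soil + (spectrum - soil) * wv, win
        )
        q = tree.get("vigor_pattern", 0.0)
        q = float(q) if q is not None and np.isfinite(q) else 0.0
        if q:
            rho2 = np.clip(d2 / r**2, 0.0, 1.0)
            mode = (1.0 - rho2) * (1.0 - 4.58 * rho2)
            re_idx = CANONICAL_BANDS.index("red_edge")
            win[:, :, re_idx] += np.where(
                better, q * params.pattern_contrast * mode, 0.0
            )
        w_max[r0:r1, c0:c1] = np.maximum(w_max[r0:r1, c0:c1], w)

    if params.reflectance_noise_sd > 0:
        data = data + rng.normal(0.0, params.reflectance_noise_sd, data.shape)
    data = np.clip(data, 0.0, 1.0)
    return BandStack(
        data=data,
        band_names=CANONICAL_BANDS,
        transform=transform,
        crs_label="synthetic-local-meters",
    )


def generate_orchard(
    params: OrchardParams, sampling_stride: int = 1
) -> tuple[BandStack, TreeInventory, GroundTruth]:
    """Generate imagery, a harvest-style inventory, and full ground truth.

    ``sampling_stride`` mimics the study's harvest design in which only
    every k-th row is individually harvested: yields are visible in the
    inventory only for rows with ``row_index % sampling_stride == 0``
    (all rows for stride 1). The ground truth always carries every yield.

    The inventory's coordinates are the *recorded* tree locations: the
    true crown centers plus isotropic Gaussian registration error of
    ``location_error_sd_m`` (field logging is not survey-grade), which is
    what every downstream consumer of the harvest table sees. The ground
    truth keeps the exact centers.
    """
    if sampling_stride < 1:
        raise ValueError("sampling_stride must be >= 1")
    seeds = np.random.SeedSequence(params.seed).spawn(4)
    layout = generate_layout(params, rng=np.random.default_rng(seeds[0]))
    truth = generate_yield_surface(
        layout, params, rng=np.random.default_rng(seeds[1])
    )
    stack = render_reflectance(truth, params, rng=np.random.default_rng(seeds[2]))
    inv = truth.table[["tree_id", "x", "y", "row_index", "yield_kg"]].copy()
    if params.location_error_sd_m > 0:
        rng_loc = np.random.default_rng(seeds[3])
        inv["x"] += rng_loc.normal(0.0, params.location_error_sd_m, len(inv))
        inv["y"] += rng_loc.normal(0.0, params.location_error_sd_m, len(inv))
    hidden = inv["row_index"] % sampling_stride != 0
    inv.loc[hidden, "yield_kg"] = np.nan
    return stack, TreeInventory(inv), truth
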