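"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive quantities from their definitions with naive
loops, sharing no code with the package implementation.
"""

import math

import numpy as np

from orchardyield.features import GLCM_OFFSETS


def brute_force_glcm(img: np.ndarray, levels: int) -> np.ndarray:
    """Symmetric normalized GLCM by enumerating every distance-1 pair."""
    counts = np.zeros((levels, levels))
    n_rows, n_cols = img.shape
    for r in range(n_rows):
        for c in range(n_cols):
            for dr, dc in GLCM_OFFSETS:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < n_rows and 0 <= c2 < n_cols:
                    counts[img[r, c], img[r2, c2]] += 1
                    counts[img[r2, c2], img[r, c]] += 1
    return counts / counts.sum()


def brute_force_measures(p: np.ndarray) -> dict:
    """The eight texture measures, from their textbook definitions."""
    levels = p.shape[0]
    contrast = dissim = homog = asm = entropy = mean_i = 0.0
    for i in range(levels):
        for j in range(levels):
            v = p[i, j]
            contrast += v * (i - j) ** 2
            dissim += v * abs(i - j)
            homog += v / (1 + (i - j) ** 2)
            asm += v * v
            mean_i += i * v
            if v > 0:
                entropy -= v * math.log(v)
    var_i = sum(
        p[i, j] * (i - mean_i) ** 2 for i in range(levels) for j in range(levels)
    )
    mean_j = sum(j * p[i, j] for i in range(levels) for j in range(levels))
    var_j = sum(
        p[i, j] * (j - mean_j) ** 2 for i in range(levels) for j in range(levels)
    )
    if var_i > 0 and var_j > 0:
        corr = sum(
            p[i, j] * (i - mean_i) * (j - mean_j)
            for i in range(levels)
            for j in range(levels)
        ) / math.sqrt(var_i * var_j)
    else:
        corr = 0.0
    return {
        "contrast": contrast,
        "dissimilarity": dissim,
        "homogeneity": homog,
        "asm": asm,
        "correlation": corr,
        "mean": mean_i,
        "variance": var_i,
        "entropy": entropy,
    }


def brute_force_metrics(obs, pred):
    """(R^2, RMSE, NRMSE%, bias) recomputed from scalar definitions."""
    obs, pred = np.asarray(obs, float), np.asarray(pred, float)
    n = len(obs)
    ss_res = sum((p - o) ** 2 for o, p in zip(obs, pred))
    mean_obs = sum(obs) / n
    ss_tot = sum((o - mean_obs) ** 2 for o in obs)
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    rmse = (ss_res / n) ** 0.5
    nrmse = rmse / mean_obs * 100
    bias = sum(p - o for o, p in zip(obs, pred)) / n
    return r2, rmse, nrmse, bias
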