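"""Sequential model-based (Bayesian) optimization.

A small Gaussian-process Expected-Improvement optimizer over a box of
mixed dimensions (continuous, log-continuous, integer, log-integer,
categorical), encoded into the unit hypercube. Used for the CNN
architecture search; deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern


@dataclass(frozen=True)
class Dim:
    """One search dimension."""

    name: str
    kind: str  # 'float' | 'logfloat' | 'int' | 'logint' | 'cat'
    low: float | None = None
    high: float | None = None
    choices: tuple | None = None

    def decode(self, u: float):
        """Map a unit-interval coordinate to a parameter value."""
        if self.kind == "cat":
            idx = min(int(u * len(self.choices)), len(self.choices) - 1)
            return self.choices[idx]
        if self.kind in ("logfloat", "logint"):
            lo, hi = np.log(self.low), np.log(self.high)
            v = float(np.exp(lo + u * (hi - lo)))
        else:
            v = float(self.low + u * (self.high - self.low))
        if self.kind in ("int", "logint"):
            return int(round(min(max(v, self.low), self.high)))
        return v


class GPOptimizer:
    """Minimize a black-box objective with GP + Expected Improvement.

    The first ``n_initial`` trials are drawn uniformly at random; each
    subsequent point maximizes EI over a random candidate pool under a
    Matern-5/2 GP fitted to the observed (point, loss) pairs.
    """

    def __init__(
        self,
        dims: Sequence[Dim],
        seed: int = 0,
        n_initial: int = 5,
        n_candidates: int = 256,
    ):
        self.dims = list(dims)
        self.rng = np.random.default_rng(seed)
        self.n_initial = n_initial
        self.n_candidates = n_candidates
        self.X: list[np.ndarray] = []
        self.y: list[float] = []

    def decode(self, u: np.ndarray) -> dict:
        return {d.name: d.decode(float(ui)) for d, ui in zip(self.dims, u)}

    def ask(self) -> np.ndarray:
        k = len(self.dims)
        if len(self.X) < self.n_initial or len(set(self.y)) < 2:
            return self.rng.random(k)
        gp = GaussianProcessRegressor(
            kernel=ConstantKernel(1.0) * Matern(length_scale=np.ones(k), nu=2.5),
            normalize_y=True,
            alpha=1e-6,
            random_state=0,
        )
        gp.fit(np.asarray(self.X), np.asarray(self.y))
        cand = self.rng.random((self.n_candidates, k))
        mu, sd = gp.predict(cand, return_std=True)
        best = min(self.y)
        sd = np.maximum(sd, 1e-12)
        z = (best - mu) / sd
        ei = (best - mu) * norm.cdf(z) + sd * norm.pdf(z)
        return cand[int(np.argmax(ei))]

    def tell(self, u: np.ndarray, loss: float) -> None:
        self.X.append(np.asarray(u, dtype=float))
        self.y.append(float(loss))

    def minimize(
        self, objective: Callable[[dict], float], max_trials: int
    ) -> tuple[dict, list[tuple[dict, float]]]:
        """Run the full loop; returns (best params, trial log)."""
        if max_trials < 1:
            raise ValueError("max_trials must be >= 1")
        log: list[tuple[dict, float]] = []
        for _ in range(max_trials):
            u = self.ask()
            params = self.decode(u)
            loss = float(objective(params))
            self.tell(u, loss)
            log.append((params, loss))
        best_idx = int(np.argmin(self.y))
        return log[best_idx][0], log
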