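"""Minimal CPU neural-network engine (numpy, channels-last).

Implements exactly the layer vocabulary the yield CNN needs — 3x3 "same"
convolution, batch normalization, ReLU, 2x2/stride-2 max and average
pooling (floor or ceil edge semantics), global average pooling, dense,
dropout — with explicit forward/backward passes, MSE loss and the Adam
optimizer. float32 throughout; all randomness (initialization, shuffling,
dropout) flows through a caller-supplied ``numpy`` Generator, so identical
seeds give identical models.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-5


class Layer:
    """Base layer: subclasses fill ``params``/``grads`` dicts by name."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def build(self, input_shape: tuple, rng: np.random.Generator) -> tuple:
        return input_shape

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 same-padding convolution, stride 1, He-normal init."""

    def __init__(self, filters: int, kernel_size: int = 3) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        self.filters = filters
        self.k = kernel_size

    def build(self, input_shape, rng):
        h, w, c = input_shape
        fan_in = self.k * self.k * c
        self.params["W"] = (
            rng.standard_normal((self.k, self.k, c, self.filters))
            * np.sqrt(2.0 / fan_in)
        ).astype(np.float32)
        self.params["b"] = np.zeros(self.filters, dtype=np.float32)
        self.in_channels = c
        return (h, w, self.filters)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        # (N, H, W, C, k, k) -> (N, H, W, k, k, C)
        cols = cols.transpose(0, 1, 2, 4, 5, 3)
        return np.ascontiguousarray(cols)

    def forward(self, x, training, rng):
        n, h, w, c = x.shape
        cols = self._im2col(x).reshape(n * h * w, self.k * self.k * c)
        self._cols = cols
        self._xshape = x.shape
        wf = self.params["W"].reshape(-1, self.filters)
        y = cols @ wf + self.params["b"]
        return y.reshape(n, h, w, self.filters)

    def backward(self, dy):
        n, h, w, f = dy.shape
        k, c = self.k, self.in_channels
        dyf = dy.reshape(n * h * w, f)
        self.grads["W"] = (self._cols.T @ dyf).reshape(self.params["W"].shape)
        self.grads["b"] = dyf.sum(axis=0)
        dcols = (dyf @ self.params["W"].reshape(-1, f).T).reshape(n, h, w, k, k, c)
        p = k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, ki : ki + h, kj : kj + w, :] += dcols[:, :, :, ki, kj, :]
        self._cols = None
        return dxp[:, p : p + h, p : p + w, :]


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, momentum: float = 0.9) -> None:
        super().__init__()
        self.momentum = momentum

    def build(self, input_shape, rng):
        c = input_shape[-1]
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.axes = tuple(range(len(input_shape)))  # plus batch axis -> computed in fwd
        return input_shape

    def forward(self, x, training, rng):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = (1.0 / np.sqrt(var + _EPS)).astype(np.float32)
        self._xhat = ((x - mean) * self._inv_std).astype(np.float32)
        self._m = int(np.prod([x.shape[a] for a in axes]))
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        xhat, inv_std, m = self._xhat, self._inv_std, self._m
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"]
        dxhat = dy * g
        dx = (
            inv_std
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=axes)
                - xhat * (dxhat * xhat).sum(axis=axes)
            )
        )
        self._xhat = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class _Pool2D(Layer):
    """2x2 stride-2 pooling. ``ceil_mode`` pads odd dims by edge
    replication (the "same"-padding behavior); floor mode crops the odd
    trailing row/col and errors at build time if a spatial dim would
    collapse to zero."""

    def __init__(self, ceil_mode: bool = False) -> None:
        super().__init__()
        self.ceil_mode = ceil_mode

    def build(self, input_shape, rng):
        h, w, c = input_shape
        if self.ceil_mode:
            oh, ow = max(1, -(-h // 2)), max(1, -(-w // 2))
        else:
            oh, ow = h // 2, w // 2
            if oh == 0 or ow == 0:
                raise ValueError(
                    f"pooling exhausts spatial dimensions ({h}x{w} input)"
                )
        self._in_hw = (h, w)
        self._out_hw = (oh, ow)
        return (oh, ow, c)

    def _prepare(self, x):
        h, w = x.shape[1:3]
        oh, ow = self._out_hw
        if self.ceil_mode:
            ph, pw = 2 * oh - h, 2 * ow - w
            if ph or pw:
                x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), mode="edge")
        else:
            x = x[:, : 2 * oh, : 2 * ow, :]
        return x.reshape(x.shape[0], oh, 2, ow, 2, x.shape[-1])

    def _unprepare(self, dxp, n, c):
        h, w = self._in_hw
        oh, ow = self._out_hw
        dxp = dxp.reshape(n, 2 * oh, 2 * ow, c)
        if self.ceil_mode:
            # fold gradients of replicated cells back onto the edge
            if 2 * oh > h:
                dxp[:, h - 1, :, :] += dxp[:, h, :, :]
            if 2 * ow > w:
                dxp[:, :, w - 1, :] += dxp[:, :, w, :]
            return dxp[:, :h, :w, :]
        dx = np.zeros((n, h, w, c), dtype=np.float32)
        dx[:, : 2 * oh, : 2 * ow, :] = dxp
        return dx


class MaxPool2D(_Pool2D):
    def forward(self, x, training, rng):
        xw = self._prepare(x)
        out = xw.max(axis=(2, 4))
        self._xw = xw
        self._out = out
        return out.astype(np.float32)

    def backward(self, dy):
        xw, out = self._xw, self._out
        mask = xw == out[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dxp = mask * (dy[:, :, None, :, None, :] / counts)
        self._xw = self._out = None
        n, c = dy.shape[0], dy.shape[-1]
        return self._unprepare(dxp.astype(np.float32), n, c)


class AvgPool2D(_Pool2D):
    def forward(self, x, training, rng):
        xw = self._prepare(x)
        return xw.mean(axis=(2, 4)).astype(np.float32)

    def backward(self, dy):
        n, c = dy.shape[0], dy.shape[-1]
        dxp = np.broadcast_to(
            dy[:, :, None, :, None, :] / 4.0,
            (n, self._out_hw[0], 2, self._out_hw[1], 2, c),
        ).copy()
        return self._unprepare(dxp.astype(np.float32), n, c)


class GlobalAvgPool(Layer):
    """Average each feature map to a scalar: (N, H, W, C) -> (N, C)."""

    def build(self, input_shape, rng):
        h, w, c = input_shape
        self._hw = (h, w)
        return (c,)

    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.mean(axis=(1, 2)).astype(np.float32)

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.broadcast_to(
            dy[:, None, None, :] / (h * w), (n, h, w, c)
        ).astype(np.float32)


class Dense(Layer):
    def __init__(self, units: int) -> None:
        super().__init__()
        self.units = units

    def build(self, input_shape, rng):
        (d,) = input_shape
        self.params["W"] = (
            rng.standard_normal((d, self.units)) * np.sqrt(2.0 / d)
        ).astype(np.float32)
        self.params["b"] = np.zeros(self.units, dtype=np.float32)
        return (self.units,)

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        dx = dy @ self.params["W"].T
        self._x = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Adam:
    """Adam optimizer with conventional moment parameters."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, dict[str, np.ndarray]] = {}
        self._v: dict[int, dict[str, np.ndarray]] = {}

    def step(self, layers: list[Layer]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for li, layer in enumerate(layers):
            if not layer.params:
                continue
            m = self._m.setdefault(li, {})
            v = self._v.setdefault(li, {})
            for name, p in layer.params.items():
                g = layer.grads[name].astype(np.float32)
                m[name] = self.beta1 * m.get(name, 0.0) + (1 - self.beta1) * g
                v[name] = self.beta2 * v.get(name, 0.0) + (1 - self.beta2) * g * g
                mhat = m[name] / b1t
                vhat = v[name] / b2t
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Sequential:
    """A feed-forward stack with MSE loss and Adam training.

    Built eagerly at construction: every layer's parameters are
    initialized from ``seed``, so two models built from the same layer
    list and seed have identical weights.
    """

    def __init__(self, layers: list[Layer], input_shape: tuple, seed: int = 0, lr: float = 1e-3):
        self.layers = layers
        self.input_shape = tuple(input_shape)
        self.seed = seed
        rng = np.random.default_rng(seed)
        shape = self.input_shape
        for layer in layers:
            shape = layer.build(shape, rng)
        self.output_shape = shape
        self.optimizer = Adam(lr=lr)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        out = x.astype(np.float32)
        for layer in self.layers:
            out = layer.forward(out, training, rng)
        return out

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        rng = np.random.default_rng(0)  # unused at inference
        outs = [
            self.forward(x[i : i + batch_size], False, rng)
            for i in range(0, len(x), batch_size)
        ]
        pred = np.concatenate(outs).ravel().astype(np.float64)
        if getattr(self, "_y_scale", None) is not None:
            mean, sd = self._y_scale
            pred = pred * float(sd) + float(mean)
        return pred

    def _train_batch(self, xb: np.ndarray, yb: np.ndarray, rng) -> float:
        pred = self.forward(xb, True, rng).ravel()
        resid = pred - yb.astype(np.float32)
        loss = float(np.mean(resid**2))
        dy = (2.0 * resid / len(resid)).astype(np.float32).reshape(-1, 1)
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        self.optimizer.step(self.layers)
        return loss

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 100,
        batch_size: int = 128,
        seed: int = 0,
        validation_data: tuple[np.ndarray, np.ndarray] | None = None,
        standardize_y: bool = True,
        cosine_decay: bool = True,
        verbose: bool = False,
    ) -> dict[str, list[float]]:
        """Train with per-epoch shuffling; returns the loss history.

        With ``standardize_y`` (default) the targets are standardized for
        training and predictions are mapped back to original units; the
        recorded losses are rescaled to original (squared) units. This
        removes the many early epochs a small-initialized head would
        otherwise spend learning the output scale. ``cosine_decay``
        anneals the learning rate to ~0 over the run (half-cosine), which
        stabilizes the minimum the short training runs settle into.
        """
        rng = np.random.default_rng(seed)
        base_lr = self.optimizer.lr
        y = np.asarray(y, dtype=np.float64)
        if standardize_y:
            mean, sd = float(y.mean()), float(y.std())
            sd = sd if sd > 0 else 1.0
            self._y_scale = (mean, sd)
            y_fit = (y - mean) / sd
            scale2 = sd**2
        else:
            self._y_scale = None
            y_fit = y
            scale2 = 1.0
        history: dict[str, list[float]] = {"loss": []}
        if validation_data is not None:
            history["val_loss"] = []
        n = len(x)
        for epoch in range(epochs):
            if cosine_decay:
                self.optimizer.lr = base_lr * 0.5 * (
                    1.0 + np.cos(np.pi * epoch / max(1, epochs))
                )
            order = rng.permutation(n)
            losses = []
            for i in range(0, n, batch_size):
                idx = order[i : i + batch_size]
                losses.append(self._train_batch(x[idx], y_fit[idx], rng))
            history["loss"].append(float(np.mean(losses)) * scale2)
            if validation_data is not None:
                xv, yv = validation_data
                pv = self.predict(xv)
                history["val_loss"].append(float(np.mean((pv - yv) ** 2)))
            if verbose:
                msg = f"epoch {epoch + 1}/{epochs} loss={history['loss'][-1]:.4f}"
                if validation_data is not None:
                    msg += f" val_loss={history['val_loss'][-1]:.4f}"
                print(msg)
        self.optimizer.lr = base_lr
        return history

    # -- introspection ------------------------------------------------------

    def count_layers(self, cls: type) -> int:
        return sum(isinstance(l, cls) for l in self.layers)

    def n_parameters(self) -> int:
        return sum(p.size for l in self.layers for p in l.params.values())

    # -- persistence --------------------------------------------------------

    def save_weights(self, path) -> None:
        """Serialize parameters, batch-norm statistics and the target
        scale as an NPZ archive (architecture is not stored; rebuild it
        with the same constructor before loading)."""
        arrays: dict[str, np.ndarray] = {
            "__input_shape": np.asarray(self.input_shape),
        }
        if getattr(self, "_y_scale", None) is not None:
            arrays["__y_scale"] = np.asarray(self._y_scale)
        for li, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                arrays[f"{li}:{name}"] = p
            if isinstance(layer, BatchNorm):
                arrays[f"{li}:running_mean"] = layer.running_mean
                arrays[f"{li}:running_var"] = layer.running_var
        np.savez_compressed(path, **arrays)

    def load_weights(self, path) -> None:
        """Load parameters saved by :meth:`save_weights` into a model
        built with the same architecture and input shape."""
        z = np.load(path)
        stored_shape = tuple(z["__input_shape"])
        if stored_shape != self.input_shape:
            raise ValueError(
                f"weights were trained for input {stored_shape}, "
                f"model expects {self.input_shape}"
            )
        self._y_scale = tuple(z["__y_scale"]) if "__y_scale" in z else None
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = z[f"{li}:{name}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean = z[f"{li}:running_mean"]
                layer.running_var = z[f"{li}:running_var"]
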