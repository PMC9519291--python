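"""Layer primitives with explicit forward/backward passes.

Feature maps are channel-last, ``(B, H, W, C)``: the im2col window copies
and the col2im scatter-adds then move contiguous channel chunks, which keeps
the convolution layers memory-bandwidth-friendly in pure numpy. Convolution
itself is one GEMM per layer. Parameters and gradients are plain numpy
arrays exposed through nested name -> array dicts; the optimizer updates
parameters in place.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Linear",
    "MaxPool2d",
    "GlobalAvgPool",
    "Sequential",
    "ResidualBlock",
]


class Module:
    """Base: leaf layers fill _params/_grads/_buffers; composites define children."""

    def __init__(self) -> None:
        self._params: dict[str, np.ndarray] = {}
        self._grads: dict[str, np.ndarray] = {}
        self._buffers: dict[str, np.ndarray] = {}

    def children(self) -> dict[str, "Module"]:
        return {}

    def _collect(self, attr: str) -> dict[str, np.ndarray]:
        out = dict(getattr(self, "_" + attr))
        for name, child in self.children().items():
            for k, v in child._collect(attr).items():
                out[f"{name}.{k}"] = v
        return out

    def params(self) -> dict[str, np.ndarray]:
        return self._collect("params")

    def grads(self) -> dict[str, np.ndarray]:
        return self._collect("grads")

    def buffers(self) -> dict[str, np.ndarray]:
        return self._collect("buffers")

    def state(self) -> dict[str, np.ndarray]:
        out = self.params()
        for k, v in self.buffers().items():
            out["buffer:" + k] = v
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        buffers = self.buffers()
        for k, v in state.items():
            if k.startswith("buffer:"):
                buffers[k[len("buffer:") :]][...] = v
            else:
                params[k][...] = v

    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params().values())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(xp: np.ndarray, k: int, s: int, Ho: int, Wo: int) -> np.ndarray:
    """(B, Hp, Wp, C) -> (B*Ho*Wo, k*k*C) patch matrix."""
    B, _, _, C = xp.shape
    cols = np.empty((B, Ho, Wo, k, k, C), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, :, i, j, :] = xp[:, i : i + s * Ho : s, j : j + s * Wo : s, :]
    return cols.reshape(B * Ho * Wo, k * k * C)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        # stored (k, k, C_in, C_out): reshapes to the GEMM operand view-free
        self._params["W"] = rng.normal(
            0.0, scale, size=(kernel, kernel, in_channels, out_channels)
        ).astype(dtype)
        self.kernel = kernel
        self.stride = stride
        self.pad = pad
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        W = self._params["W"]
        k, _, ci, co = W.shape
        if x.ndim != 4 or x.shape[3] != ci:
            raise ValueError(f"expected (B,H,W,{ci}) input, got {x.shape}")
        s, p = self.stride, self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        B, Hp, Wp, _ = xp.shape
        Ho = (Hp - k) // s + 1
        Wo = (Wp - k) // s + 1
        cols = _im2col(xp, k, s, Ho, Wo)
        y = cols @ W.reshape(-1, co)
        if train:
            self._cache = (cols, x.shape, (B, Ho, Wo))
        return y.reshape(B, Ho, Wo, co)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, (B, Ho, Wo) = self._cache
        self._cache = None
        W = self._params["W"]
        k, _, ci, co = W.shape
        s, p = self.stride, self.pad
        d2 = dout.reshape(-1, co)
        self._grads["W"] = (cols.T @ d2).reshape(W.shape)
        dcols = (d2 @ W.reshape(-1, co).T).reshape(B, Ho, Wo, k, k, ci)
        _, H, Wd, _ = x_shape
        dxp = np.zeros((B, H + 2 * p, Wd + 2 * p, ci), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + s * Ho : s, j : j + s * Wo : s, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p : p + H, p : p + Wd, :] if p else dxp


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32) -> None:
        super().__init__()
        self._params["gamma"] = np.ones(channels, dtype=dtype)
        self._params["beta"] = np.zeros(channels, dtype=dtype)
        self._buffers["running_mean"] = np.zeros(channels, dtype=dtype)
        self._buffers["running_var"] = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        g = self._params["gamma"]
        b = self._params["beta"]
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self._buffers["running_mean"][...] = (1 - m) * self._buffers["running_mean"] + m * mean
            self._buffers["running_var"][...] = (1 - m) * self._buffers["running_var"] + m * var
            inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
            xhat = (x - mean) * inv
            self._cache = (xhat, inv)
            return g * xhat + b
        mean = self._buffers["running_mean"]
        var = self._buffers["running_var"]
        return g * (x - mean) / np.sqrt(var + self.eps) + b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        g = self._params["gamma"]
        n = dout.size // dout.shape[-1]
        self._grads["gamma"] = (dout * xhat).sum(axis=(0, 1, 2))
        self._grads["beta"] = dout.sum(axis=(0, 1, 2))
        dxhat = dout * g
        s1 = dxhat.sum(axis=(0, 1, 2))
        s2 = (dxhat * xhat).sum(axis=(0, 1, 2))
        return (inv / n) * (n * dxhat - s1 - xhat * s2)


class ReLU(Module):
    def __init__(self) -> None:
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng=None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(1.0 / in_features)
        self._params["W"] = rng.normal(0.0, scale, size=(out_features, in_features)).astype(dtype)
        self._params["b"] = np.zeros(out_features, dtype=dtype)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._cache = x
        return x @ self._params["W"].T + self._params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self._grads["W"] = dout.T @ x
        self._grads["b"] = dout.sum(axis=0)
        return dout @ self._params["W"]


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1) -> None:
        super().__init__()
        self.kernel = kernel
        self.stride = stride
        self.pad = pad
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        pad_val = np.finfo(x.dtype).min if np.issubdtype(x.dtype, np.floating) else x.min()
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)), constant_values=pad_val) if p else x
        B, Hp, Wp, C = xp.shape
        Ho = (Hp - k) // s + 1
        Wo = (Wp - k) // s + 1
        win = np.empty((B, Ho, Wo, k * k, C), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                win[:, :, :, i * k + j, :] = xp[:, i : i + s * Ho : s, j : j + s * Wo : s, :]
        idx = win.argmax(axis=3)
        if train:
            self._cache = (idx, x.shape, (B, Ho, Wo))
        return np.take_along_axis(win, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, x_shape, (B, Ho, Wo) = self._cache
        self._cache = None
        k, s, p = self.kernel, self.stride, self.pad
        _, H, W, C = x_shape
        dxp = np.zeros((B, H + 2 * p, W + 2 * p, C), dtype=dout.dtype)
        for t in range(k * k):
            i, j = divmod(t, k)
            dxp[:, i : i + s * Ho : s, j : j + s * Wo : s, :] += np.where(idx == t, dout, 0)
        return dxp[:, p : p + H, p : p + W, :] if p else dxp


class GlobalAvgPool(Module):
    def __init__(self) -> None:
        super().__init__()
        self._hw = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._hw = x.shape[1:3]
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h, w = self._hw
        return np.broadcast_to(
            dout[:, None, None, :], (dout.shape[0], h, w, dout.shape[1])
        ) / (h * w)


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        super().__init__()
        self.layers = list(layers)

    def children(self) -> dict[str, Module]:
        return {str(i): layer for i, layer in enumerate(self.layers)}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class ResidualBlock(Module):
    """conv-bn-relu-conv-bn plus (projected) identity, ReLU on the sum."""

    def __init__(self, in_channels: int, out_channels: int, stride: int = 1, rng=None, dtype=np.float32) -> None:
        super().__init__()
        self.conv1 = Conv2d(in_channels, out_channels, 3, stride, 1, rng, dtype)
        self.bn1 = BatchNorm2d(out_channels, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_channels, out_channels, 3, 1, 1, rng, dtype)
        self.bn2 = BatchNorm2d(out_channels, dtype=dtype)
        self.project = stride != 1 or in_channels != out_channels
        if self.project:
            self.conv_sc = Conv2d(in_channels, out_channels, 1, stride, 0, rng, dtype)
            self.bn_sc = BatchNorm2d(out_channels, dtype=dtype)
        self._mask = None

    def children(self) -> dict[str, Module]:
        out = {
            "conv1": self.conv1,
            "bn1": self.bn1,
            "conv2": self.conv2,
            "bn2": self.bn2,
        }
        if self.project:
            out["conv_sc"] = self.conv_sc
            out["bn_sc"] = self.bn_sc
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        main = self.bn1.forward(self.conv1.forward(x, train), train)
        main = self.relu1.forward(main, train)
        main = self.bn2.forward(self.conv2.forward(main, train), train)
        short = (
            self.bn_sc.forward(self.conv_sc.forward(x, train), train)
            if self.project
            else x
        )
        y = main + short
        if train:
            self._mask = y > 0
            return y * self._mask
        return np.maximum(y, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dsum = dout * self._mask
        dmain = self.conv2.backward(self.bn2.backward(dsum))
        dmain = self.conv1.backward(self.bn1.backward(self.relu1.backward(dmain)))
        dshort = (
            self.conv_sc.backward(self.bn_sc.backward(dsum)) if self.project else dsum
        )
        return dmain + dshort
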