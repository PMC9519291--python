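"""Context-aware caries classifier.

A shared-weight residual backbone maps every tooth crop to a representation
r in R^d. For a tooth with representations r_c (itself) and r_a1..r_aK (its
anatomical neighbors, extracted by the *same* backbone):

    r_a   = mean(r_a1, ..., r_aK)                       (average pooling)
    alpha = sigmoid(W2 . sigmoid(W1 [r_c, r_a] + b1) + b2)
    r_f   = alpha * r_c + (1 - alpha) * r_a             (convex fusion)

and r_f goes through a softmax-activated linear classifier. The attention
network is sigmoid-activated in both layers, exactly as the fusion rule is
defined; alpha is therefore always in (0,1) and the fused representation is
a convex combination. When a tooth has no usable context (k_neighbors = 0,
a non-primary position, or all neighbors missing) the fusion stage is
bypassed and the classifier sees r_c directly, which makes the context
model degenerate exactly to the plain baseline.

Only the fusion network (h*(2d) + h weights, h + 1 biases) is added on top
of the baseline backbone + classifier.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import Adam, Linear, make_backbone
from .nn.layers import Module

__all__ = [
    "ModelConfig",
    "FusionNet",
    "ContextAwareModel",
    "pool_neighbors",
    "fuse",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "tiny"
    d: int = 64
    h: int = 128
    k_neighbors: int = 3
    n_classes: int = 2
    input_side: int = 48
    pooling: str = "average"
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors not in (0, 2, 3, 5):
            raise ValueError("k_neighbors must be one of 0, 2, 3, 5")
        if self.pooling != "average":
            raise ValueError("only average pooling is supported")
        if self.n_classes != 2:
            raise ValueError("binary caries classification only")
        if self.backbone == "resnet18" and self.d != 512:
            raise ValueError("resnet18 backbone has d = 512")


def pool_neighbors(reps: np.ndarray | list) -> np.ndarray:
    """Elementwise mean of 1..K neighbor representations (order-invariant)."""
    arr = np.asarray(reps, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.size == 0:
        raise ValueError("pool_neighbors needs at least one representation")
    return arr.mean(axis=0)


def fuse(r_c: np.ndarray, r_a: np.ndarray, alpha: float | np.ndarray) -> np.ndarray:
    """Convex combination alpha*r_c + (1-alpha)*r_a."""
    r_c = np.asarray(r_c, dtype=float)
    r_a = np.asarray(r_a, dtype=float)
    if r_c.shape != r_a.shape:
        raise ValueError(f"shape mismatch {r_c.shape} vs {r_a.shape}")
    a = np.asarray(alpha, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("alpha must lie in [0,1]")
    return a * r_c + (1.0 - a) * r_a


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class FusionNet(Module):
    """Two-weight-layer sigmoid MLP emitting the attention weight alpha.

    Initialization: small Gaussian weights and b2 = 2 so alpha starts near
    0.88 — the model begins close to the context-free baseline and learns
    how much context to mix in.
    """

    def __init__(self, d: int, h: int, rng=None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self._params["W1"] = rng.normal(0.0, 1.0 / np.sqrt(2 * d), size=(h, 2 * d)).astype(dtype)
        self._params["b1"] = np.zeros(h, dtype=dtype)
        self._params["W2"] = rng.normal(0.0, 1.0 / np.sqrt(h), size=(h,)).astype(dtype)
        self._params["b2"] = np.array([2.0], dtype=dtype)
        self._cache = None

    def alpha(self, r_c: np.ndarray, r_a: np.ndarray, train: bool = False) -> np.ndarray:
        """alpha for each row of (B, d) inputs; returns shape (B,)."""
        if not (np.all(np.isfinite(r_c)) and np.all(np.isfinite(r_a))):
            raise ValueError("attention inputs must be finite")
        cat = np.concatenate([r_c, r_a], axis=1)
        z1 = cat @ self._params["W1"].T + self._params["b1"]
        a1 = _sigmoid(z1)
        z2 = a1 @ self._params["W2"] + self._params["b2"][0]
        alpha = _sigmoid(z2)
        if train:
            self._cache = (cat, a1, alpha)
        return alpha

    def backward_alpha(self, dalpha: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Gradients w.r.t. r_c and r_a given dL/dalpha; fills param grads."""
        cat, a1, alpha = self._cache
        dz2 = dalpha * alpha * (1.0 - alpha)
        self._grads["W2"] = dz2 @ a1
        self._grads["b2"] = np.array([dz2.sum()], dtype=cat.dtype)
        da1 = dz2[:, None] * self._params["W2"][None, :]
        dz1 = da1 * a1 * (1.0 - a1)
        self._grads["W1"] = dz1.T @ cat
        self._grads["b1"] = dz1.sum(axis=0)
        dcat = dz1 @ self._params["W1"]
        d = cat.shape[1] // 2
        return dcat[:, :d], dcat[:, d:]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ContextAwareModel(Module):
    """Backbone + neighbor pooling + attention fusion + softmax classifier.

    ``forward_batch`` consumes a batch of current-tooth images plus one flat
    array of all present neighbor images with a segment-id vector mapping
    each neighbor to its example; the backbone runs once over the
    concatenated batch (shared weights by construction).
    """

    def __init__(self, config: ModelConfig, dtype=np.float32) -> None:
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        self.backbone = make_backbone(config.backbone, config.d, rng=rng, dtype=dtype)
        self.fusion = FusionNet(config.d, config.h, rng=rng, dtype=dtype)
        self.classifier = Linear(config.d, config.n_classes, rng=rng, dtype=dtype)
        self._cache = None

    def children(self) -> dict[str, Module]:
        return {
            "backbone": self.backbone,
            "fusion": self.fusion,
            "classifier": self.classifier,
        }

    # -- method building blocks ------------------------------------------

    def backbone_forward(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        """Representations for a (B, S, S) grayscale image batch in [0,1]."""
        x = np.asarray(images)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1] != self.config.input_side or x.shape[2] != self.config.input_side:
            raise ValueError(
                f"expected (B, {self.config.input_side}, {self.config.input_side}) input, got {x.shape}"
            )
        x = x.astype(self._dtype(), copy=False)[..., None]
        return self.backbone.forward(x, train)

    def attention_weight(self, r_c: np.ndarray, r_a: np.ndarray) -> np.ndarray:
        r_c = np.atleast_2d(np.asarray(r_c, dtype=self._dtype()))
        r_a = np.atleast_2d(np.asarray(r_a, dtype=self._dtype()))
        return self.fusion.alpha(r_c, r_a)

    def classify(self, r_f: np.ndarray, train: bool = False) -> np.ndarray:
        r = np.atleast_2d(np.asarray(r_f, dtype=self._dtype()))
        if not np.all(np.isfinite(r)):
            raise ValueError("classifier input must be finite")
        return _softmax(self.classifier.forward(r, train))

    def _dtype(self):
        return self.classifier._params["W"].dtype

    # -- full passes -----------------------------------------------------

    def forward_batch(
        self,
        x_cur: np.ndarray,
        x_nb: np.ndarray | None = None,
        seg: np.ndarray | None = None,
        train: bool = False,
    ) -> np.ndarray:
        """Class probabilities for a batch.

        x_cur: (B, S, S); x_nb: (M, S, S) neighbor images; seg: (M,)
        example index of each neighbor. Examples with no neighbors bypass
        fusion (r_f = r_c exactly).
        """
        B = x_cur.shape[0]
        if x_nb is None or len(x_nb) == 0:
            x_nb = np.zeros((0,) + x_cur.shape[1:], dtype=x_cur.dtype)
            seg = np.zeros(0, dtype=np.intp)
        seg = np.asarray(seg, dtype=np.intp)
        big = np.concatenate([x_cur, x_nb], axis=0)
        reps = self.backbone_forward(big, train)
        r_c = reps[:B]
        counts = np.bincount(seg, minlength=B)
        has_ctx = counts > 0
        r_a = np.zeros_like(r_c)
        np.add.at(r_a, seg, reps[B:])
        r_a[has_ctx] /= counts[has_ctx, None]

        r_f = r_c.copy()
        alpha = np.zeros(B, dtype=r_c.dtype)
        if has_ctx.any():
            a = self.fusion.alpha(r_c[has_ctx], r_a[has_ctx], train)
            alpha[has_ctx] = a
            r_f[has_ctx] = a[:, None] * r_c[has_ctx] + (1 - a[:, None]) * r_a[has_ctx]
        probs = _softmax(self.classifier.forward(r_f, train))
        if train:
            self._cache = (B, seg, counts, has_ctx, r_c, r_a, alpha, probs)
        return probs

    def loss_and_backward(self, labels: np.ndarray) -> float:
        """Mean cross-entropy of the last train-mode forward; runs backprop."""
        B, seg, counts, has_ctx, r_c, r_a, alpha, probs = self._cache
        y = np.asarray(labels, dtype=np.intp)
        eps = 1e-12
        loss = -float(np.mean(np.log(probs[np.arange(B), y] + eps)))
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss")
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        dr_f = self.classifier.backward(dlogits)

        dr_c = dr_f.copy()
        dr_a_full = np.zeros_like(dr_f)
        if has_ctx.any():
            a = alpha[has_ctx][:, None]
            g = dr_f[has_ctx]
            dalpha = np.einsum(
                "bd,bd->b", g, r_c[has_ctx] - r_a[has_ctx]
            )
            dc_att, da_att = self.fusion.backward_alpha(dalpha)
            dr_c[has_ctx] = a * g + dc_att
            dr_a_full[has_ctx] = (1 - a) * g + da_att
        else:
            # keep fusion grads defined (zero) when a batch has no context
            for k, v in self.fusion._params.items():
                self.fusion._grads[k] = np.zeros_like(v)
        if len(seg):
            dr_nb = dr_a_full[seg] / counts[seg][:, None].astype(dr_f.dtype)
        else:
            dr_nb = np.zeros((0, dr_f.shape[1]), dtype=dr_f.dtype)
        dbig = np.concatenate([dr_c, dr_nb], axis=0)
        self.backbone.backward(dbig)
        return loss

    def predict_proba(
        self,
        x_cur: np.ndarray,
        x_nb: np.ndarray | None = None,
        seg: np.ndarray | None = None,
    ) -> np.ndarray:
        return self.forward_batch(x_cur, x_nb, seg, train=False)

    def forward_single(
        self, image: np.ndarray, neighbor_images: list[np.ndarray] | None = None
    ) -> np.ndarray:
        """Probability vector (normal, caries) for one preprocessed tooth."""
        x_cur = np.asarray(image)[None]
        nbs = list(neighbor_images or [])
        if nbs:
            x_nb = np.stack([np.asarray(n) for n in nbs])
            seg = np.zeros(len(nbs), dtype=np.intp)
        else:
            x_nb, seg = None, None
        return self.forward_batch(x_cur, x_nb, seg, train=False)[0]

    # -- bookkeeping -----------------------------------------------------

    def extra_params_over_baseline(self) -> int:
        """Parameters added by context fusion: h*(2d) + h + h + 1."""
        return sum(int(v.size) for v in self.fusion.params().values())

    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.params(), lr=lr)


def save_checkpoint(model: ContextAwareModel, path: str | Path, meta: dict | None = None) -> None:
    """Single-file archive of weights + config (+ optional metadata)."""
    payload = {f"state/{k}": v for k, v in model.state().items()}
    payload["config_json"] = np.frombuffer(
        json.dumps({"model": asdict(model.config), "meta": meta or {}, "format": 1}).encode(),
        dtype=np.uint8,
    )
    np.savez(path, **payload)


def load_checkpoint(path: str | Path) -> tuple[ContextAwareModel, dict]:
    with np.load(path) as data:
        info = json.loads(bytes(data["config_json"].tobytes()).decode())
        model = ContextAwareModel(ModelConfig(**info["model"]))
        state = {k[len("state/") :]: data[k] for k in data.files if k.startswith("state/")}
    model.load_state(state)
    return model, info.get("meta", {})
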