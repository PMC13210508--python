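"""Neural-network building blocks on top of the autodiff engine.

Modules own named parameter Tensors and compose into the encoder/decoder
and Transformer stacks of the saliency models.  Initialization is seeded
through a numpy Generator passed at construction: convolutions and linear
layers use fan-in-scaled (He) normals, Transformer projections truncated
normals with SD 0.02.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "TransformerEncoderBlock",
    "TransformerDecoderBlock",
    "Adam",
    "AdamW",
]


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) clipped to +/- 2 std, the usual Transformer init."""
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2 * std, 2 * std)


class Module:
    """Minimal parameter container with recursive traversal."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            params.extend(_collect(v))
        return params

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            out.update(_collect_named(v, key))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(
                f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}"
            )
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(
                    f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}"
                )
            p.data = state[k].astype(np.float64).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


def _collect(v) -> list[Tensor]:
    if isinstance(v, Tensor):
        return [v] if v.requires_grad else []
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect(item))
        return out
    return []


def _collect_named(v, key: str) -> dict[str, Tensor]:
    if isinstance(v, Tensor):
        return {key: v} if v.requires_grad else {}
    if isinstance(v, Module):
        return v.named_parameters(prefix=key + ".")
    if isinstance(v, (list, tuple)):
        out = {}
        for i, item in enumerate(v):
            out.update(_collect_named(item, f"{key}.{i}"))
        return out
    return {}


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 init: str = "fan_in"):
        if init == "trunc_normal":
            w = trunc_normal(rng, (out_features, in_features))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / in_features), (out_features, in_features))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight.transpose() + self.bias


class Conv2d(Module):
    """3x3/1x1 convolution, He-init weights, small positive bias.

    The positive bias (0.01) keeps ReLU units alive at initialization;
    with narrow desk-scale widths a zero-bias layer whose activations are
    spatially correlated can die wholesale and block all gradient flow.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, padding: int,
                 rng: np.random.Generator):
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, kernel, kernel))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.full(out_ch, 0.01), requires_grad=True)
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.padding)


class MultiHeadAttention(Module):
    """Multi-head scaled-dot-product attention.

    Queries come from ``x`` (T_q x C); keys and values from ``context``
    (T_k x C).  Per head, Q/K/V are projected to d_k = C / heads columns;
    head outputs concatenate back to C channels through an output
    projection.  ``logit_scale`` selects division of the logits by
    sqrt(d_k) (the literature convention, default) or by d_k.
    """

    def __init__(self, C: int, heads: int, rng: np.random.Generator,
                 logit_scale: str = "sqrt_dk"):
        if C % heads != 0:
            raise ValueError(f"C={C} not divisible by heads={heads}")
        self.heads = heads
        self.d_k = C // heads
        if logit_scale not in ("sqrt_dk", "dk"):
            raise ValueError(f"unknown logit_scale {logit_scale!r}")
        self.scale = self.d_k**0.5 if logit_scale == "sqrt_dk" else float(self.d_k)
        self.w_q = Linear(C, C, rng, init="trunc_normal")
        self.w_k = Linear(C, C, rng, init="trunc_normal")
        self.w_v = Linear(C, C, rng, init="trunc_normal")
        self.w_o = Linear(C, C, rng, init="trunc_normal")

    def __call__(self, x: Tensor, context: Tensor) -> Tensor:
        tq, C = x.shape
        tk = context.shape[0]
        h, dk = self.heads, self.d_k
        # (T, C) -> (h, T, dk)
        q = self.w_q(x).reshape(tq, h, dk).transpose(1, 0, 2)
        k = self.w_k(context).reshape(tk, h, dk).transpose(1, 0, 2)
        v = self.w_v(context).reshape(tk, h, dk).transpose(1, 0, 2)
        logits = (q @ k.transpose(0, 2, 1)) * (1.0 / self.scale)
        attn = logits.softmax(axis=-1)
        out = attn @ v  # (h, tq, dk)
        out = out.transpose(1, 0, 2).reshape(tq, C)
        return self.w_o(out)


class FeedForward(Module):
    def __init__(self, C: int, rng: np.random.Generator, expansion: int = 4):
        self.fc1 = Linear(C, expansion * C, rng, init="trunc_normal")
        self.fc2 = Linear(expansion * C, C, rng, init="trunc_normal")

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class TransformerEncoderBlock(Module):
    """Pre-norm self-attention block: x + SA(LN(x)), then x + FF(LN(x))."""

    def __init__(self, C: int, heads: int, rng: np.random.Generator,
                 logit_scale: str = "sqrt_dk"):
        self.attn = MultiHeadAttention(C, heads, rng, logit_scale)
        self.ff = FeedForward(C, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = x.layer_norm()
        x = x + self.attn(h, h)
        x = x + self.ff(x.layer_norm())
        return x


class TransformerDecoderBlock(Module):
    """Pre-norm decoder block: optional self-attention over the image
    tokens, cross-attention with the user token as key/value source, then
    a feed-forward sublayer, each with a residual connection."""

    def __init__(self, C: int, heads: int, rng: np.random.Generator,
                 logit_scale: str = "sqrt_dk", self_attention: bool = True):
        self.self_attention = self_attention
        if self_attention:
            self.self_attn = MultiHeadAttention(C, heads, rng, logit_scale)
        self.cross_attn = MultiHeadAttention(C, heads, rng, logit_scale)
        self.ff = FeedForward(C, rng)

    def __call__(self, x: Tensor, context: Tensor) -> Tensor:
        if self.self_attention:
            h = x.layer_norm()
            x = x + self.self_attn(h, h)
        x = x + self.cross_attn(x.layer_norm(), context.layer_norm())
        x = x + self.ff(x.layer_norm())
        return x


class Adam:
    """Adam with optional decoupled weight decay (AdamW when decay > 0)."""

    def __init__(self, params: list[Tensor], lr: float, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def AdamW(params: list[Tensor], lr: float, weight_decay: float = 0.05, **kw) -> Adam:
    return Adam(params, lr, weight_decay=weight_decay, **kw)
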