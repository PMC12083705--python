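"""Trainable clean-image estimator f(x_t, y, noise level).

A U-shaped encoder/decoder over a 2-channel stack of the noisy state x_t
and the corrupted image y, with windowed (Swin-style) self-attention
replacing conventional attention at the two lowest-resolution levels.
The scalar noise level sqrt(beta_t) enters through a sinusoidal embedding
of its logarithm and modulates every residual block, so the network is
agnostic to the length of the schedule it is queried under — a model
trained with a 20-step schedule can serve a 4-step sampler.

The network is implemented in numpy with reverse-mode differentiation by
autograd and optimized with Adam; parameters are float32.  Feature maps
are channels-last, convolutions are expressed as nine shifted matrix
products, and window attention uses cyclic shifts between the paired
non-shifted/shifted blocks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.extend import defvjp, primitive
from autograd.misc.flatten import flatten
from autograd.tracer import getval
from numpy.lib.stride_tricks import sliding_window_view

from .schedule import ScheduleConfig

__all__ = [
    "DenoiserSpec",
    "DenoiserModel",
    "build_denoiser",
    "denoise",
    "SPEC_PRESETS",
    "ConstantDenoiser",
]

_GROUPS = 4
_EPS = 1e-5


@dataclass(frozen=True)
class DenoiserSpec:
    """Architecture hyperparameters.

    ``base_channels`` doubles at each of ``depth`` resolution levels;
    attention sits at the two lowest-resolution levels with windows of
    edge ``swin_window``.  Input grids must be divisible by
    ``2**(depth-1)`` and by the window size at the attention levels.
    """

    base_channels: int = 16
    depth: int = 3
    swin_window: int = 4
    n_heads: int = 2
    time_embed_dim: int = 64

    def __post_init__(self) -> None:
        if self.base_channels % _GROUPS:
            raise ValueError(
                f"base_channels must be divisible by {_GROUPS}"
            )
        if self.depth < 2:
            raise ValueError("depth must be at least 2")
        ch = self.base_channels * 2 ** (self.depth - 1)
        if ch % self.n_heads:
            raise ValueError("channel count not divisible by n_heads")

    @property
    def channels(self) -> list[int]:
        return [self.base_channels * 2**i for i in range(self.depth)]

    @property
    def attn_levels(self) -> set[int]:
        return {self.depth - 2, self.depth - 1}

    def validate_grid(self, shape: tuple[int, int]) -> None:
        h, w = shape
        div = 2 ** (self.depth - 1)
        if h % div or w % div:
            raise ValueError(
                f"grid {shape} not divisible by pyramid factor {div}"
            )
        for lvl in self.attn_levels:
            if (h // 2**lvl) % self.swin_window or (
                w // 2**lvl
            ) % self.swin_window:
                raise ValueError(
                    f"grid {shape} incompatible with window "
                    f"{self.swin_window} at level {lvl}"
                )


SPEC_PRESETS = {
    "tiny": DenoiserSpec(),
    "paper": DenoiserSpec(
        base_channels=64,
        depth=4,
        swin_window=8,
        n_heads=4,
        time_embed_dim=256,
    ),
}


# ---------------------------------------------------------------------------
# differentiable building blocks (channels-last, autograd-traceable)


def _silu(x):
    return x * 0.5 * (anp.tanh(0.5 * x) + 1.0)


def _pad1(x):
    b, h, w, c = x.shape
    zr = anp.zeros((b, 1, w, c), dtype=x.dtype)
    x = anp.concatenate([zr, x, zr], axis=1)
    zc = anp.zeros((b, h + 2, 1, c), dtype=x.dtype)
    return anp.concatenate([zc, x, zc], axis=2)


def _im2col(xp, stride):
    """(B, Hp, Wp, C) padded -> (B*Ho*Wo, 9C) patch matrix."""
    b, hp, wp, c = xp.shape
    h, w = hp - 2, wp - 2
    ho, wo = -(-h // stride), -(-w // stride)
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (B,H,W,C,3,3)
    win = win[:, ::stride, ::stride]
    cols = np.ascontiguousarray(np.moveaxis(win, 3, 5))  # (B,Ho,Wo,3,3,C)
    return cols.reshape(b * ho * wo, 9 * c), (b, ho, wo)


@primitive
def _conv_padded(xp, wgt, stride):
    """Valid 3x3 convolution of a pre-padded channels-last tensor.

    Implemented as one GEMM over a sliding-window view; registered as an
    autograd primitive with a hand-written adjoint (the generic
    slice-gradient path is far too slow for a training loop).
    """
    c, co = xp.shape[3], wgt.shape[3]
    cols, (b, ho, wo) = _im2col(xp, stride)
    out = cols @ wgt.reshape(9 * c, co)
    return out.reshape(b, ho, wo, co)


def _conv_padded_vjp_x(ans, xp, wgt, stride):
    b, hp, wp, c = xp.shape
    h, w = hp - 2, wp - 2

    def vjp(g):
        _, ho, wo, co = g.shape
        gw = g.reshape(b * ho * wo, co) @ wgt.reshape(9 * c, co).T
        gw = gw.reshape(b, ho, wo, 3, 3, c)
        dxp = np.zeros_like(xp)
        for di in range(3):
            for dj in range(3):
                dxp[:, di : di + h : stride, dj : dj + w : stride, :] += gw[
                    :, :, :, di, dj, :
                ]
        return dxp

    return vjp


def _conv_padded_vjp_w(ans, xp, wgt, stride):
    c, co = xp.shape[3], wgt.shape[3]

    def vjp(g):
        cols, (b, ho, wo) = _im2col(xp, stride)
        dw = cols.T @ g.reshape(b * ho * wo, co)
        return dw.reshape(wgt.shape)

    return vjp


defvjp(_conv_padded, _conv_padded_vjp_x, _conv_padded_vjp_w)


def _conv3x3(x, p, stride=1):
    """3x3 convolution with zero padding (GEMM primitive + bias)."""
    return _conv_padded(_pad1(x), p["W"], stride) + p["b"]


def _conv1x1(x, p):
    return anp.matmul(x, p["W"]) + p["b"]


def _group_norm(x, gain, bias):
    b, h, w, c = x.shape
    xg = anp.reshape(x, (b, h, w, _GROUPS, c // _GROUPS))
    mu = anp.mean(xg, axis=(1, 2, 4), keepdims=True)
    var = anp.mean((xg - mu) ** 2, axis=(1, 2, 4), keepdims=True)
    xg = (xg - mu) / anp.sqrt(var + _EPS)
    return anp.reshape(xg, (b, h, w, c)) * gain + bias


def _layer_norm(x, gain, bias):
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=-1, keepdims=True)
    return (x - mu) / anp.sqrt(var + _EPS) * gain + bias


def _upsample2(x):
    b, h, w, c = x.shape
    x = anp.reshape(x, (b, h, 1, w, 1, c))
    x = x * anp.ones((1, 1, 2, 1, 2, 1), dtype=x.dtype)
    return anp.reshape(x, (b, 2 * h, 2 * w, c))


def _roll2(x, sh, sw):
    """np.roll along the two spatial axes via concatenation."""
    _, h, w, _ = x.shape
    sh %= h
    sw %= w
    if sh:
        x = anp.concatenate([x[:, h - sh :], x[:, : h - sh]], axis=1)
    if sw:
        x = anp.concatenate([x[:, :, w - sw :], x[:, :, : w - sw]], axis=2)
    return x


def _time_embedding(levels, dim):
    """Sinusoidal features of the log noise level."""
    half = dim // 2
    freqs = np.exp(np.linspace(0.0, np.log(100.0), half)).astype(np.float32)
    pos = anp.log(anp.maximum(levels, 1e-8))
    args = pos[:, None] * freqs[None, :]
    return anp.concatenate([anp.sin(args), anp.cos(args)], axis=1)


def _res_block(x, temb, p):
    h = _conv3x3(_silu(_group_norm(x, p["g1"], p["gb1"])), p["c1"])
    h = h + (anp.matmul(temb, p["tW"]) + p["tb"])[:, None, None, :]
    h = _conv3x3(_silu(_group_norm(h, p["g2"], p["gb2"])), p["c2"])
    skip = _conv1x1(x, p["cs"]) if "cs" in p else x
    return skip + h


def _window_attention(x, p, window, heads, shifted):
    b, h, w, c = x.shape
    shift = window // 2 if shifted else 0
    if shift:
        x = _roll2(x, -shift, -shift)
    nh, nw = h // window, w // window
    n = window * window
    dh = c // heads

    t = _layer_norm(x, p["ln1g"], p["ln1b"])
    t = anp.reshape(t, (b, nh, window, nw, window, c))
    t = anp.transpose(t, (0, 1, 3, 2, 4, 5))
    t = anp.reshape(t, (b * nh * nw, n, c))

    def _heads(z):
        z = anp.reshape(z, (b * nh * nw, n, heads, dh))
        return anp.transpose(z, (0, 2, 1, 3))

    q = _heads(anp.matmul(t, p["Wq"]) + p["bq"])
    k = _heads(anp.matmul(t, p["Wk"]) + p["bk"])
    v = _heads(anp.matmul(t, p["Wv"]) + p["bv"])
    att = anp.matmul(q, anp.transpose(k, (0, 1, 3, 2))) / np.sqrt(dh)
    att = att + p["pbias"][None]
    att = att - anp.max(att, axis=-1, keepdims=True)
    att = anp.exp(att)
    att = att / anp.sum(att, axis=-1, keepdims=True)
    o = anp.matmul(att, v)
    o = anp.transpose(o, (0, 2, 1, 3))
    o = anp.reshape(o, (b * nh * nw, n, c))
    o = anp.matmul(o, p["Wproj"]) + p["bproj"]
    o = anp.reshape(o, (b, nh, nw, window, window, c))
    o = anp.transpose(o, (0, 1, 3, 2, 4, 5))
    x = x + anp.reshape(o, (b, h, w, c))

    m = _layer_norm(x, p["ln2g"], p["ln2b"])
    m = anp.matmul(_silu(anp.matmul(m, p["Wm1"]) + p["bm1"]), p["Wm2"]) + p["bm2"]
    x = x + m
    if shift:
        x = _roll2(x, shift, shift)
    return x


def _forward(params, x_t, y, levels, spec: DenoiserSpec):
    inp = anp.stack([x_t, y], axis=-1)
    temb = _time_embedding(levels, spec.time_embed_dim)
    temb = anp.matmul(temb, params["temb"]["W1"]) + params["temb"]["b1"]
    temb = anp.matmul(_silu(temb), params["temb"]["W2"]) + params["temb"]["b2"]

    h = _conv3x3(inp, params["stem"])
    skips = []
    for i, lvl in enumerate(params["enc"]):
        h = _res_block(h, temb, lvl["res"])
        for j, ap in enumerate(lvl.get("attn", [])):
            h = _window_attention(
                h, ap, spec.swin_window, spec.n_heads, shifted=bool(j % 2)
            )
        skips.append(h)
        if "down" in lvl:
            h = _conv3x3(h, lvl["down"], stride=2)
    for dec, skip in zip(params["dec"], reversed(skips[:-1])):
        h = _upsample2(h)
        h = _conv3x3(h, dec["up"])
        h = anp.concatenate([h, skip], axis=-1)
        h = _res_block(h, temb, dec["res"])
        for j, ap in enumerate(dec.get("attn", [])):
            h = _window_attention(
                h, ap, spec.swin_window, spec.n_heads, shifted=bool(j % 2)
            )
    h = _silu(_group_norm(h, params["head"]["g"], params["head"]["b"]))
    out = _conv3x3(h, params["head"]["c"])
    out = anp.reshape(out, out.shape[:3])
    w = params["skip_w"]
    return out + w[0] * x_t + w[1] * y


# ---------------------------------------------------------------------------
# initialization


def _f32(a):
    return np.asarray(a, dtype=np.float32)


def _init_conv3x3(rng, cin, cout, scale=1.0):
    std = scale * np.sqrt(2.0 / (9 * cin))
    return {
        "W": _f32(rng.normal(0, std, (3, 3, cin, cout))),
        "b": _f32(np.zeros(cout)),
    }


def _init_linear(rng, cin, cout, scale=1.0):
    std = scale * np.sqrt(1.0 / cin)
    return _f32(rng.normal(0, std, (cin, cout))), _f32(np.zeros(cout))


def _init_res_block(rng, cin, cout, tdim):
    p = {
        "g1": _f32(np.ones(cin)),
        "gb1": _f32(np.zeros(cin)),
        "c1": _init_conv3x3(rng, cin, cout),
        "g2": _f32(np.ones(cout)),
        "gb2": _f32(np.zeros(cout)),
        "c2": _init_conv3x3(rng, cout, cout, scale=0.5),
    }
    p["tW"], p["tb"] = _init_linear(rng, tdim, cout)
    if cin != cout:
        wcs, bcs = _init_linear(rng, cin, cout)
        p["cs"] = {"W": wcs, "b": bcs}
    return p


def _init_attn(rng, c, heads, window, mlp_ratio=2):
    n = window * window
    wq, bq = _init_linear(rng, c, c)
    wk, bk = _init_linear(rng, c, c)
    wv, bv = _init_linear(rng, c, c)
    wproj, bproj = _init_linear(rng, c, c, scale=0.5)
    wm1, bm1 = _init_linear(rng, c, mlp_ratio * c)
    wm2, bm2 = _init_linear(rng, mlp_ratio * c, c, scale=0.5)
    return {
        "ln1g": _f32(np.ones(c)),
        "ln1b": _f32(np.zeros(c)),
        "Wq": wq,
        "bq": bq,
        "Wk": wk,
        "bk": bk,
        "Wv": wv,
        "bv": bv,
        "Wproj": wproj,
        "bproj": bproj,
        "pbias": _f32(np.zeros((heads, n, n))),
        "ln2g": _f32(np.ones(c)),
        "ln2b": _f32(np.zeros(c)),
        "Wm1": wm1,
        "bm1": bm1,
        "Wm2": wm2,
        "bm2": bm2,
    }


def _init_params(spec: DenoiserSpec, rng: np.random.Generator) -> dict:
    chans = spec.channels
    tdim = spec.time_embed_dim
    w1, b1 = _init_linear(rng, tdim, tdim)
    w2, b2 = _init_linear(rng, tdim, tdim)
    params = {
        "stem": _init_conv3x3(rng, 2, chans[0]),
        "temb": {"W1": w1, "b1": b1, "W2": w2, "b2": b2},
        "enc": [],
        "dec": [],
        "head": {
            "g": _f32(np.ones(chans[0])),
            "b": _f32(np.zeros(chans[0])),
            "c": _init_conv3x3(rng, chans[0], 1, scale=0.1),
        },
        "skip_w": _f32([1.0, 0.0]),
    }
    for i, c in enumerate(chans):
        lvl = {"res": _init_res_block(rng, c, c, tdim)}
        if i in spec.attn_levels:
            lvl["attn"] = [
                _init_attn(rng, c, spec.n_heads, spec.swin_window)
                for _ in range(2)
            ]
        if i < spec.depth - 1:
            lvl["down"] = _init_conv3x3(rng, c, chans[i + 1])
        params["enc"].append(lvl)
    for i in range(spec.depth - 2, -1, -1):
        dec = {
            "up": _init_conv3x3(rng, chans[i + 1], chans[i]),
            "res": _init_res_block(rng, 2 * chans[i], chans[i], tdim),
        }
        if i in spec.attn_levels:
            dec["attn"] = [
                _init_attn(rng, chans[i], spec.n_heads, spec.swin_window)
                for _ in range(2)
            ]
        params["dec"].append(dec)
    return params


# ---------------------------------------------------------------------------
# model


class DenoiserModel:
    """Stateful wrapper: parameters, Adam optimizer, and I/O helpers."""

    def __init__(
        self,
        spec: DenoiserSpec,
        params: dict,
        gamma: Optional[float] = None,
        schedule_config: Optional[ScheduleConfig] = None,
        lr: float = 2e-3,
        normalization: str = "per-slice max to [0, 1]",
    ):
        self.spec = spec
        self.params = params
        self.schedule_config = schedule_config
        self.gamma = gamma if gamma is not None else (
            schedule_config.gamma if schedule_config else None
        )
        self.lr = lr
        self.normalization = normalization
        self._adam_m = None
        self._adam_v = None
        self._adam_t = 0
        self._ema = None

    # -- inference ----------------------------------------------------------

    @property
    def n_params(self) -> int:
        flat, _ = flatten(self.params)
        return int(flat.size)

    def _apply(self, params, x_t, y, levels):
        return _forward(params, x_t, y, levels, self.spec)

    def predict(self, x_t: np.ndarray, y: np.ndarray, level) -> np.ndarray:
        """Estimate the clean image from (x_t, y) at a given noise level.

        Accepts a single (H, W) pair with a scalar level or a batched
        (B, H, W) stack with per-element levels.
        """
        x_t = np.asarray(x_t, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        single = x_t.ndim == 2
        if single:
            x_t = x_t[None]
            y = y[None]
            levels = np.asarray([level], dtype=np.float32)
        else:
            levels = np.atleast_1d(np.asarray(level, dtype=np.float32))
        if x_t.shape != y.shape:
            raise ValueError("x_t and y must share a grid")
        self.spec.validate_grid(x_t.shape[1:])
        out = self._apply(self.params, x_t, y, levels)
        out = np.asarray(out, dtype=float)
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("denoiser produced non-finite output")
        return out[0] if single else out

    # -- training -----------------------------------------------------------

    def _loss(self, params, x_t, y, levels, target, l2_only):
        f = self._apply(params, x_t, y, levels)
        d = f - target
        l2 = anp.mean(d**2)
        if l2_only:
            return l2, l2, 0.0 * l2
        l1 = anp.mean(anp.abs(d))
        return l2 + l1, l2, l1

    def train_batch(self, x_t, y, levels, target, l2_only: bool = False):
        """One Adam update on the combined loss; returns its components."""
        from .diffusion import LossValue

        x_t = np.asarray(x_t, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        target = np.asarray(target, dtype=np.float32)
        levels = np.asarray(levels, dtype=np.float32)
        self.spec.validate_grid(x_t.shape[1:])

        parts = {}

        def objective(params):
            total, l2, l1 = self._loss(
                params, x_t, y, levels, target, l2_only
            )
            parts["l2"] = l2
            parts["l1"] = l1
            return total

        total, grads = value_and_grad(objective)(self.params)
        self._adam_step(grads)
        l2 = float(getval(parts["l2"]))
        l1 = float(getval(parts["l1"]))
        return LossValue(total=float(total), l2_part=l2, l1_part=l1)

    def _adam_step(self, grads, beta1=0.9, beta2=0.999, eps=1e-8):
        def zeros_like_tree(node):
            if isinstance(node, dict):
                return {k: zeros_like_tree(v) for k, v in node.items()}
            if isinstance(node, list):
                return [zeros_like_tree(v) for v in node]
            return np.zeros_like(node)

        if self._adam_m is None:
            self._adam_m = zeros_like_tree(self.params)
            self._adam_v = zeros_like_tree(self.params)
        self._adam_t += 1
        c1 = 1 - beta1**self._adam_t
        c2 = 1 - beta2**self._adam_t

        def upd(p, g, m, v):
            if isinstance(p, dict):
                for k in p:
                    p[k] = upd(p[k], g[k], m[k], v[k])
                return p
            if isinstance(p, list):
                return [upd(pi, gi, mi, vi) for pi, gi, mi, vi in zip(p, g, m, v)]
            g = np.asarray(g, dtype=np.float32)
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            return (p - self.lr * (m / c1) / (np.sqrt(v / c2) + eps)).astype(
                np.float32
            )

        self.params = upd(self.params, grads, self._adam_m, self._adam_v)

    # -- weight averaging ----------------------------------------------------

    def ema_update(self, decay: float) -> None:
        """Fold the current weights into an exponential moving average."""

        def walk(e, p):
            if isinstance(p, dict):
                return {k: walk(e[k], p[k]) for k in p}
            if isinstance(p, list):
                return [walk(ei, pi) for ei, pi in zip(e, p)]
            return decay * e + (1 - decay) * p

        if self._ema is None:
            import copy

            self._ema = copy.deepcopy(self.params)
        else:
            self._ema = walk(self._ema, self.params)

    def swap_in_ema(self) -> None:
        """Replace the live weights with their moving average (done once
        at the end of training; averaged weights sample better)."""
        if self._ema is not None:
            self.params = self._ema
            self._ema = None

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Self-describing checkpoint: weights + spec + schedule metadata."""
        named = {}

        def walk(node, prefix):
            if isinstance(node, dict):
                for k, v in node.items():
                    walk(v, f"{prefix}.{k}")
            elif isinstance(node, list):
                for i, v in enumerate(node):
                    walk(v, f"{prefix}.{i}")
            else:
                named[prefix] = node

        walk(self.params, "p")
        meta = {
            "spec": asdict(self.spec),
            "gamma": self.gamma,
            "schedule_config": asdict(self.schedule_config)
            if self.schedule_config
            else None,
            "lr": self.lr,
            "normalization": self.normalization,
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        ), **named)

    @classmethod
    def load(cls, path) -> "DenoiserModel":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        spec = DenoiserSpec(**meta["spec"])
        model = build_denoiser(spec)
        flat_named = {k[2:]: data[k] for k in data.files if k != "__meta__"}

        def walk(node, prefix):
            if isinstance(node, dict):
                return {k: walk(v, f"{prefix}.{k}" if prefix else k)
                        for k, v in node.items()}
            if isinstance(node, list):
                return [walk(v, f"{prefix}.{i}") for i, v in enumerate(node)]
            return flat_named[prefix]

        model.params = walk(model.params, "")
        model.gamma = meta["gamma"]
        if meta["schedule_config"]:
            model.schedule_config = ScheduleConfig(**meta["schedule_config"])
        model.lr = meta["lr"]
        model.normalization = meta["normalization"]
        return model


def build_denoiser(
    spec: DenoiserSpec | str = "tiny",
    seed: int = 0,
    schedule_config: Optional[ScheduleConfig] = None,
    lr: float = 2e-3,
) -> DenoiserModel:
    """Construct a randomly initialized denoiser.

    ``spec`` may be a DenoiserSpec or a preset name ('tiny', 'paper').
    """
    if isinstance(spec, str):
        try:
            spec = SPEC_PRESETS[spec]
        except KeyError:
            raise ValueError(
                f"unknown preset {spec!r}; options: {sorted(SPEC_PRESETS)}"
            ) from None
    rng = np.random.default_rng(seed)
    params = _init_params(spec, rng)
    return DenoiserModel(
        spec, params, schedule_config=schedule_config, lr=lr
    )


def denoise(model: DenoiserModel, x_t, y, level) -> np.ndarray:
    """Functional alias for ``model.predict``."""
    return model.predict(x_t, y, level)


class ConstantDenoiser:
    """Oracle stand-in returning a fixed image; used for exactness checks."""

    def __init__(self, image: np.ndarray, gamma: Optional[float] = None):
        self.image = np.asarray(image, dtype=float)
        self.gamma = gamma

    def predict(self, x_t, y, level):
        return self.image.copy()
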