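"""Neural-network building blocks on top of the autograd engine.

Parameters live in a flat ``dict[str, Tensor]`` keyed by dotted names
(``"prot.gcn0.W"``); the flat manifest makes freezing, checkpointing and
low-rank adaptation straightforward.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .autograd import Tensor

__all__ = [
    "glorot", "param", "linear", "layer_norm", "init_gru_cell", "gru_cell",
    "Adam", "save_params", "load_params", "manifest",
]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier uniform initialisation."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def param(data: np.ndarray, name: str) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True, name=name)


def linear(x: Tensor, W: Tensor, b: Tensor | None = None) -> Tensor:
    out = x @ W
    if b is not None:
        out = out + b
    return out


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise over the last axis, then apply learnable gain and bias."""
    mu = x.mean(axis=-1, keepdims=True)
    centred = x - mu
    var = (centred ** 2).mean(axis=-1, keepdims=True)
    return centred * ((var + eps) ** -0.5) * gain + bias


def init_gru_cell(rng: np.random.Generator, d_in: int, d_hidden: int,
                  prefix: str) -> dict[str, Tensor]:
    p = {}
    for gate in ("z", "r", "n"):
        p[f"{prefix}.W{gate}"] = param(glorot(rng, d_in, d_hidden), f"{prefix}.W{gate}")
        p[f"{prefix}.U{gate}"] = param(glorot(rng, d_hidden, d_hidden), f"{prefix}.U{gate}")
        p[f"{prefix}.b{gate}"] = param(np.zeros(d_hidden), f"{prefix}.b{gate}")
    return p


def gru_cell(x: Tensor, h: Tensor, params: dict[str, Tensor], prefix: str) -> Tensor:
    """Standard gated recurrent unit update: h' = (1-z)*n + z*h."""
    g = lambda k: params[f"{prefix}.{k}"]
    z = (x @ g("Wz") + h @ g("Uz") + g("bz")).sigmoid()
    r = (x @ g("Wr") + h @ g("Ur") + g("br")).sigmoid()
    n = (x @ g("Wn") + (r * h) @ g("Un") + g("bn")).tanh()
    return (1.0 - z) * n + z * h


class Adam:
    """Adaptive-moment optimiser over a named parameter dict.

    Only names in ``trainable`` are updated; all other parameters are left
    bit-identical, which the fine-tuning strategies rely on.
    """

    def __init__(self, params: dict[str, Tensor], lr: float = 5e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self, trainable: set[str] | None = None):
        self.t += 1
        for name, p in self.params.items():
            if trainable is not None and name not in trainable:
                continue
            if p.grad is None:
                continue
            m = self._m.setdefault(name, np.zeros_like(p.data))
            v = self._v.setdefault(name, np.zeros_like(p.data))
            m[:] = self.b1 * m + (1 - self.b1) * p.grad
            v[:] = self.b2 * v + (1 - self.b2) * p.grad ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def manifest(params: dict[str, Tensor]) -> dict[str, list[int]]:
    """Layer name -> shape, for checkpoint interoperability and freezing."""
    return {name: list(p.data.shape) for name, p in sorted(params.items())}


def save_params(path: str | Path, params: dict[str, Tensor],
                meta: dict | None = None) -> None:
    """Write a named-array checkpoint (.npz) plus a JSON manifest sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, **{k: v.data for k, v in params.items()})
    side = {"manifest": manifest(params)}
    if meta:
        side["meta"] = meta
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(side, indent=1))


def load_params(path: str | Path) -> tuple[dict[str, Tensor], dict]:
    path = Path(path)
    try:
        with np.load(path) as npz:
            params = {k: param(npz[k], k) for k in npz.files}
    except Exception as exc:
        raise ValueError(f"corrupt or unreadable checkpoint: {path}") from exc
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text()).get("meta", {})
    return params, meta
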