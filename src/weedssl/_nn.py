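"""Minimal dense neural-network primitives with hand-written gradients.

The detector's learnable part is a per-location multilayer perceptron (a
stack of shared linear layers, i.e. 1x1 convolutions over the feature
grid) with several linear output heads.  Parameters live in a flat
``dict[str, np.ndarray]`` so exponential-moving-average updates and
checkpointing can treat them uniformly.
"""

from __future__ import annotations

import numpy as np


def he_init(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    return rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)


class MLPWithHeads:
    """Shared ReLU trunk feeding independent linear heads.

    Parameters
    ----------
    n_in
        Input feature dimension.
    trunk_widths
        Hidden widths of the trunk, e.g. ``(96, 96)``.
    head_dims
        Mapping head name -> output dimension.
    head_bias_init
        Optional constant bias per head (e.g. the focal-loss prior logit
        for the classification head).
    """

    def __init__(
        self,
        n_in: int,
        trunk_widths: tuple[int, ...],
        head_dims: dict[str, int],
        rng: np.random.Generator,
        head_bias_init: dict[str, float] | None = None,
    ) -> None:
        self.n_in = n_in
        self.trunk_widths = tuple(trunk_widths)
        self.head_dims = dict(head_dims)
        head_bias_init = head_bias_init or {}
        self.params: dict[str, np.ndarray] = {}
        prev = n_in
        for i, w in enumerate(self.trunk_widths):
            self.params[f"trunk{i}_W"] = he_init(rng, prev, w)
            self.params[f"trunk{i}_b"] = np.zeros(w)
            prev = w
        for name, dim in self.head_dims.items():
            self.params[f"head_{name}_W"] = he_init(rng, prev, dim) * 0.1
            self.params[f"head_{name}_b"] = np.full(
                dim, head_bias_init.get(name, 0.0), dtype=np.float64
            )

    def forward(self, x: np.ndarray) -> tuple[dict[str, np.ndarray], dict]:
        """Return head outputs and a cache for :meth:`backward`."""
        acts = [x]
        h = x
        for i in range(len(self.trunk_widths)):
            h = h @ self.params[f"trunk{i}_W"] + self.params[f"trunk{i}_b"]
            h = np.maximum(h, 0.0)
            acts.append(h)
        outputs = {
            name: h @ self.params[f"head_{name}_W"] + self.params[f"head_{name}_b"]
            for name in self.head_dims
        }
        return outputs, {"acts": acts}

    def backward(
        self, cache: dict, head_grads: dict[str, np.ndarray]
    ) -> dict[str, np.ndarray]:
        """Parameter gradients given dLoss/dOutput for each head."""
        acts = cache["acts"]
        h = acts[-1]
        grads: dict[str, np.ndarray] = {}
        dh = np.zeros_like(h)
        for name in self.head_dims:
            dy = head_grads.get(name)
            if dy is None:
                grads[f"head_{name}_W"] = np.zeros_like(
                    self.params[f"head_{name}_W"]
                )
                grads[f"head_{name}_b"] = np.zeros_like(
                    self.params[f"head_{name}_b"]
                )
                continue
            grads[f"head_{name}_W"] = h.T @ dy
            grads[f"head_{name}_b"] = dy.sum(axis=0)
            dh = dh + dy @ self.params[f"head_{name}_W"].T
        for i in reversed(range(len(self.trunk_widths))):
            dh = dh * (acts[i + 1] > 0.0)
            grads[f"trunk{i}_W"] = acts[i].T @ dh
            grads[f"trunk{i}_b"] = dh.sum(axis=0)
            dh = dh @ self.params[f"trunk{i}_W"].T
        return grads


class SGDMomentum:
    """Plain SGD with classical momentum over a parameter dict."""

    def __init__(self, lr: float, momentum: float = 0.9) -> None:
        self.lr = lr
        self.momentum = momentum
        self.velocity: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for name, g in grads.items():
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite gradient in {name}")
            v = self.velocity.get(name)
            v = g if v is None else self.momentum * v + g
            self.velocity[name] = v
            params[name] -= self.lr * v


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)
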