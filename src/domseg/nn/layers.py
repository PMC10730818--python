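"""Parameterised layers built on the autograd engine.

Includes the pieces the segmentation network needs: linear maps, layer
normalisation, a two-layer bidirectional GRU with a hand-derived
backpropagation-through-time backward pass (fused into a single tape node so
long chains stay cheap), and the rectified-Adam optimiser.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = ["Module", "Linear", "LayerNorm", "BiGRU", "RAdam"]


class Module:
    """Container tracking parameters through attribute registration."""

    def named_parameters(self, prefix: str = ""):
        out = []

        def collect(key, val):
            if isinstance(val, Tensor):
                if val.requires_grad:
                    out.append((key, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(key))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    collect(f"{key}.{i}", item)

        for name, val in vars(self).items():
            collect(f"{prefix}.{name}" if prefix else name, val)
        return out

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self):
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state):
        for k, v in self.named_parameters():
            v.data[...] = state[k]


def _uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.W = Tensor(_uniform(rng, d_in, (d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc / (var + self.eps).sqrt()
        return xhat * self.gamma + self.beta


# --------------------------------------------------------------------- GRU


def _gru_direction(x: Tensor, Wih: Tensor, Whh: Tensor, bih: Tensor, bhh: Tensor,
                   reverse: bool) -> Tensor:
    """One GRU layer in one direction over a [N, D] sequence; returns [N, H].

    Gate convention (r, z, n):
        r = sigmoid(x Wir + bir + h Whr + bhr)
        z = sigmoid(x Wiz + biz + h Whz + bhz)
        n = tanh(x Win + bin + r * (h Whn + bhn))
        h' = (1 - z) * n + z * h
    Forward and the full BPTT backward are fused into one tape node.
    """
    X = x.data[::-1] if reverse else x.data
    N = X.shape[0]
    H = Whh.data.shape[0]
    Wih_d, Whh_d, bih_d, bhh_d = Wih.data, Whh.data, bih.data, bhh.data

    pre_i = X @ Wih_d + bih_d  # [N, 3H]
    hs = np.zeros((N + 1, H))
    R = np.empty((N, H))
    Z = np.empty((N, H))
    Nn = np.empty((N, H))
    HN = np.empty((N, H))  # h-side candidate preactivation (h Whn + bhn)
    h = np.zeros(H)
    for t in range(N):
        pre_h = h @ Whh_d + bhh_d
        r = 1.0 / (1.0 + np.exp(-(pre_i[t, :H] + pre_h[:H])))
        z = 1.0 / (1.0 + np.exp(-(pre_i[t, H:2 * H] + pre_h[H:2 * H])))
        hn = pre_h[2 * H:]
        n = np.tanh(pre_i[t, 2 * H:] + r * hn)
        h = (1.0 - z) * n + z * h
        R[t], Z[t], Nn[t], HN[t], hs[t + 1] = r, z, n, hn, h

    out_data = hs[1:][::-1].copy() if reverse else hs[1:].copy()
    out = Tensor(out_data)
    parents = (x, Wih, Whh, bih, bhh)
    if not any(p.requires_grad for p in parents):
        return out

    def back(g):
        dout = g[::-1] if reverse else g
        dGi = np.empty((N, 3 * H))
        dGh = np.empty((N, 3 * H))
        WhhT = Whh_d.T
        dh = np.zeros(H)
        for t in range(N - 1, -1, -1):
            dht = dout[t] + dh
            r, z, n, hn, hprev = R[t], Z[t], Nn[t], HN[t], hs[t]
            dn = dht * (1.0 - z)
            dz = dht * (hprev - n)
            dh = dht * z
            dn_pre = dn * (1.0 - n * n)
            dhn = dn_pre * r
            dr_pre = dn_pre * hn * r * (1.0 - r)
            dz_pre = dz * z * (1.0 - z)
            dGi[t, :H], dGi[t, H:2 * H], dGi[t, 2 * H:] = dr_pre, dz_pre, dn_pre
            dgh = np.concatenate([dr_pre, dz_pre, dhn])
            dGh[t] = dgh
            dh = dh + dgh @ WhhT
        x._accum((dGi @ Wih_d.T)[::-1] if reverse else dGi @ Wih_d.T)
        Wih._accum(X.T @ dGi)
        Whh._accum(hs[:-1].T @ dGh)
        bih._accum(dGi.sum(axis=0))
        bhh._accum(dGh.sum(axis=0))

    out.requires_grad = True
    out._parents = parents
    out._backward = back
    return out


class BiGRU(Module):
    """Multi-layer bidirectional GRU over a length-N sequence; output [N, 2H]."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator, n_layers: int = 2):
        self.hidden = hidden
        self.layers = []
        for layer in range(n_layers):
            din = d_in if layer == 0 else 2 * hidden
            per_dir = []
            for _ in range(2):
                per_dir.append(_GRUDirectionParams(din, hidden, rng))
            self.layers.append(per_dir)

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for fwd, bwd in self.layers:
            out_f = _gru_direction(h, fwd.Wih, fwd.Whh, fwd.bih, fwd.bhh, reverse=False)
            out_b = _gru_direction(h, bwd.Wih, bwd.Whh, bwd.bih, bwd.bhh, reverse=True)
            h = concat([out_f, out_b], axis=-1)
        return h

    def final_state(self, out: Tensor) -> Tensor:
        """Final timestep of each direction of the last layer: [2H]."""
        H = self.hidden
        return concat([out[out.shape[0] - 1, :H], out[0, H:]], axis=0)


class _GRUDirectionParams(Module):
    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.Wih = Tensor(_uniform(rng, hidden, (d_in, 3 * hidden)), requires_grad=True)
        self.Whh = Tensor(_uniform(rng, hidden, (hidden, 3 * hidden)), requires_grad=True)
        self.bih = Tensor(np.zeros(3 * hidden), requires_grad=True)
        self.bhh = Tensor(np.zeros(3 * hidden), requires_grad=True)


# ----------------------------------------------------------------- optimiser


class RAdam:
    """Rectified Adam (variance-rectified adaptive learning rate)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2, t = self.b1, self.b2, self.t
        rho_inf = 2.0 / (1.0 - b2) - 1.0
        rho_t = rho_inf - 2.0 * t * b2 ** t / (1.0 - b2 ** t)
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** t)
            if rho_t > 4.0:
                v_hat = np.sqrt(self.v[i] / (1 - b2 ** t))
                r = np.sqrt(((rho_t - 4) * (rho_t - 2) * rho_inf)
                            / ((rho_inf - 4) * (rho_inf - 2) * rho_t))
                p.data -= self.lr * r * m_hat / (v_hat + self.eps)
            else:
                p.data -= self.lr * m_hat
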