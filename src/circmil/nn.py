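"""Neural-network building blocks: linear / embedding layers, stacked
bidirectional LSTMs, and the Adam optimizer.

All parameters are :class:`~circmil._tensor.Tensor` leaves; initialization
follows the usual uniform(-1/sqrt(fan), 1/sqrt(fan)) convention with an
explicit ``numpy.random.Generator`` so every model build is reproducible.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, concat, lstm_cell_c, lstm_cell_h, stack

__all__ = ["Module", "Linear", "Embedding", "LSTM", "BiLSTMStack", "Adam"]


class Module:
    """Base class: tracks named parameters of itself and sub-modules."""

    def named_parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out[name] = val
            elif isinstance(val, Module):
                for sub, p in val.named_parameters().items():
                    out[f"{name}.{sub}"] = p
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, p in item.named_parameters().items():
                            out[f"{name}.{i}.{sub}"] = p
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in checkpoint: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr


def _uniform(rng: np.random.Generator, shape, scale: float, dtype) -> Tensor:
    return Tensor(rng.uniform(-scale, scale, size=shape).astype(dtype), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = 1.0 / np.sqrt(d_in)
        self.W = _uniform(rng, (d_in, d_out), scale, dtype)
        self.b = _uniform(rng, (d_out,), scale, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Embedding(Module):
    def __init__(self, n_symbols: int, dim: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.W = Tensor(rng.standard_normal((n_symbols, dim)).astype(dtype),
                        requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        from ._tensor import embedding_lookup
        return embedding_lookup(self.W, idx)


class LSTM(Module):
    """One direction of one LSTM layer, run over a full (N, T, D) batch."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator,
                 reverse: bool = False, dtype=np.float32):
        scale = 1.0 / np.sqrt(hidden)
        self.Wx = _uniform(rng, (d_in, 4 * hidden), scale, dtype)
        self.Wh = _uniform(rng, (hidden, 4 * hidden), scale, dtype)
        self.b = _uniform(rng, (4 * hidden,), scale, dtype)
        # forget-gate bias starts at 1 so early training does not flush
        # the cell state (standard LSTM practice)
        self.b.data[hidden:2 * hidden] += 1.0
        self.hidden = hidden
        self.reverse = reverse
        self._dtype = dtype

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (per-step hidden states (N, T, H), final state (N, H)).

        For the reverse direction the "final" state is the one produced
        after reading position 0, and per-step states are re-ordered to
        align with sequence positions.
        """
        N, T, D = x.shape
        H = self.hidden
        # input projection for all timesteps at once
        zx = (x.reshape(N * T, D) @ self.Wx + self.b).reshape(N, T, 4 * H)
        h = Tensor(np.zeros((N, H), dtype=self._dtype))
        c = Tensor(np.zeros((N, H), dtype=self._dtype))
        order = range(T - 1, -1, -1) if self.reverse else range(T)
        hs: list[Tensor] = []
        for t in order:
            z = zx[:, t, :] + h @ self.Wh
            c = lstm_cell_c(z, c, H)
            h = lstm_cell_h(z, c, H)
            hs.append(h)
        if self.reverse:
            hs.reverse()
        return stack(hs, axis=1), h


class BiLSTMStack(Module):
    """Stacked bidirectional LSTM; per-step outputs of both directions are
    concatenated and fed to the next layer.  Returns the concatenated
    final states (forward last step, backward first step) of the top layer.
    """

    def __init__(self, d_in: int, hidden: int, n_layers: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.layers: list[LSTM] = []
        d = d_in
        for _ in range(n_layers):
            self.layers.append(LSTM(d, hidden, rng, reverse=False, dtype=dtype))
            self.layers.append(LSTM(d, hidden, rng, reverse=True, dtype=dtype))
            d = 2 * hidden
        self.hidden = hidden
        self.n_layers = n_layers

    def __call__(self, x: Tensor, return_sequence: bool = False) -> Tensor:
        h_final = None
        for li in range(self.n_layers):
            fwd, bwd = self.layers[2 * li], self.layers[2 * li + 1]
            hs_f, hf = fwd(x)
            hs_b, hb = bwd(x)
            x = concat([hs_f, hs_b], axis=2)
            h_final = concat([hf, hb], axis=1)
        return x if return_sequence else h_final


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-5):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.data = (p.data - self.lr * update).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
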