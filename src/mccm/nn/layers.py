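"""Network building blocks on top of the autodiff engine.

All layers operate on (B, T, C) batches of padded sequences; weights use a
uniform fan-in initialisation drawn from a caller-supplied seeded generator
so whole models are reproducible.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, pad_time, stack


class Module:
    """Base: recursively collects parameters, toggles train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(a, dtype=float)


def _init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, rng, in_dim: int, out_dim: int):
        super().__init__()
        self.W = _init(rng, (in_dim, out_dim), in_dim)
        self.b = _init(rng, (out_dim,), in_dim)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Dropout(Module):
    """Inverted dropout; identity in eval mode.  Mask noise comes from the
    shared generator so training runs are reproducible end to end."""

    def __init__(self, rng: np.random.Generator, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0,1)")
        self.p = p
        self._rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self._rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class Conv1dSame(Module):
    """Same-length 1-D convolution with ReLU, centred zero padding.

    Realised as an unfold (concatenation of time-shifted slices) followed by
    one affine map, which keeps the whole op inside the autodiff graph.
    """

    def __init__(self, rng, in_dim: int, out_dim: int, kernel: int):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {kernel}")
        self.kernel = kernel
        self.W = _init(rng, (kernel * in_dim, out_dim), kernel * in_dim)
        self.b = _init(rng, (out_dim,), kernel * in_dim)

    def __call__(self, x: Tensor) -> Tensor:
        T = x.data.shape[1]
        half = self.kernel // 2
        xp = pad_time(x, half, half)
        windows = concat([xp[:, i:i + T, :] for i in range(self.kernel)], axis=2)
        return (windows @ self.W + self.b).relu()


class GRU(Module):
    """Single-direction gated recurrent unit over (B, T, C).

    Gate algebra: r_t = sigm(Wcr c_t + Whr h_{t-1} + br),
    u_t = sigm(Wcu c_t + Whu h_{t-1} + bu),
    h~_t = tanh(Wch c_t + Whh (r_t * h_{t-1} + bh)),
    h_t = u_t * h_{t-1} + (1 - u_t) * h~_t.
    """

    def __init__(self, rng, in_dim: int, hidden: int):
        super().__init__()
        self.hidden = hidden
        self.Wcr = _init(rng, (in_dim, hidden), in_dim)
        self.Whr = _init(rng, (hidden, hidden), hidden)
        self.br = _init(rng, (hidden,), in_dim)
        self.Wcu = _init(rng, (in_dim, hidden), in_dim)
        self.Whu = _init(rng, (hidden, hidden), hidden)
        self.bu = _init(rng, (hidden,), in_dim)
        self.Wch = _init(rng, (in_dim, hidden), in_dim)
        self.Whh = _init(rng, (hidden, hidden), hidden)
        self.bh = _init(rng, (hidden,), in_dim)

    def step(self, c_t: Tensor, h_prev: Tensor) -> Tensor:
        r = (c_t @ self.Wcr + h_prev @ self.Whr + self.br).sigmoid()
        u = (c_t @ self.Wcu + h_prev @ self.Whu + self.bu).sigmoid()
        h_tilde = (c_t @ self.Wch + (r * h_prev + self.bh) @ self.Whh).tanh()
        return u * h_prev + (1.0 - u) * h_tilde

    def __call__(self, x: Tensor, reverse: bool = False) -> Tensor:
        B, T, _ = x.data.shape
        h = Tensor(np.zeros((B, self.hidden)))
        order = range(T - 1, -1, -1) if reverse else range(T)
        outputs: list[Tensor] = [None] * T
        for t in order:
            h = self.step(x[:, t, :], h)
            outputs[t] = h
        return stack(outputs, axis=1)


class BiGRU(Module):
    """Bidirectional wrapper: forward and backward passes concatenated."""

    def __init__(self, rng, in_dim: int, hidden: int):
        super().__init__()
        self.fwd = GRU(rng, in_dim, hidden)
        self.bwd = GRU(rng, in_dim, hidden)

    def __call__(self, x: Tensor) -> Tensor:
        return concat([self.fwd(x), self.bwd(x, reverse=True)], axis=2)


class SequenceAttention(Module):
    """Additive attention pooling a (B, T, H) sequence into (B, H).

    Scores a~_t = s_a . tanh(Wa h_t + ba) are softmax-normalised over
    masked-true positions only; padding receives zero weight.
    """

    def __init__(self, rng, in_dim: int, hidden: int):
        super().__init__()
        self.Wa = _init(rng, (in_dim, hidden), in_dim)
        self.ba = _init(rng, (hidden,), in_dim)
        self.sa = _init(rng, (hidden, 1), hidden)

    def __call__(self, h: Tensor, mask: np.ndarray):
        """Returns (alpha (B,T) Tensor, pooled (B,H) Tensor)."""
        mask = np.asarray(mask, dtype=bool)
        if not mask.any(axis=1).all():
            raise ValueError("attention requires at least one real position per sequence")
        scores = ((h @ self.Wa + self.ba).tanh() @ self.sa).reshape(h.data.shape[:2])
        neg = np.where(mask, 0.0, -1e30)
        logp = (scores + Tensor(neg)).log_softmax(axis=1)
        alpha = logp.exp() * Tensor(mask.astype(float))
        pooled = (alpha.reshape(*alpha.data.shape, 1) * h).sum(axis=1)
        return alpha, pooled


class MLP(Module):
    """ReLU multilayer perceptron with dropout on hidden activations."""

    def __init__(self, rng, in_dim: int, hidden: list[int], out_dim: int, dropout: Dropout | None = None):
        super().__init__()
        dims = [in_dim] + list(hidden)
        self.layers = [Linear(rng, dims[i], dims[i + 1]) for i in range(len(hidden))]
        self.out = Linear(rng, dims[-1], out_dim)
        self.dropout = dropout

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x).relu()
            if self.dropout is not None:
                x = self.dropout(x)
        return self.out(x)
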