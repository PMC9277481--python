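"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is a small tape-based engine: each :class:`Tensor` records the
operation that produced it and a closure that propagates the upstream
gradient to its parents.  It supports exactly the operations the
shifted-window transformer and its training loop need (broadcast add/mul,
stacked matmul, reshape/transpose/roll/gather, softmax, layer norm, GELU,
reductions, MAE and cross-entropy losses) plus an AdamW optimizer with a
cosine-decay schedule.  Everything is float64 numpy under the hood and
fully deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "AdamW",
    "cosine_lr",
    "concat",
    "mae_loss",
    "cross_entropy_loss",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad or p._parents:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- construction helpers ---------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _track(self, *parents: "Tensor") -> bool:
        return any(p.requires_grad or p._parents for p in parents)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd if self._track(self, other) else None
        if out._backward is None:
            out._parents = ()
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = (lambda g: self._accumulate(-g)) if self._track(self) else None
        if out._backward is None:
            out._parents = ()
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd if self._track(self, other) else None
        if out._backward is None:
            out._parents = ()
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            self._accumulate(_unbroadcast(ga, self.data.shape))
            other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = bwd if self._track(self, other) else None
        if out._backward is None:
            out._parents = ()
        return out

    __matmul__ = matmul

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = (
            (lambda g: self._accumulate(g.reshape(src))) if self._track(self) else None
        )
        if out._backward is None:
            out._parents = ()
        return out

    def transpose(self, axes) -> "Tensor":
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = (
            (lambda g: self._accumulate(g.transpose(inv))) if self._track(self) else None
        )
        if out._backward is None:
            out._parents = ()
        return out

    def roll(self, shift: int, axis: int) -> "Tensor":
        out = Tensor(np.roll(self.data, shift, axis=axis), parents=(self,))
        out._backward = (
            (lambda g: self._accumulate(np.roll(g, -shift, axis=axis)))
            if self._track(self)
            else None
        )
        if out._backward is None:
            out._parents = ()
        return out

    def take(self, indices: np.ndarray, axis: int = 0) -> "Tensor":
        """Gather along ``axis`` with an integer index array (scatter-add grad)."""
        idx = np.asarray(indices)
        out = Tensor(np.take(self.data, idx, axis=axis), parents=(self,))

        def bwd(g):
            acc = np.zeros_like(self.data)
            moved = np.moveaxis(acc, axis, 0)  # view: writes land in acc
            g_moved = np.moveaxis(
                g, tuple(range(axis, axis + idx.ndim)), tuple(range(idx.ndim))
            )
            np.add.at(moved, idx, g_moved)
            self._accumulate(acc)

        out._backward = bwd if self._track(self) else None
        if out._backward is None:
            out._parents = ()
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bwd if self._track(self) else None
        if out._backward is None:
            out._parents = ()
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ----------------------------------------------------
    def gelu(self) -> "Tensor":
        # tanh approximation; derivative is its analytic form
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out = Tensor(0.5 * x * (1.0 + t), parents=(self,))

        def bwd(g):
            dinner = c * (1.0 + 3 * 0.044715 * x**2)
            dt = (1.0 - t**2) * dinner
            self._accumulate(g * (0.5 * (1.0 + t) + 0.5 * x * dt))

        out._backward = bwd if self._track(self) else None
        if out._backward is None:
            out._parents = ()
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, parents=(self,))

        def bwd(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accumulate(s * (g - dot))

        out._backward = bwd if self._track(self) else None
        if out._backward is None:
            out._parents = ()
        return out

    def layer_norm(self, weight: "Tensor", bias: "Tensor", eps: float = 1e-5) -> "Tensor":
        """Normalize over the last axis and apply an affine transform."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        out = Tensor(xhat * weight.data + bias.data, parents=(self, weight, bias))

        def bwd(g):
            n = x.shape[-1]
            gw = g * weight.data
            gx = (
                inv
                / n
                * (n * gw - gw.sum(axis=-1, keepdims=True) - xhat * (gw * xhat).sum(axis=-1, keepdims=True))
            )
            self._accumulate(gx)
            weight._accumulate(_unbroadcast(g * xhat, weight.data.shape))
            bias._accumulate(_unbroadcast(g, bias.data.shape))

        out._backward = bwd if self._track(self, weight, bias) else None
        if out._backward is None:
            out._parents = ()
        return out

    def abs(self) -> "Tensor":
        out = Tensor(np.abs(self.data), parents=(self,))
        sign = np.sign(self.data)
        out._backward = (lambda g: self._accumulate(g * sign)) if self._track(self) else None
        if out._backward is None:
            out._parents = ()
        return out

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out._backward = bwd if any(t.requires_grad or t._parents for t in tensors) else None
    if out._backward is None:
        out._parents = ()
    return out


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module system: submodules and parameters discovered by attribute."""

    def parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                out[key] = val
            elif isinstance(val, Module):
                out.update(val.parameters(prefix=f"{key}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.update(item.parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        out[f"{key}.{i}"] = item
        return out

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        params = self.parameters()
        for key, value in state.items():
            full = prefix + key
            if full not in params:
                raise KeyError(f"unknown parameter {full!r}")
            if params[full].data.shape != value.shape:
                raise ValueError(
                    f"shape mismatch for {full!r}: "
                    f"{params[full].data.shape} vs {value.shape}"
                )
            params[full].data = np.asarray(value, dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.weight, self.bias, eps=self.eps)


def mae_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    return (pred - Tensor(target)).abs().mean()


def cross_entropy_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over all leading axes; classes on the last axis."""
    z = logits.data
    zmax = z.max(axis=-1, keepdims=True)
    lse = zmax + np.log(np.exp(z - zmax).sum(axis=-1, keepdims=True))
    labels = np.asarray(labels, dtype=np.int64)
    onehot = np.zeros_like(z)
    np.put_along_axis(onehot, labels[..., None], 1.0, axis=-1)
    n = labels.size
    out = Tensor((lse[..., 0] - np.take_along_axis(z, labels[..., None], axis=-1)[..., 0]).mean(),
                 parents=(logits,))

    def bwd(g):
        softmax = np.exp(z - lse)
        logits._accumulate(g * (softmax - onehot) / n)

    out._backward = bwd if (logits.requires_grad or logits._parents) else None
    if out._backward is None:
        out._parents = ()
    return out


def cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    """Cosine decay from ``base_lr`` at epoch 0 toward 0 at the final epoch."""
    if total_epochs <= 1:
        return base_lr
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * epoch / (total_epochs - 1)))


class AdamW:
    """AdamW with decoupled weight decay."""

    def __init__(self, params: dict[str, Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        for key, p in self.params.items():
            if p.grad is None:
                continue
            m = self._m[key] = b1 * self._m[key] + (1 - b1) * p.grad
            v = self._v[key] = b2 * self._v[key] + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self._t)
            vhat = v / (1 - b2**self._t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
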