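"""Minimal reverse-mode automatic differentiation on numpy arrays.

The explanation-supervision objective needs *second-order* derivatives: the
saliency maps entering the loss are themselves gradients of the class score,
and the loss is then differentiated w.r.t. the network weights.  Every
vector-Jacobian product below is therefore expressed in terms of engine ops,
so the output of :func:`grad` is again a differentiable :class:`Tensor` and
``grad(grad(...))`` is well-defined (the ReLU derivative mask is treated as
locally constant, the usual convention for piecewise-linear activations).

Only the small set of dense operations a graph convolutional pipeline needs
is implemented: broadcasting arithmetic, (batched) matmul, reductions,
elementwise nonlinearities, stacking and basic indexing.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "grad", "stack", "maximum", "minimum", "where", "Adam"]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = parents  # tuple of (Tensor, vjp) pairs
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p, _ in parents)

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = tensor(other)
        return Tensor(
            self.data + other.data,
            parents=(
                (self, lambda g: _unbroadcast(g, self.shape)),
                (other, lambda g: _unbroadcast(g, other.shape)),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=((self, lambda g: -g),))

    def __sub__(self, other):
        return self + (-tensor(other))

    def __rsub__(self, other):
        return tensor(other) + (-self)

    def __mul__(self, other):
        other = tensor(other)
        return Tensor(
            self.data * other.data,
            parents=(
                (self, lambda g: _unbroadcast(g * other, self.shape)),
                (other, lambda g: _unbroadcast(g * self, other.shape)),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return tensor(other) * self**-1.0

    def __pow__(self, p: float):
        p = float(p)
        return Tensor(
            self.data**p,
            parents=((self, lambda g: g * (p * self ** (p - 1.0))),),
        )

    def __matmul__(self, other):
        other = tensor(other)
        out = self.data @ other.data
        a, b = self, other

        def vjp_a(g):
            r = g @ _swap(b)
            return _unbroadcast(r, a.shape)

        def vjp_b(g):
            r = _swap(a) @ g
            return _unbroadcast(r, b.shape)

        return Tensor(out, parents=((a, vjp_a), (b, vjp_b)))

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor(
            self.data.reshape(shape),
            parents=((self, lambda g: g.reshape(old)),),
        )

    def transpose(self, axes=None):
        ax = tuple(axes) if axes is not None else tuple(range(self.ndim))[::-1]
        inv = tuple(np.argsort(ax))
        return Tensor(
            self.data.transpose(ax),
            parents=((self, lambda g: g.transpose(inv)),),
        )

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        shape = self.shape
        return Tensor(
            self.data[idx],
            parents=((self, lambda g: _scatter(g, idx, shape)),),
        )

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        shape = self.shape
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            gd = g
            if axis is not None and not keepdims:
                gd = g.reshape(_keep_shape(shape, axis))
            return gd * Tensor(np.ones(shape))

        return Tensor(out, parents=((self, vjp),))

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod([self.shape[a] for a in _axtuple(axis, self.ndim)])
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis=None, keepdims=False):
        return _minmax_reduce(self, axis, keepdims, np.max, np.argmax)

    def min(self, axis=None, keepdims=False):
        return _minmax_reduce(self, axis, keepdims, np.min, np.argmin)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = Tensor((self.data > 0).astype(np.float64))
        return Tensor(self.data * mask.data, parents=((self, lambda g: g * mask),))

    def guided_relu(self):
        """ReLU whose backward pass also rectifies the incoming gradient.

        Forward identical to :meth:`relu`; the modified VJP implements the
        guided-backpropagation rule (negative upstream gradients are zeroed at
        every rectifier).
        """
        mask = Tensor((self.data > 0).astype(np.float64))
        return Tensor(self.data * mask.data, parents=((self, lambda g: g.relu() * mask),))

    def exp(self):
        res = Tensor(np.exp(self.data))
        # backward references the output node itself so d(exp)' = exp chains
        # correctly under repeated differentiation
        res.parents = ((self, lambda g: g * res),)
        res.requires_grad = self.requires_grad
        return res

    def log(self):
        return Tensor(np.log(self.data), parents=((self, lambda g: g / self),))

    def sqrt(self):
        return self**0.5

    def abs(self):
        sign = Tensor(np.sign(self.data))
        return Tensor(np.abs(self.data), parents=((self, lambda g: g * sign),))

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


# -- free functions ----------------------------------------------------------


def tensor(x, requires_grad=False) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(x, requires_grad=requires_grad)


def stack(tensors, axis=0) -> Tensor:
    tensors = [tensor(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)
    parents = []
    for i, t in enumerate(tensors):
        idx = tuple(slice(None) for _ in range(axis)) + (i,)
        parents.append((t, (lambda ix: lambda g: g[ix])(idx)))
    return Tensor(out, parents=tuple(parents))


def maximum(a, b) -> Tensor:
    """Elementwise max; on ties the subgradient goes to the first argument."""
    a, b = tensor(a), tensor(b)
    mask = Tensor((a.data >= b.data).astype(np.float64))
    inv = Tensor(1.0 - mask.data)
    return Tensor(
        np.maximum(a.data, b.data),
        parents=(
            (a, lambda g: _unbroadcast(g * mask, a.shape)),
            (b, lambda g: _unbroadcast(g * inv, b.shape)),
        ),
    )


def minimum(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    mask = Tensor((a.data <= b.data).astype(np.float64))
    inv = Tensor(1.0 - mask.data)
    return Tensor(
        np.minimum(a.data, b.data),
        parents=(
            (a, lambda g: _unbroadcast(g * mask, a.shape)),
            (b, lambda g: _unbroadcast(g * inv, b.shape)),
        ),
    )


def where(cond: np.ndarray, a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    m = Tensor(cond.astype(np.float64))
    return a * m + b * (1.0 - m.data)


def grad(output: Tensor, wrt, create_graph: bool = False):
    """Adjoints of a scalar ``output`` w.r.t. each tensor in ``wrt``.

    With ``create_graph=True`` the returned tensors stay connected to the
    graph, so they can be differentiated again.
    """
    if output.data.size != 1:
        raise ValueError("grad expects a scalar output")
    wrt = list(wrt)

    order: list[Tensor] = []
    seen: set[int] = set()
    # iterative DFS post-order (graphs can be deep at many epochs)
    stack_ = [(output, False)]
    while stack_:
        node, processed = stack_.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack_.append((node, True))
        for p, _ in node.parents:
            if id(p) not in seen and p.requires_grad:
                stack_.append((p, False))

    adjoint: dict[int, Tensor] = {id(output): Tensor(np.ones_like(output.data))}
    for node in reversed(order):
        g = adjoint.get(id(node))
        if g is None:
            continue
        for p, vjp in node.parents:
            if not p.requires_grad:
                continue
            contrib = vjp(g)
            prev = adjoint.get(id(p))
            adjoint[id(p)] = contrib if prev is None else prev + contrib

    out = []
    for w in wrt:
        g = adjoint.get(id(w))
        if g is None:
            g = Tensor(np.zeros_like(w.data))
        if not create_graph:
            g = g.detach()
        out.append(g)
    return out


# -- internals ---------------------------------------------------------------


def _axtuple(axis, ndim):
    if axis is None:
        return tuple(range(ndim))
    if isinstance(axis, int):
        return (axis % ndim,)
    return tuple(a % ndim for a in axis)


def _keep_shape(shape, axis):
    ax = _axtuple(axis, len(shape))
    return tuple(1 if i in ax else s for i, s in enumerate(shape))


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce a broadcast gradient back to ``shape``."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _swap(t: Tensor) -> Tensor:
    """Transpose the last two axes (matmul adjoint helper)."""
    if t.ndim < 2:
        return t
    ax = tuple(range(t.ndim - 2)) + (t.ndim - 1, t.ndim - 2)
    return t.transpose(ax)


def _scatter(g: Tensor, idx, shape) -> Tensor:
    data = np.zeros(shape)
    np.add.at(data, idx, g.data)
    out = Tensor(data, parents=((g, lambda gg: gg[idx]),))
    return out


def _minmax_reduce(t: Tensor, axis, keepdims, npfun, argfun):
    out = npfun(t.data, axis=axis, keepdims=keepdims)
    if axis is None:
        flat_i = argfun(t.data)
        mask = np.zeros(t.data.size)
        mask[flat_i] = 1.0  # first extremum wins on ties
        mask = mask.reshape(t.shape)
    else:
        ax = axis % t.ndim
        idx = argfun(t.data, axis=ax)
        mask = np.zeros(t.shape)
        np.put_along_axis(mask, np.expand_dims(idx, ax), 1.0, axis=ax)
    maskT = Tensor(mask)
    shape = t.shape

    def vjp(g):
        gd = g
        if axis is not None and not keepdims:
            gd = g.reshape(_keep_shape(shape, axis))
        elif axis is None:
            gd = g.reshape((1,) * len(shape))
        return gd * maskT

    return Tensor(out, parents=((t, vjp),))


class Adam:
    """Adam optimizer over a list of leaf tensors (updates ``.data`` in place)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(self.params, grads)):
            g = g.data if isinstance(g, Tensor) else np.asarray(g)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
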