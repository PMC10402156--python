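"""Minimal reverse-mode autodiff on numpy arrays, with the layers the
V-stripe model needs: 1D/2D convolution ('same' padding), batch norm,
average pooling, linear layers and SGD with momentum + weight decay.

Tensors default to float32 on CPU (switchable via set_default_dtype);
gradients are verified against finite differences in the test suite. Gradients are accumulated lazily (a tensor's
``grad`` stays None until something flows into it) to avoid allocating
zeros for every intermediate.
"""

from __future__ import annotations

import numpy as np

#: dtype for all tensors/parameters; float32 is ~2x faster, float64 is used
#: by the finite-difference gradient checks.
DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global DTYPE
    DTYPE = np.dtype(dtype)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _acc(t: "Tensor", g: np.ndarray, own: bool = False) -> None:
    """Accumulate gradient ``g`` into ``t``; ``own`` marks ``g`` as a fresh
    array that may be adopted without copying."""
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g if own else np.array(g)
    else:
        t.grad += g


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(),
                 backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph -----------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bw(g):
            _acc(self, _unbroadcast(g, self.data.shape))
            _acc(other, _unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                _acc(self, _unbroadcast(g * other.data, self.data.shape),
                     own=True)
            if other.requires_grad:
                _acc(other, _unbroadcast(g * self.data, other.data.shape),
                     own=True)

        return Tensor(self.data * other.data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        return self * as_tensor(other).pow(-1.0)

    def pow(self, exponent: float):
        def bw(g):
            _acc(self, g * exponent * np.power(self.data, exponent - 1),
                 own=True)

        return Tensor(np.power(self.data, exponent), parents=(self,), backward=bw)

    def sqrt(self):
        return self.pow(0.5)

    def matmul(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                _acc(self, g @ np.swapaxes(other.data, -1, -2), own=True)
            if other.requires_grad:
                _acc(other, _unbroadcast(
                    np.swapaxes(self.data, -1, -2) @ g, other.data.shape),
                    own=True)

        return Tensor(self.data @ other.data, parents=(self, other), backward=bw)

    __matmul__ = matmul

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def bw(g):
            _acc(self, g.reshape(old))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bw)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bw(g):
            _acc(self, g.transpose(*inv))

        return Tensor(self.data.transpose(*axes), parents=(self,), backward=bw)

    def __getitem__(self, idx):
        def bw(g):
            if not self.requires_grad:
                return
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            np.add.at(self.grad, idx, g)

        return Tensor(self.data[idx], parents=(self,), backward=bw)

    def flip(self, axis: int):
        def bw(g):
            _acc(self, np.flip(g, axis=axis))

        return Tensor(np.flip(self.data, axis=axis), parents=(self,), backward=bw)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if not self.requires_grad:
                return
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            _acc(self, np.broadcast_to(gg, self.data.shape))

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            denom = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            denom = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / denom)

    def relu(self):
        pos = self.data > 0

        def bw(g):
            _acc(self, g * pos, own=True)

        return Tensor(self.data * pos, parents=(self,), backward=bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                _acc(t, g[tuple(sl)])

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=bw)


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """'same' 1D convolution. x: (N,Cin,L), w: (Cout,Cin,K) with K odd."""
    N, Cin, L = x.data.shape
    Cout, Cin2, K = w.data.shape
    assert Cin == Cin2 and K % 2 == 1
    pad = K // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    y = np.zeros((N, Cout, L), dtype=x.data.dtype)
    for k in range(K):
        y += np.einsum("ncl,oc->nol", xp[:, :, k:k + L], w.data[:, :, k])
    if b is not None:
        y += b.data[None, :, None]

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        if b is not None and b.requires_grad:
            _acc(b, g.sum(axis=(0, 2)), own=True)
        gw = np.zeros_like(w.data) if w.requires_grad else None
        gxp = np.zeros_like(xp) if x.requires_grad else None
        for k in range(K):
            if gw is not None:
                gw[:, :, k] = np.einsum("nol,ncl->oc", g, xp[:, :, k:k + L])
            if gxp is not None:
                gxp[:, :, k:k + L] += np.einsum("nol,oc->ncl", g,
                                                w.data[:, :, k])
        if gw is not None:
            _acc(w, gw, own=True)
        if gxp is not None:
            gx = gxp[:, :, pad:pad + L] if pad else gxp
            _acc(x, gx, own=(pad == 0))

    return Tensor(y, parents=parents, backward=bw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """'same' 2D convolution. x: (N,Cin,H,W), w: (Cout,Cin,K,K), K odd."""
    N, Cin, H, W = x.data.shape
    Cout, Cin2, K, K2 = w.data.shape
    assert Cin == Cin2 and K == K2 and K % 2 == 1
    pad = K // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    y = np.zeros((N, Cout, H, W), dtype=x.data.dtype)
    for ki in range(K):
        for kj in range(K):
            y += np.einsum("nchw,oc->nohw",
                           xp[:, :, ki:ki + H, kj:kj + W], w.data[:, :, ki, kj])
    if b is not None:
        y += b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        if b is not None and b.requires_grad:
            _acc(b, g.sum(axis=(0, 2, 3)), own=True)
        gw = np.zeros_like(w.data) if w.requires_grad else None
        gxp = np.zeros_like(xp) if x.requires_grad else None
        for ki in range(K):
            for kj in range(K):
                patch = xp[:, :, ki:ki + H, kj:kj + W]
                if gw is not None:
                    gw[:, :, ki, kj] = np.einsum("nohw,nchw->oc", g, patch)
                if gxp is not None:
                    gxp[:, :, ki:ki + H, kj:kj + W] += np.einsum(
                        "nohw,oc->nchw", g, w.data[:, :, ki, kj])
        if gw is not None:
            _acc(w, gw, own=True)
        if gxp is not None:
            _acc(x, gxp[:, :, pad:pad + H, pad:pad + W], own=False)

    return Tensor(y, parents=parents, backward=bw)


def batchnorm1d(x: Tensor, gamma: Tensor, beta: Tensor,
                eps: float) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused training-mode batch norm over (N, C, L) with per-channel stats.

    Returns (output, batch_mean, batch_var) — the stats feed the running
    buffers. The closed-form backward keeps this from dominating runtime.
    """
    mu = x.data.mean(axis=(0, 2), keepdims=True)
    var = x.data.var(axis=(0, 2), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    y = gamma.data[None, :, None] * xhat + beta.data[None, :, None]

    def bw(g):
        if gamma.requires_grad:
            _acc(gamma, (g * xhat).sum(axis=(0, 2)), own=True)
        if beta.requires_grad:
            _acc(beta, g.sum(axis=(0, 2)), own=True)
        if x.requires_grad:
            gmean = g.mean(axis=(0, 2), keepdims=True)
            gx_mean = (g * xhat).mean(axis=(0, 2), keepdims=True)
            dx = (gamma.data[None, :, None] * inv) * (
                g - gmean - xhat * gx_mean)
            _acc(x, dx, own=True)

    out = Tensor(y, parents=(x, gamma, beta), backward=bw)
    return out, mu.ravel(), var.ravel()


def channel_affine(x: Tensor, scale: np.ndarray, shift: np.ndarray,
                   gamma: Tensor, beta: Tensor) -> Tensor:
    """Eval-mode batch norm: y = x*scale + shift with constant per-channel
    scale/shift derived from running stats; gradients flow to x, gamma, beta
    via the chain rule through scale = gamma*inv, shift = beta - rm*scale."""
    y = x.data * scale[None, :, None] + shift[None, :, None]

    def bw(g):
        if x.requires_grad:
            _acc(x, g * scale[None, :, None], own=True)
        # scale = gamma*inv and shift = beta - rm*gamma*inv: fold rm into
        # the gamma gradient via xhat = (x - rm)*inv = (y - beta)/gamma
        if gamma.requires_grad:
            xhat = (y - shift[None, :, None]) / np.where(
                gamma.data[None, :, None] == 0, 1.0,
                gamma.data[None, :, None])
            _acc(gamma, (g * xhat).sum(axis=(0, 2)), own=True)
        if beta.requires_grad:
            _acc(beta, g.sum(axis=(0, 2)), own=True)

    return Tensor(y, parents=(x, gamma, beta), backward=bw)


def avg_pool1d(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping average pooling along the last axis."""
    N, C, L = x.data.shape
    if L % factor:
        raise ValueError(f"length {L} not divisible by pool factor {factor}")
    y = x.data.reshape(N, C, L // factor, factor).mean(axis=-1)

    def bw(g):
        _acc(x, np.repeat(g / factor, factor, axis=-1), own=True)

    return Tensor(y, parents=(x,), backward=bw)


def outer_concat(f: Tensor) -> Tensor:
    """(N, L, C) -> (N, L, L, 2C) with out[n,i,j] = concat(f[n,i], f[n,j])."""
    N, L, C = f.data.shape
    a = np.broadcast_to(f.data[:, :, None, :], (N, L, L, C))
    b = np.broadcast_to(f.data[:, None, :, :], (N, L, L, C))
    y = np.concatenate([a, b], axis=-1)

    def bw(g):
        _acc(f, g[..., :C].sum(axis=2) + g[..., C:].sum(axis=1), own=True)

    return Tensor(y, parents=(f,), backward=bw)


# --------------------------------------------------------------------------
# modules
# --------------------------------------------------------------------------


class Module:
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

    def buffers(self) -> list[np.ndarray]:
        """Non-parameter state (batch-norm running stats)."""
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v.buffers())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.buffers())
        if isinstance(self, BatchNorm1d):
            out.extend([self.running_mean, self.running_var])
        return out

    def _submodules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def train(self) -> None:
        self.training = True
        for m in self._submodules():
            m.train()

    def eval(self) -> None:
        self.training = False
        for m in self._submodules():
            m.eval()

    def state_arrays(self) -> list[np.ndarray]:
        """Parameters then buffers, in deterministic traversal order."""
        return [p.data for p in self.parameters()] + self.buffers()

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state) -> None:
        arrays = self.state_arrays()
        if len(arrays) != len(state):
            raise ValueError("state length mismatch")
        for a, s in zip(arrays, state):
            a[...] = s


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Conv1d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.w = Tensor(_kaiming(rng, (cout, cin, k), cin * k),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.w = Tensor(_kaiming(rng, (cout, cin, k, k), cin * k * k),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b)


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator):
        super().__init__()
        self.w = Tensor(_kaiming(rng, (fin, fout), fin), requires_grad=True)
        self.b = Tensor(np.zeros(fout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.w) + self.b


class BatchNorm1d(Module):
    """Batch normalization over (N, C, L): statistics per channel."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.eps = eps
        self.momentum = momentum

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = batchnorm1d(x, self.gamma, self.beta, self.eps)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            return out
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = self.gamma.data * inv
        shift = self.beta.data - self.running_mean * scale
        return channel_affine(x, scale, shift, self.gamma, self.beta)


class SGD:
    """SGD with classical momentum and L2 weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0, max_grad_norm: float | None = None):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.max_grad_norm = max_grad_norm
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        if self.max_grad_norm is not None:
            sq = sum(float((p.grad ** 2).sum()) for p in self.params
                     if p.grad is not None)
            norm = np.sqrt(sq)
            if norm > self.max_grad_norm:
                scale = self.max_grad_norm / norm
                for p in self.params:
                    if p.grad is not None:
                        p.grad *= scale
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
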