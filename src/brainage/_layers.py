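"""Numpy neural-network primitives with manual backpropagation.

Everything the 3D attention-ResNet needs, implemented directly on numpy
arrays: stride-1 "same" 3D convolution (im2col), batch normalisation, ELU,
2x2x2 max-pooling, dot-product attention over flattened spatial positions,
dense layers and inverted dropout, plus an Adam optimiser.  Tensors are
channels-last: ``(batch, x, y, z, channels)``.

Each layer caches what its backward pass needs during ``forward(train=True)``
and returns the gradient with respect to its input from ``backward``.
Gradient correctness is pinned down by central-difference checks in the
test suite, so the layers here can stay lean.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


# ---------------------------------------------------------------------------
# convolution


def _conv3d_same(x: np.ndarray, w: np.ndarray, return_patches: bool = False):
    """Stride-1 zero-padded 'same' 3D convolution, odd kernels only.

    x: (B, D, H, W, Cin); w: (kd, kh, kw, Cin, Cout) -> (B, D, H, W, Cout).
    """
    kd, kh, kw, cin, cout = w.shape
    pd, ph, pw = kd // 2, kh // 2, kw // 2
    if kd == kh == kw == 1:
        out = x @ w.reshape(cin, cout)
        return (out, x) if return_patches else out
    xp = np.pad(x, ((0, 0), (pd, pd), (ph, ph), (pw, pw), (0, 0)))
    win = sliding_window_view(xp, (kd, kh, kw), axis=(1, 2, 3))
    # win: (B, D, H, W, Cin, kd, kh, kw) -> patches (B, D, H, W, kd*kh*kw*Cin)
    b, d, h, wd = x.shape[:4]
    patches = np.ascontiguousarray(win.transpose(0, 1, 2, 3, 5, 6, 7, 4)).reshape(
        b, d, h, wd, kd * kh * kw * cin
    )
    out = patches @ w.reshape(-1, cout)
    return (out, patches) if return_patches else out


class Conv3D(Layer):
    """3D convolution, stride 1, zero 'same' padding, odd kernel."""

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        if kernel % 2 == 0:
            raise ValueError("only odd kernel sizes are supported")
        fan_in = kernel ** 3 * cin
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel, kernel, kernel, cin, cout))
        self.w = Param(w.astype(dtype), "conv_w")
        self.b = Param(np.zeros(cout, dtype=dtype), "conv_b")
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool | None = None) -> np.ndarray:
        cache = train if cache is None else cache
        out, patches = _conv3d_same(x, self.w.value, return_patches=True)
        self._cache = patches if cache else None
        return out + self.b.value

    def backward(self, gout: np.ndarray) -> np.ndarray:
        kd, kh, kw, cin, cout = self.w.value.shape
        patches = self._cache
        if patches is None:
            raise RuntimeError("backward called without forward(train=True)")
        pf = patches.reshape(-1, patches.shape[-1])
        gf = gout.reshape(-1, cout)
        self.w.grad += (pf.T @ gf).reshape(self.w.value.shape)
        self.b.grad += gf.sum(axis=0)
        # grad wrt input = same-conv of gout with the spatially flipped,
        # in/out-transposed kernel (exact for stride-1 odd 'same' convs)
        w_flip = self.w.value[::-1, ::-1, ::-1].transpose(0, 1, 2, 4, 3)
        return _conv3d_same(gout, np.ascontiguousarray(w_flip))

    def params(self) -> list[Param]:
        return [self.w, self.b]


# ---------------------------------------------------------------------------
# batch normalisation


class BatchNorm(Layer):
    """Per-channel batch normalisation over all non-channel axes.

    Training mode normalises by batch statistics and updates exponential
    running estimates; inference mode uses the running estimates, making the
    forward pass a pure function of (parameters, input).
    """

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3,
                 dtype=np.float32) -> None:
        self.gamma = Param(np.ones(channels, dtype=dtype), "bn_gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), "bn_beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool | None = None) -> np.ndarray:
        cache = train if cache is None else cache
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu).astype(self.running_mean.dtype)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(self.running_var.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if cache:
            self._cache = (xhat, inv, x.ndim, train)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv, ndim, train_stats = self._cache
        axes = tuple(range(ndim - 1))
        m = gout.size // gout.shape[-1]
        self.gamma.grad += (gout * xhat).sum(axis=axes)
        self.beta.grad += gout.sum(axis=axes)
        if not train_stats:
            # running statistics are constants w.r.t. the input
            return self.gamma.value * inv * gout
        gx = (self.gamma.value * inv / m) * (
            m * gout
            - gout.sum(axis=axes)
            - xhat * (gout * xhat).sum(axis=axes)
        )
        return gx

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


# ---------------------------------------------------------------------------
# activations / pooling / dropout


class ELU(Layer):
    """Exponential linear unit, f(x) = x for x>0 else alpha*(exp(x)-1)."""

    def __init__(self, alpha: float = 1.0) -> None:
        self.alpha = alpha
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool | None = None) -> np.ndarray:
        cache = train if cache is None else cache
        neg = self.alpha * np.expm1(np.minimum(x, 0.0))
        out = np.where(x > 0, x, neg)
        if cache:
            self._cache = (x > 0, neg)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        pos, neg = self._cache
        return gout * np.where(pos, 1.0, neg + self.alpha)


class MaxPool3D(Layer):
    """2x2x2 max pooling with stride 2 (spatial dims must be even)."""

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool | None = None) -> np.ndarray:
        cache = train if cache is None else cache
        b, d, h, w, c = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2x2 pooling, got {x.shape}")
        xr = x.reshape(b, d // 2, 2, h // 2, 2, w // 2, 2, c)
        windows = np.ascontiguousarray(xr.transpose(0, 1, 3, 5, 7, 2, 4, 6)).reshape(
            b, d // 2, h // 2, w // 2, c, 8
        )
        idx = windows.argmax(axis=-1)
        out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
        if cache:
            self._cache = (idx, x.shape)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        idx, in_shape = self._cache
        b, d, h, w, c = in_shape
        gwin = np.zeros((b, d // 2, h // 2, w // 2, c, 8), dtype=gout.dtype)
        np.put_along_axis(gwin, idx[..., None], gout[..., None], axis=-1)
        gx = gwin.reshape(b, d // 2, h // 2, w // 2, c, 2, 2, 2).transpose(
            0, 1, 5, 2, 6, 3, 7, 4
        )
        return np.ascontiguousarray(gx).reshape(in_shape)


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool | None = None) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask.astype(x.dtype)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gout
        return gout * self._mask.astype(gout.dtype)


class Dense(Layer):
    """Fully connected layer with optional l2 penalty on the kernel."""

    def __init__(self, fin: int, fout: int, rng: np.random.Generator,
                 l2: float = 0.0, dtype=np.float32) -> None:
        limit = np.sqrt(6.0 / (fin + fout))
        self.w = Param(rng.uniform(-limit, limit, size=(fin, fout)).astype(dtype), "dense_w")
        self.b = Param(np.zeros(fout, dtype=dtype), "dense_b")
        self.l2 = l2
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool | None = None) -> np.ndarray:
        cache = train if cache is None else cache
        if cache:
            self._cache = x
        return x @ self.w.value + self.b.value

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.w.grad += x.T @ gout
        if self.l2 > 0:
            self.w.grad += 2.0 * self.l2 * self.w.value
        self.b.grad += gout.sum(axis=0)
        return gout @ self.w.value.T

    def l2_loss(self) -> float:
        return float(self.l2 * np.sum(self.w.value.astype(np.float64) ** 2))

    def params(self) -> list[Param]:
        return [self.w, self.b]


# ---------------------------------------------------------------------------
# attention


def attention_forward(Q: np.ndarray, V: np.ndarray, use_scale: bool = False,
                      chunk: Optional[int] = None) -> np.ndarray:
    """Dot-product attention over flattened spatial positions.

    ``Q`` and ``V`` are (B, D, H, W, C) feature maps of identical shape.
    Positions are flattened to a sequence of length N = D*H*W; scores
    S[i, j] = Q_i . V_j (divided by sqrt(C) when ``use_scale``); weights are
    a row softmax; output_i = sum_j weights[i, j] V_j, reshaped back.  The
    values serve as their own keys — no separate key embedding exists.

    ``chunk`` bounds memory to O(chunk * N) by processing query rows in
    slabs; the result is identical.
    """
    if Q.shape != V.shape:
        raise ValueError(f"Q shape {Q.shape} != V shape {V.shape}")
    shape = Q.shape
    b, c = shape[0], shape[-1]
    n = int(np.prod(shape[1:-1]))
    Qf = Q.reshape(b, n, c)
    Vf = V.reshape(b, n, c)
    scale = 1.0 / np.sqrt(c) if use_scale else 1.0
    if chunk is None or chunk >= n:
        S = (Qf @ Vf.transpose(0, 2, 1)) * scale
        S -= S.max(axis=-1, keepdims=True)
        np.exp(S, out=S)
        S /= S.sum(axis=-1, keepdims=True)
        out = S @ Vf
    else:
        out = np.empty_like(Qf)
        Vt = Vf.transpose(0, 2, 1)
        for start in range(0, n, chunk):
            sl = slice(start, min(start + chunk, n))
            S = (Qf[:, sl] @ Vt) * scale
            S -= S.max(axis=-1, keepdims=True)
            np.exp(S, out=S)
            S /= S.sum(axis=-1, keepdims=True)
            out[:, sl] = S @ Vf
    return out.reshape(shape)


class Attention(Layer):
    """Parameter-free attention layer wrapping :func:`attention_forward`.

    In training mode the full softmax weight matrix is cached for backward;
    at inference a chunked computation caps memory on large grids.
    """

    def __init__(self, use_scale: bool = False, inference_chunk: int = 1024) -> None:
        self.use_scale = use_scale
        self.inference_chunk = inference_chunk
        self._cache = None

    def forward(self, Q: np.ndarray, V: np.ndarray, train: bool = False,
                cache: bool | None = None) -> np.ndarray:
        cache = train if cache is None else cache
        if not cache:
            return attention_forward(Q, V, self.use_scale, chunk=self.inference_chunk)
        shape = Q.shape
        b, c = shape[0], shape[-1]
        n = int(np.prod(shape[1:-1]))
        Qf = Q.reshape(b, n, c)
        Vf = V.reshape(b, n, c)
        scale = 1.0 / np.sqrt(c) if self.use_scale else 1.0
        S = (Qf @ Vf.transpose(0, 2, 1)) * scale
        S -= S.max(axis=-1, keepdims=True)
        np.exp(S, out=S)
        S /= S.sum(axis=-1, keepdims=True)
        out = S @ Vf
        self._cache = (Qf, Vf, S, scale, shape)
        return out.reshape(shape)

    def backward(self, gout: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Qf, Vf, A, scale, shape = self._cache
        b, c = shape[0], shape[-1]
        n = A.shape[1]
        g = gout.reshape(b, n, c)
        dV = A.transpose(0, 2, 1) @ g
        # turn dA into dS in place: dS = A * (dA - rowsum(dA * A))
        dS = g @ Vf.transpose(0, 2, 1)
        dS -= np.einsum("bnm,bnm->bn", dS, A)[..., None]
        dS *= A
        dQ = (dS @ Vf) * scale
        dV += (dS.transpose(0, 2, 1) @ Qf) * scale
        return dQ.reshape(shape), dV.reshape(shape)


# ---------------------------------------------------------------------------
# optimiser


class Adam:
    """Adam with Keras-flavoured defaults (beta1=0.9, beta2=0.999, eps=1e-7)."""

    def __init__(self, params: Sequence[Param], lr: float = 7e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64)
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            update = self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
            p.value = (p.value.astype(np.float64) - update).astype(p.value.dtype)
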