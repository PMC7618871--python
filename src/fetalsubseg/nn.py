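"""Minimal NumPy 3D convolutional network stack.

Implements exactly what the segmentation U-Net needs — 3D convolution,
batch normalization, ReLU, 2x max-pooling, nearest-neighbour upsampling,
skip concatenation and an Adam optimizer — with hand-derived backward
passes.  Convolutions are computed as a sum over kernel offsets of
channel-mixing matmuls, which keeps memory low and routes the heavy
lifting through BLAS.  Tensors are ``(batch, channels, D, H, W)``
float32; everything is deterministic given the seeded initializer.
"""

from __future__ import annotations

import numpy as np

try:  # fused JIT conv kernels; the BLAS/im2col path is the fallback
    import numba as _numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

_f32 = np.float32


if _HAVE_NUMBA:

    @_numba.njit(fastmath=True, cache=True)
    def _conv_fwd_kernel(xp, w, bias, out):
        B, C, Dp, Hp, Wp = xp.shape
        cout, _, k, _, _ = w.shape
        _, _, D, H, W = out.shape
        for bb in range(B):
            for co in range(cout):
                for z in range(D):
                    for y in range(H):
                        orow = out[bb, co, z, y]
                        for x in range(W):
                            orow[x] = bias[co]
                        for ci in range(C):
                            for dz in range(k):
                                for dy in range(k):
                                    row = xp[bb, ci, z + dz, y + dy]
                                    for dx in range(k):
                                        wv = w[co, ci, dz, dy, dx]
                                        for x in range(W):
                                            orow[x] += wv * row[x + dx]

    @_numba.njit(fastmath=True, cache=True)
    def _conv_gradw_kernel(xp, gout, gw):
        B, C, Dp, Hp, Wp = xp.shape
        cout, _, k, _, _ = gw.shape
        _, _, D, H, W = gout.shape
        sacc = np.zeros(k, dtype=np.float64)
        for bb in range(B):
            for co in range(cout):
                for ci in range(C):
                    for dz in range(k):
                        for dy in range(k):
                            for dx in range(k):
                                sacc[dx] = 0.0
                            for z in range(D):
                                for y in range(H):
                                    g = gout[bb, co, z, y]
                                    row = xp[bb, ci, z + dz, y + dy]
                                    for dx in range(k):
                                        s = 0.0
                                        for x in range(W):
                                            s += g[x] * row[x + dx]
                                        sacc[dx] += s
                            for dx in range(k):
                                gw[co, ci, dz, dy, dx] += sacc[dx]


class Layer:
    params: list["Param"]

    def __init__(self):
        self.params = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(_f32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Conv3d(Layer):
    """3D convolution with 'same' zero padding (odd kernel)."""

    def __init__(self, cin: int, cout: int, ksize: int = 3, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = cin * ksize**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, ksize, ksize, ksize))
        self.w = Param(w)
        self.b = Param(np.zeros(cout))
        self.params = [self.w, self.b]
        self.ksize = ksize
        self.pad = ksize // 2

    def _im2col(self, xp_b: np.ndarray, D: int, H: int, W: int) -> np.ndarray:
        # (C, k^3, V) column matrix for one sample's padded volume
        k = self.ksize
        C = xp_b.shape[0]
        col = np.empty((C, k**3, D * H * W), dtype=_f32)
        o = 0
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    col[:, o] = xp_b[:, i:i + D, j:j + H, l:l + W].reshape(C, -1)
                    o += 1
        return col

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        k, p = self.ksize, self.pad
        B, C, D, H, W = x.shape
        x = np.ascontiguousarray(x)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        cout = self.w.value.shape[0]
        self._pad_shape = xp.shape
        if _HAVE_NUMBA:
            out = np.empty((B, cout, D, H, W), dtype=x.dtype)
            _conv_fwd_kernel(xp, self.w.value, self.b.value.astype(x.dtype), out)
            self._xp = xp if train else None
            return out
        w2 = self.w.value.reshape(cout, C * k**3)
        out = np.empty((B, cout, D * H * W), dtype=_f32)
        cols = []
        for b in range(B):  # per sample: one large GEMM, bounded memory
            col = self._im2col(xp[b], D, H, W)
            out[b] = w2 @ col.reshape(C * k**3, -1)
            if train:
                cols.append(col)
        self._cols = cols if train else None
        out += self.b.value[None, :, None]
        return out.reshape(B, cout, D, H, W)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, p = self.ksize, self.pad
        B, cout, D, H, W = grad.shape
        C = self._pad_shape[1]
        self.b.grad += grad.sum(axis=(0, 2, 3, 4))
        if _HAVE_NUMBA:
            grad = np.ascontiguousarray(grad)
            gw = np.zeros_like(self.w.grad)
            _conv_gradw_kernel(self._xp, grad, gw)
            self.w.grad += gw
            # grad wrt input: same-padded correlation of the output grad
            # with the channel-transposed, spatially flipped kernel
            wt = np.ascontiguousarray(
                self.w.value.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1])
            gp = np.pad(grad, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else grad
            cin = self.w.value.shape[1]
            gx = np.empty((B, cin, D, H, W), dtype=grad.dtype)
            _conv_fwd_kernel(gp, wt, np.zeros(cin, dtype=grad.dtype), gx)
            self._xp = None
            return gx
        w2 = self.w.value.reshape(cout, C * k**3)
        gw2 = np.zeros_like(w2)
        gxp = np.zeros(self._pad_shape, dtype=_f32)
        for b in range(B):
            g = grad[b].reshape(cout, -1)
            col = self._cols[b]
            gw2 += g @ col.reshape(C * k**3, -1).T
            gcol = (w2.T @ g).reshape(C, k**3, D, H, W)
            o = 0
            for i in range(k):  # col2im scatter-add
                for j in range(k):
                    for l in range(k):
                        gxp[b, :, i:i + D, j:j + H, l:l + W] += gcol[:, o]
                        o += 1
        self.w.grad += gw2.reshape(self.w.value.shape)
        self._cols = None
        return gxp[:, :, p:p + D, p:p + H, p:p + W] if p else gxp


class BatchNorm3d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.params = [self.gamma, self.beta]
        self.running_mean = np.zeros(c, dtype=_f32)
        self.running_var = np.ones(c, dtype=_f32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        # Normalization always uses the statistics of the current input:
        # with the tiny batches used here, frozen running averages differ
        # systematically from any batch's statistics and degrade inference
        # (instance-normalization-style behaviour at batch size 1).
        # Running buffers are still tracked for inspection/checkpoints.
        axes = (0, 2, 3, 4)
        mean = x.mean(axis=axes)
        var = x.var(axis=axes)
        if train:
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(_f32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(_f32)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv[None, :, None, None, None]
        if train:
            self._cache = (xhat, inv)
        out = xhat * self.gamma.value[None, :, None, None, None] \
            + self.beta.value[None, :, None, None, None]
        return out.astype(_f32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        axes = (0, 2, 3, 4)
        n = grad.shape[0] * grad.shape[2] * grad.shape[3] * grad.shape[4]
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value[None, :, None, None, None]
        gsum = g.sum(axis=axes, keepdims=True)
        gxsum = (g * xhat).sum(axis=axes, keepdims=True)
        return ((g - gsum / n - xhat * gxsum / n)
                * inv[None, :, None, None, None]).astype(_f32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        self._mask = None
        return out


class MaxPool3d(Layer):
    """2x2x2 max pooling; spatial dims must be even."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, D, H, W = x.shape
        r = x.reshape(B, C, D // 2, 2, H // 2, 2, W // 2, 2)
        r = r.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(B, C, D // 2, H // 2, W // 2, 8)
        idx = np.argmax(r, axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._in_shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, D2, H2, W2 = grad.shape
        g = np.zeros((B, C, D2, H2, W2, 8), dtype=_f32)
        np.put_along_axis(g, self._idx[..., None], grad[..., None], axis=-1)
        g = g.reshape(B, C, D2, H2, W2, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        out = g.reshape(self._in_shape)
        self._idx = None
        return out


class Upsample3d(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, D, H, W = grad.shape
        r = grad.reshape(B, C, D // 2, 2, H // 2, 2, W // 2, 2)
        return r.sum(axis=(3, 5, 7))


class ConvBlock(Layer):
    """(conv -> BN -> ReLU) x2, the standard U-Net level block."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.layers = [
            Conv3d(cin, cout, 3, rng), BatchNorm3d(cout), ReLU(),
            Conv3d(cout, cout, 3, rng), BatchNorm3d(cout), ReLU(),
        ]
        for l in self.layers:
            self.params.extend(l.params)

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class UNet3D:
    """Symmetric 3D U-Net: per-level double-conv blocks with BN/ReLU,
    2x pooling, channel doubling per level, nearest upsampling with a
    channel-halving convolution, and skip concatenation.

    ``depth`` counts resolution levels (the bottleneck included), so the
    input grid must be divisible by ``2**(depth-1)``.
    """

    def __init__(self, depth: int = 5, init_features: int = 16, num_classes: int = 5,
                 in_channels: int = 1, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.depth = depth
        feats = [init_features * 2**l for l in range(depth)]
        self.enc = []
        cin = in_channels
        for f in feats:
            self.enc.append(ConvBlock(cin, f, rng))
            cin = f
        self.pool = MaxPool3d()
        self.up_convs = []
        self.dec = []
        for l in range(depth - 2, -1, -1):
            self.up_convs.append(Conv3d(feats[l + 1], feats[l], 3, rng))
            self.dec.append(ConvBlock(2 * feats[l], feats[l], rng))
        self.head = Conv3d(feats[0], num_classes, 1, rng)
        self.params: list[Param] = []
        for blk in self.enc + self.up_convs + self.dec + [self.head]:
            self.params.extend(blk.params)
        self.num_classes = num_classes

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Logits on the input grid (softmax applied in the loss/predict)."""
        x = x.astype(_f32)
        skips = []
        self._pools = []
        for l, blk in enumerate(self.enc):
            x = blk.forward(x, train)
            if l < self.depth - 1:
                skips.append(x)
                pool = MaxPool3d()
                x = pool.forward(x, train)
                self._pools.append(pool)
        self._ups = []
        self._skip_channels = []
        for up_conv, dec in zip(self.up_convs, self.dec):
            up = Upsample3d()
            x = up.forward(x, train)
            self._ups.append(up)
            x = up_conv.forward(x, train)
            skip = skips.pop()
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, grad: np.ndarray) -> None:
        grad = self.head.backward(grad)
        skip_grads = []
        for up_conv, dec, up, cs in zip(reversed(self.up_convs), reversed(self.dec),
                                        reversed(self._ups),
                                        reversed(self._skip_channels)):
            # walk the decoder in reverse build order
            pass
        # explicit reverse pass (kept unrolled for clarity)
        for i in range(len(self.dec) - 1, -1, -1):
            grad = self.dec[i].backward(grad)
            cs = self._skip_channels[i]
            skip_grad, grad = grad[:, :cs], grad[:, cs:]
            skip_grads.append(skip_grad)
            grad = self.up_convs[i].backward(grad)
            grad = self._ups[i].backward(grad)
        for l in range(self.depth - 1, -1, -1):
            if l < self.depth - 1:
                grad = self._pools[l].backward(grad)
                grad = grad + skip_grads[len(skip_grads) - 1 - (self.depth - 2 - l)]
            grad = self.enc[l].backward(grad)
        self._pools = self._ups = None

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[:] = 0

    def state_dict(self) -> dict:
        state = {"params": [p.value.copy() for p in self.params], "bn": []}
        for blk in self._bn_layers():
            state["bn"].append((blk.running_mean.copy(), blk.running_var.copy()))
        return state

    def load_state_dict(self, state: dict) -> None:
        for p, v in zip(self.params, state["params"]):
            p.value[:] = v
        for blk, (rm, rv) in zip(self._bn_layers(), state["bn"]):
            blk.running_mean[:] = rm
            blk.running_var[:] = rv

    def _bn_layers(self):
        for blk in self.enc + self.dec:
            for l in blk.layers:
                if isinstance(l, BatchNorm3d):
                    yield l


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p in self.params:
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * p.grad**2
            p.value -= self.lr * (p.m / bc1) / (np.sqrt(p.v / bc2) + self.eps)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
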