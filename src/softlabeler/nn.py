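"""A small U-shaped fully convolutional network in pure NumPy.

The segmentation backbone is an encoder-decoder with skip connections:
one 3x3 convolution + ReLU per level, 2x2 max-pooling on the way down,
nearest-neighbour upsampling and skip concatenation on the way up, and a
final 1x1 convolution + sigmoid producing per-pixel lesion probabilities.
Forward and backward passes are written explicitly (im2col matrix
multiplies); the optimiser is a hand-written Adam.  This keeps training
runnable on one CPU with no deep-learning framework while preserving the
U-Net family's structural ingredients (matched down/up levels, skips).

Tensors are ``(N, C, H, W)`` float64.  The loss gradient enters through
``backward(dlogits)`` where ``dlogits`` is the derivative of the scalar
loss w.r.t. the pre-sigmoid logits.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError

__all__ = ["UNet", "Adam", "build_network"]


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, C*9, H*W) patch matrix for 3x3 same-padding conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    v = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # v: (N, C, H, W, 3, 3) -> (N, C, 3, 3, H, W) -> (N, C*9, H*W)
    return np.ascontiguousarray(v.transpose(0, 1, 4, 5, 2, 3)).reshape(n, c * 9, h * w)


class _Conv3x3:
    """3x3 stride-1 same-padding convolution with bias."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        # He initialisation for ReLU units
        std = np.sqrt(2.0 / (c_in * 9))
        self.w = rng.normal(0.0, std, size=(c_out, c_in, 3, 3))
        self.b = np.zeros(c_out)
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col3(x)
        self._cols, self._in_shape = cols, x.shape
        wmat = self.w.reshape(self.w.shape[0], -1)
        y = np.matmul(wmat, cols) + self.b[:, None]
        return y.reshape(n, -1, h, w)

    def backward(self, dy: np.ndarray):
        n, co, h, w = dy.shape
        dyf = dy.reshape(n, co, h * w)
        dw = np.einsum("nop,ncp->oc", dyf, self._cols).reshape(self.w.shape)
        db = dyf.sum(axis=(0, 2))
        # dX = same-padding conv of dY with the 180-degree-rotated kernels,
        # input/output channels swapped
        w_t = self.w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        cols_dy = _im2col3(dy)
        dx = np.matmul(w_t.reshape(w_t.shape[0], -1), cols_dy)
        dx = dx.reshape(n, -1, h, w)
        self._cols = None
        return dx, [dw, db]


class _Conv1x1:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / c_in)
        self.w = rng.normal(0.0, std, size=(c_out, c_in))
        self.b = np.zeros(c_out)
        self._x: np.ndarray | None = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.einsum("oc,nchw->nohw", self.w, x) + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray):
        dw = np.einsum("nohw,nchw->oc", dy, self._x)
        db = dy.sum(axis=(0, 2, 3))
        dx = np.einsum("oc,nohw->nchw", self.w, dy)
        self._x = None
        return dx, [dw, db]


def _relu_fwd(x):
    mask = x > 0
    return x * mask, mask


def _pool2_fwd(x):
    n, c, h, w = x.shape
    v = x.reshape(n, c, h // 2, 2, w // 2, 2)
    y = v.max(axis=(3, 5))
    # winner mask for routing gradients (ties route to every max entry,
    # which is fine for subgradient descent)
    winners = v == y[:, :, :, None, :, None]
    return y, winners


def _pool2_bwd(dy, winners):
    d = winners * dy[:, :, :, None, :, None]
    n, c, h2, _, w2, _ = d.shape
    return d.reshape(n, c, h2 * 2, w2 * 2)


def _up2_fwd(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _up2_bwd(dy):
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class UNet:
    """Encoder-decoder segmentation network with skip connections.

    ``widths`` gives the channel count per level, shallow to deep; the
    depth is ``len(widths)``. Input must be divisible by 2**(depth-1)
    in both spatial dimensions.
    """

    def __init__(self, widths=(8, 16, 32), in_channels: int = 3, seed: int = 0):
        widths = tuple(int(c) for c in widths)
        if len(widths) < 2:
            raise InvalidParameterError("network needs depth >= 2")
        if any(c < 1 for c in widths):
            raise InvalidParameterError("channel widths must be positive")
        self.widths = widths
        self.depth = len(widths)
        rng = np.random.default_rng(seed)
        self.enc = []
        c_prev = in_channels
        for c in widths:
            self.enc.append(_Conv3x3(c_prev, c, rng))
            c_prev = c
        self.dec = []
        for i in range(self.depth - 2, -1, -1):
            self.dec.append(_Conv3x3(widths[i + 1] + widths[i], widths[i], rng))
        self.head = _Conv1x1(widths[0], 1, rng)
        self._cache: dict | None = None

    # -- parameter plumbing ------------------------------------------------
    @property
    def layers(self):
        return [*self.enc, *self.dec, self.head]

    def parameters(self):
        return [p for layer in self.layers for p in layer.params]

    def set_parameters(self, values) -> None:
        for p, v in zip(self.parameters(), values, strict=True):
            p[...] = v

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- forward / backward ------------------------------------------------
    def _check_spatial(self, h: int, w: int) -> None:
        f = 2 ** (self.depth - 1)
        if h % f or w % f:
            raise InvalidParameterError(
                f"spatial size {h}x{w} not divisible by {f} (depth {self.depth})")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Predicted lesion probabilities, shape (N, H, W)."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[None]
        n, c, h, w = x.shape
        self._check_spatial(h, w)
        cache = {"relu": [], "pool": [], "skips": []}

        a = x
        for i, conv in enumerate(self.enc):
            z = conv.forward(a)
            a, mask = _relu_fwd(z)
            cache["relu"].append(mask)
            if i < self.depth - 1:
                cache["skips"].append(a)
                a, winners = _pool2_fwd(a)
                cache["pool"].append(winners)

        for j, conv in enumerate(self.dec):
            skip = cache["skips"][self.depth - 2 - j]
            a = np.concatenate([_up2_fwd(a), skip], axis=1)
            z = conv.forward(a)
            a, mask = _relu_fwd(z)
            cache["relu"].append(mask)

        logits = self.head.forward(a)[:, 0]
        probs = 1.0 / (1.0 + np.exp(-logits))
        self._cache = cache if train else None
        return probs

    def backward(self, dlogits: np.ndarray):
        """Gradients of the loss w.r.t. every parameter.

        ``dlogits``: derivative w.r.t. the pre-sigmoid logits, (N, H, W).
        Must follow a ``forward(..., train=True)`` call.
        """
        if self._cache is None:
            raise InvalidParameterError("backward requires forward(train=True)")
        cache = self._cache
        grads = {}

        da, g = self.head.backward(np.asarray(dlogits)[:, None])
        grads[id(self.head)] = g

        relu_masks = cache["relu"]
        dskips = [None] * (self.depth - 1)
        # decoder layers in reverse (shallow to deep)
        for j in range(len(self.dec) - 1, -1, -1):
            conv = self.dec[j]
            da = da * relu_masks[self.depth + j]
            da, g = conv.backward(da)
            grads[id(conv)] = g
            # split concat: first block came from upsampling, second is the skip
            c_deep = self.widths[self.depth - 1 - j]
            d_up, d_skip = da[:, :c_deep], da[:, c_deep:]
            dskips[self.depth - 2 - j] = d_skip
            da = _up2_bwd(d_up)

        for i in range(self.depth - 1, -1, -1):
            conv = self.enc[i]
            if i < self.depth - 1:
                da = _pool2_bwd(da, cache["pool"][i])
                da = da + dskips[i]
            da = da * relu_masks[i]
            da, g = conv.backward(da)
            grads[id(conv)] = g

        self._cache = None
        return [gi for layer in self.layers for gi in grads[id(layer)]]


def build_network(channels=(8, 16, 32), depth: int | None = None,
                  in_channels: int = 3, seed: int = 0) -> UNet:
    """Construct a seeded U-shaped network; ``depth`` defaults to
    ``len(channels)`` and must match it when given."""
    if depth is not None and depth != len(channels):
        raise InvalidParameterError(
            f"depth={depth} does not match {len(channels)} channel widths")
    return UNet(widths=channels, in_channels=in_channels, seed=seed)


class Adam:
    """Adam optimiser over a flat list of parameter arrays."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
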