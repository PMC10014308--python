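"""Layer primitives with explicit forward/backward passes.

Array convention: batches are channel-first, ``(B, C, *spatial)`` with 2 or 3
spatial dimensions.  Each layer caches what its backward pass needs during
``forward`` and exposes parameter/gradient dicts for the optimizers.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: parameterless layers leave ``params``/``grads`` empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class ConvND(Layer):
    """N-D convolution (cross-correlation), stride 1, zero-padded to same size.

    Weights ``W`` have shape ``(out_channels, in_channels, *kernel)``; He
    initialization scaled by fan-in.  Odd kernel sizes only.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        ndim: int,
        kernel: int = 3,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("ConvND supports odd kernels only")
        rng = rng or np.random.default_rng(0)
        self.ndim = ndim
        self.kernel = (kernel,) * ndim
        fan_in = in_channels * kernel**ndim
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels) + self.kernel)
        self.params = {"W": w.astype(dtype), "b": np.zeros(out_channels, dtype=dtype)}
        self._x_padded: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        W, b = self.params["W"], self.params["b"]
        nd = self.ndim
        pad = [(0, 0), (0, 0)] + [((k - 1) // 2,) * 2 for k in self.kernel]
        xp = np.pad(x, pad)
        self._x_padded = xp
        self._spatial = x.shape[2:]
        win = sliding_window_view(xp, self.kernel, axis=tuple(range(2, 2 + nd)))
        # contract input channels + kernel offsets against W
        out = np.tensordot(
            win,
            W,
            axes=([1] + list(range(2 + nd, 2 + 2 * nd)), [1] + list(range(2, 2 + nd))),
        )
        out = np.moveaxis(out, -1, 1)
        return out + b.reshape((1, -1) + (1,) * nd)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        W = self.params["W"]
        xp = self._x_padded
        nd = self.ndim
        spatial = self._spatial
        sum_axes = (0,) + tuple(range(2, 2 + nd))

        dW = np.zeros_like(W)
        dxp = np.zeros_like(xp)
        for offset in product(*(range(k) for k in self.kernel)):
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(offset, spatial)
            )
            dW[(slice(None), slice(None)) + offset] = np.tensordot(
                dout, xp[sl], axes=(sum_axes, sum_axes)
            )
            w_o = W[(slice(None), slice(None)) + offset]  # (F, C)
            dxp[sl] += np.einsum("fc,bf...->bc...", w_o, dout)
        self.grads = {"W": dW, "b": dout.sum(axis=sum_axes)}

        crop = (slice(None), slice(None)) + tuple(
            slice((k - 1) // 2, (k - 1) // 2 + s) for k, s in zip(self.kernel, spatial)
        )
        self._x_padded = None
        return dxp[crop]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0)


class MaxPoolND(Layer):
    """2x max pooling along every spatial axis; odd sizes are -inf padded."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        nd = x.ndim - 2
        self._in_shape = x.shape
        pads = [(0, 0), (0, 0)] + [(0, s % 2) for s in x.shape[2:]]
        xp = np.pad(x, pads, constant_values=-np.inf)
        self._padded_shape = xp.shape
        newshape = xp.shape[:2] + tuple(
            v for s in xp.shape[2:] for v in (s // 2, 2)
        )
        xr = xp.reshape(newshape)
        win_axes = tuple(3 + 2 * i for i in range(nd))
        xr = np.moveaxis(xr, win_axes, tuple(range(-nd, 0)))
        flat = xr.reshape(xr.shape[:-nd] + (2**nd,))
        self._argmax = flat.argmax(axis=-1)
        return np.take_along_axis(flat, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        nd = len(self._in_shape) - 2
        flat = np.zeros(dout.shape + (2**nd,), dtype=dout.dtype)
        np.put_along_axis(flat, self._argmax[..., None], dout[..., None], axis=-1)
        xr = flat.reshape(dout.shape + (2,) * nd)
        win_axes = tuple(3 + 2 * i for i in range(nd))
        xr = np.moveaxis(xr, tuple(range(-nd, 0)), win_axes)
        dxp = xr.reshape(self._padded_shape)
        crop = (slice(None), slice(None)) + tuple(slice(0, s) for s in self._in_shape[2:])
        return dxp[crop]


class UpConvND(Layer):
    """Transposed convolution with kernel 2, stride 2 (non-overlapping).

    Doubles every spatial dimension; weights ``W`` have shape
    ``(in_channels, out_channels, *2)``.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        ndim: int,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.ndim = ndim
        w = rng.normal(
            0.0, np.sqrt(2.0 / in_channels), size=(in_channels, out_channels) + (2,) * ndim
        )
        self.params = {"W": w.astype(dtype), "b": np.zeros(out_channels, dtype=dtype)}

    def forward(self, x: np.ndarray) -> np.ndarray:
        W, b = self.params["W"], self.params["b"]
        self._x = x
        nd = self.ndim
        out_shape = x.shape[:1] + (W.shape[1],) + tuple(2 * s for s in x.shape[2:])
        out = np.empty(out_shape, dtype=x.dtype)
        for offset in product((0, 1), repeat=nd):
            sl = (slice(None), slice(None)) + tuple(slice(o, None, 2) for o in offset)
            w_o = W[(slice(None), slice(None)) + offset]  # (C, F)
            out[sl] = np.einsum("cf,bc...->bf...", w_o, x)
        return out + b.reshape((1, -1) + (1,) * nd)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        W = self.params["W"]
        x = self._x
        nd = self.ndim
        sum_axes = (0,) + tuple(range(2, 2 + nd))
        dW = np.zeros_like(W)
        dx = np.zeros_like(x)
        for offset in product((0, 1), repeat=nd):
            sl = (slice(None), slice(None)) + tuple(slice(o, None, 2) for o in offset)
            d_o = dout[sl]
            w_o = W[(slice(None), slice(None)) + offset]
            dW[(slice(None), slice(None)) + offset] = np.tensordot(
                x, d_o, axes=(sum_axes, sum_axes)
            )
            dx += np.einsum("cf,bf...->bc...", w_o, d_o)
        self.grads = {"W": dW, "b": dout.sum(axis=sum_axes)}
        self._x = None
        return dx


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    """Numerically stable softmax along ``axis``."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, class_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean per-pixel cross-entropy and its gradient w.r.t. the logits.

    ``logits``: ``(B, n_classes, *spatial)``; ``labels``: integer class ids
    ``(B, *spatial)``.  Optional ``class_weights`` (length ``n_classes``)
    reweight each pixel's term by its true class; the loss is normalized by
    the total weight so unit weights reduce to the plain mean.
    """
    p = softmax(logits, axis=1)
    onehot_p = np.take_along_axis(p, labels[:, None], axis=1)[:, 0]
    nll = -np.log(np.clip(onehot_p, 1e-12, None))
    if class_weights is None:
        total = float(labels.size)
        pixel_w = None
        loss = float(nll.sum() / total)
    else:
        class_weights = np.asarray(class_weights, dtype=np.float64)
        pixel_w = class_weights[labels]
        total = float(pixel_w.sum())
        loss = float((pixel_w * nll).sum() / total)
    dlogits = p.copy()
    idx = labels[:, None]
    np.put_along_axis(
        dlogits, idx, np.take_along_axis(dlogits, idx, axis=1) - 1.0, axis=1
    )
    if pixel_w is not None:
        dlogits *= pixel_w[:, None]
    dlogits /= total
    return loss, dlogits.astype(logits.dtype)
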