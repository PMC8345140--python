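"""Layers with explicit forward/backward on NCHW float32 arrays.

Convolutions use im2col / col2im built from 9 shifted views (3x3 case), so
both passes are plain matrix products.  Each layer caches what its backward
pass needs; ``backward`` returns the gradient w.r.t. the layer input and
stores parameter gradients on the layer (``grads`` dict keyed like
``params``).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Layer", "Conv2d", "ConvTranspose2d", "ReLU", "MaxPool2x2"]


class Layer:
    """Base class: parameterless unless ``params`` is non-empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col3(xp: np.ndarray) -> np.ndarray:
    """(N, C, H+2, W+2) padded input -> (N, C*9, H*W) column matrix."""
    n, c, hp, wp = xp.shape
    h, w = hp - 2, wp - 2
    cols = np.empty((n, c, 9, h, w), dtype=xp.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            cols[:, :, k] = xp[:, :, di : di + h, dj : dj + w]
            k += 1
    return cols.reshape(n, c * 9, h * w)


def _col2im3(dcols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of :func:`_im2col3`; returns the unpadded input gradient."""
    n, c, h, w = shape
    dcols = dcols.reshape(n, c, 9, h, w)
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, k]
            k += 1
    return dxp[:, :, 1 : 1 + h, 1 : 1 + w]


class Conv2d(Layer):
    """3x3 (same padding) or 1x1 convolution with bias, He-initialised."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if kernel not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_ch, in_ch, kernel, kernel))
        self.params = {"w": w.astype(np.float32),
                       "b": np.zeros(out_ch, dtype=np.float32)}
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        wmat = self.params["w"].reshape(self.out_ch, -1)
        if self.kernel == 1:
            cols = x.reshape(n, c, h * w)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
            cols = _im2col3(xp)
        self._cache = (cols, x.shape)
        out = np.einsum("ok,nkp->nop", wmat, cols, optimize=True)
        out += self.params["b"][None, :, None]
        return out.reshape(n, self.out_ch, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, h, w = xshape
        dout2 = dout.reshape(n, self.out_ch, h * w)
        wmat = self.params["w"].reshape(self.out_ch, -1)
        dw = np.einsum("nop,nkp->ok", dout2, cols, optimize=True)
        self.grads["w"] = dw.reshape(self.params["w"].shape)
        self.grads["b"] = dout2.sum(axis=(0, 2))
        dcols = np.einsum("ok,nop->nkp", wmat, dout2, optimize=True)
        if self.kernel == 1:
            return dcols.reshape(xshape)
        return _col2im3(dcols, xshape)


class ConvTranspose2d(Layer):
    """2x2, stride-2 transposed convolution (the U-Net 'up-conv')."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        w = rng.normal(0.0, np.sqrt(2.0 / in_ch), size=(in_ch, out_ch, 2, 2))
        self.params = {"w": w.astype(np.float32),
                       "b": np.zeros(out_ch, dtype=np.float32)}
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._cache = x
        # out[n,o,2i+a,2j+b] = sum_c x[n,c,i,j] * w[c,o,a,b]
        out = np.einsum("ncij,coab->noiajb", x, self.params["w"], optimize=True)
        out = out.reshape(n, self.out_ch, 2 * h, 2 * w)
        out += self.params["b"][None, :, None, None]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        n, c, h, w = x.shape
        d = dout.reshape(n, self.out_ch, h, 2, w, 2)
        self.grads["w"] = np.einsum("ncij,noiajb->coab", x, d, optimize=True)
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        return np.einsum("coab,noiajb->ncij", self.params["w"], d, optimize=True)


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0)


class MaxPool2x2(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2x2 needs even spatial dims")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        self._cache = (arg, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        arg, (n, c, h, w) = self._cache
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, arg[..., None], dout[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2) \
            .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        return dx
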