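"""Minimal numpy neural-network layers with explicit backpropagation.

Dense 3D convolution is implemented by gathering patches into a
``(batch, positions, patch)`` matrix ("im2col") followed by one GEMM;
the transposed convolution is its exact adjoint (scatter-add with the
same index map). Activations use the ``(B, C, D, H, W)`` layout with
``D`` the temporal axis. All arithmetic is float32.

Layers cache whatever the backward pass needs during ``forward``; a
layer therefore supports one in-flight forward/backward pair at a time,
which is all a plain training loop requires.
"""

from __future__ import annotations

import numpy as np

Triple = tuple[int, int, int]


class Param:
    """A learnable tensor and its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray, need_input_grad: bool = True):
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


def _conv_geometry(
    in_ch: int, spatial: Triple, kernel: Triple, stride: Triple, padding: Triple
):
    """Index map for im2col on a zero-padded (C, Dp, Hp, Wp) volume.

    Returns (idx, out_spatial, padded_spatial) where ``idx`` has shape
    (P, K): P = number of output positions (C-order over D, H, W), and
    K = C * kd * kh * kw flat indices into the padded volume.
    """
    d, h, w = spatial
    kd, kh, kw = kernel
    sd, sh, sw = stride
    pd, ph, pw = padding
    dp, hp, wp = d + 2 * pd, h + 2 * ph, w + 2 * pw
    do = (dp - kd) // sd + 1
    ho = (hp - kh) // sh + 1
    wo = (wp - kw) // sw + 1
    if min(do, ho, wo) < 1:
        raise ValueError(
            f"kernel {kernel} with stride {stride} does not fit input {spatial}"
        )
    z0 = (np.arange(do) * sd)[:, None, None]
    y0 = (np.arange(ho) * sh)[None, :, None]
    x0 = (np.arange(wo) * sw)[None, None, :]
    base = ((z0 * hp + y0) * wp + x0).reshape(-1)  # (P,)
    coff = np.arange(in_ch)[:, None, None, None] * (dp * hp * wp)
    off = (
        coff
        + (np.arange(kd)[None, :, None, None] * hp
           + np.arange(kh)[None, None, :, None]) * wp
        + np.arange(kw)[None, None, None, :]
    ).reshape(-1)  # (K,)
    idx = base[:, None] + off[None, :]
    return idx, (do, ho, wo), (dp, hp, wp)


class Conv3d(Layer):
    """3D convolution with stride and zero padding (He-initialized)."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: Triple,
        stride: Triple = (1, 1, 1),
        padding: Triple = (0, 0, 0),
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        fan_in = in_ch * int(np.prod(kernel))
        self.W = Param(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, out_ch))
        )
        self.b = Param(np.zeros(out_ch))
        self._geom: dict[Triple, tuple] = {}

    def _geometry(self, spatial: Triple):
        if spatial not in self._geom:
            self._geom[spatial] = _conv_geometry(
                self.in_ch, spatial, self.kernel, self.stride, self.padding
            )
        return self._geom[spatial]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C = x.shape[:2]
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {C}")
        idx, out_sp, padded_sp = self._geometry(x.shape[2:])
        pd, ph, pw = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        col = xp.reshape(B, -1)[:, idx]  # (B, P, K)
        out = col @ self.W.value + self.b.value  # (B, P, F)
        self._cache = (col, x.shape, idx, padded_sp)
        do, ho, wo = out_sp
        return out.reshape(B, do, ho, wo, self.out_ch).transpose(0, 4, 1, 2, 3)

    def backward(self, grad: np.ndarray, need_input_grad: bool = True):
        col, x_shape, idx, padded_sp = self._cache
        B = grad.shape[0]
        g = grad.transpose(0, 2, 3, 4, 1).reshape(B, -1, self.out_ch)  # (B,P,F)
        K = col.shape[2]
        self.W.grad += col.reshape(-1, K).T @ g.reshape(-1, self.out_ch)
        self.b.grad += g.sum(axis=(0, 1))
        if not need_input_grad:
            self._cache = None
            return None
        dcol = g @ self.W.value.T  # (B, P, K)
        dp, hp, wp = padded_sp
        size = self.in_ch * dp * hp * wp
        flat_idx = idx.reshape(-1)
        dxp = np.empty((B, size), dtype=np.float32)
        for bb in range(B):
            dxp[bb] = np.bincount(
                flat_idx, weights=dcol[bb].reshape(-1), minlength=size
            )
        dxp = dxp.reshape(B, self.in_ch, dp, hp, wp)
        pd, ph, pw = self.padding
        d, h, w = x_shape[2:]
        self._cache = None
        return dxp[:, :, pd : pd + d, ph : ph + h, pw : pw + w]

    def params(self) -> list[Param]:
        return [self.W, self.b]


class ConvTranspose3d(Layer):
    """Transposed 3D convolution, the adjoint of :class:`Conv3d`.

    ``output_size`` fixes the spatial shape of the output explicitly
    (resolving the stride ambiguity without output-padding arithmetic):
    the layer is the adjoint of a Conv3d mapping ``output_size`` down to
    the input's spatial size with the given kernel/stride/padding.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: Triple,
        stride: Triple,
        padding: Triple,
        output_size: Triple,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.output_size = output_size
        idx, small_sp, padded_sp = _conv_geometry(
            out_ch, output_size, kernel, stride, padding
        )
        self._idx, self._small_sp, self._padded_sp = idx, small_sp, padded_sp
        K = out_ch * int(np.prod(kernel))
        fan_in = in_ch
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (K, in_ch)))
        self.b = Param(np.zeros(out_ch))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C = x.shape[:2]
        if C != self.in_ch or x.shape[2:] != self._small_sp:
            raise ValueError(
                f"expected input ({self.in_ch}, {self._small_sp}), got {x.shape[1:]}"
            )
        x2 = x.transpose(0, 2, 3, 4, 1).reshape(B, -1, self.in_ch)  # (B,P,F)
        dcol = x2 @ self.W.value.T  # (B, P, K)
        dp, hp, wp = self._padded_sp
        size = self.out_ch * dp * hp * wp
        flat_idx = self._idx.reshape(-1)
        yp = np.empty((B, size), dtype=np.float32)
        for bb in range(B):
            yp[bb] = np.bincount(
                flat_idx, weights=dcol[bb].reshape(-1), minlength=size
            )
        yp = yp.reshape(B, self.out_ch, dp, hp, wp)
        pd, ph, pw = self.padding
        d, h, w = self.output_size
        y = yp[:, :, pd : pd + d, ph : ph + h, pw : pw + w]
        y = y + self.b.value[None, :, None, None, None]
        self._cache = x2
        return np.ascontiguousarray(y)

    def backward(self, grad: np.ndarray, need_input_grad: bool = True):
        x2 = self._cache
        B = grad.shape[0]
        pd, ph, pw = self.padding
        gp = np.pad(grad, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        col = gp.reshape(B, -1)[:, self._idx]  # (B, P, K)
        K = col.shape[2]
        self.W.grad += col.reshape(-1, K).T @ x2.reshape(-1, self.in_ch)
        self.b.grad += grad.sum(axis=(0, 2, 3, 4))
        self._cache = None
        if not need_input_grad:
            return None
        dx2 = col @ self.W.value  # (B, P, F)
        do, ho, wo = self._small_sp
        return dx2.reshape(B, do, ho, wo, self.in_ch).transpose(0, 4, 1, 2, 3)

    def params(self) -> list[Param]:
        return [self.W, self.b]


class Dense(Layer):
    def __init__(self, in_units: int, out_units: int, rng=None):
        rng = rng or np.random.default_rng()
        self.W = Param(
            rng.normal(0.0, np.sqrt(2.0 / in_units), (in_units, out_units))
        )
        self.b = Param(np.zeros(out_units))

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad, need_input_grad=True):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        self._x = None
        return grad @ self.W.value.T if need_input_grad else None

    def params(self):
        return [self.W, self.b]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad, need_input_grad=True):
        g = grad * self._mask
        self._mask = None
        return g


class ClippedReLU(Layer):
    """ReLU capped at ``ceiling`` (255 keeps reconstructions valid 8-bit)."""

    def __init__(self, ceiling: float = 255.0):
        self.ceiling = ceiling

    def forward(self, x, train=False):
        self._mask = (x > 0) & (x < self.ceiling)
        return np.clip(x, 0.0, self.ceiling)

    def backward(self, grad, need_input_grad=True):
        g = grad * self._mask
        self._mask = None
        return g


class Dropout(Layer):
    """Inverted dropout; active only when ``train=True``. The mask RNG is
    owned by the layer so training runs are reproducible via reseeding."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad, need_input_grad=True):
        if self._mask is None:
            return grad
        g = grad * self._mask
        self._mask = None
        return g


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad, need_input_grad=True):
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad, need_input_grad=True):
        for i, layer in enumerate(reversed(self.layers)):
            last = i == len(self.layers) - 1
            grad = layer.backward(grad, need_input_grad or not last)
            if last and not need_input_grad:
                return None
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
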