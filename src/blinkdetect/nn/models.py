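"""The three 3D subsequence classifiers.

All three map a ``(48, 48, ns)`` grayscale window (raw 0-255 intensity)
to a blink probability:

* ``cnn3d``    -- the 4-block 3D conv encoder + latent dense layer and a
  fully-connected classifier head;
* ``ae3d``     -- the same encoder/head plus a skip-connected transposed-conv
  decoder reconstructing the input (clipped-ReLU ceiling 255), trained
  with a weighted classification + reconstruction objective;
* ``resnet3d`` -- a compact residual network (stem + one stack of four
  64-filter residual blocks + global average pooling).

Intensities are scaled by 1/255 at the network entry; reconstruction
targets stay on the raw 0-255 scale, matching the decoder's clipped
output range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..types import DEFAULT_NS, EYE_SIZE
from .layers import (
    ClippedReLU,
    Conv3d,
    ConvTranspose3d,
    Dense,
    Dropout,
    Flatten,
    Layer,
    Param,
    ReLU,
    Sequential,
    softmax,
)

logger = logging.getLogger(__name__)

ARCHITECTURES = ("cnn3d", "ae3d", "resnet3d")


@dataclass
class ClassifierSpec:
    """Architecture and structural hyperparameters of one classifier."""

    architecture: str = "cnn3d"
    ns: int = DEFAULT_NS
    latent_units: int = 2048
    dropout_rate: float = 0.3
    loss_weights: tuple[float, float] = (0.9, 0.1)
    head_units: tuple[int, ...] = (256, 64)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; "
                f"expected one of {ARCHITECTURES}"
            )
        if self.latent_units <= 0:
            raise ValueError("latent_units must be positive")
        if abs(sum(self.loss_weights) - 1.0) > 1e-9:
            raise ValueError("loss weights must sum to 1")


class BaseModel:
    """Shared plumbing: the classifier contract, parameter bookkeeping,
    checkpoint round-trips."""

    spec: ClassifierSpec

    def params(self) -> list[Param]:
        raise NotImplementedError

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits of shape (B, 2) from a (B, 1, ns, H, W) float batch."""
        raise NotImplementedError

    def backward(self, dlogits: np.ndarray) -> None:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[:] = 0.0

    def reseed_dropout(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for layer in self._dropout_layers():
            layer.rng = np.random.default_rng(rng.integers(2**31))

    def _dropout_layers(self) -> list[Dropout]:
        found = []

        def scan(layer):
            if isinstance(layer, Dropout):
                found.append(layer)
            elif isinstance(layer, Sequential):
                for sub in layer.layers:
                    scan(sub)

        for layer in self._all_layers():
            scan(layer)
        return found

    def _all_layers(self) -> list[Layer]:
        raise NotImplementedError

    # -- classifier contract -------------------------------------------
    def _prepare(self, windows: np.ndarray) -> tuple[np.ndarray, bool]:
        windows = np.asarray(windows, dtype=np.float32)
        single = windows.ndim == 3
        if single:
            windows = windows[None]
        if windows.ndim != 4:
            raise ValueError(
                f"expected (ns, H, W) or (B, ns, H, W) windows, got {windows.shape}"
            )
        if windows.shape[1] != self.spec.ns or windows.shape[2:] != (
            EYE_SIZE,
            EYE_SIZE,
        ):
            raise ValueError(
                f"window shape {windows.shape[1:]} incompatible with "
                f"({self.spec.ns}, {EYE_SIZE}, {EYE_SIZE})"
            )
        return windows[:, None], single  # add channel axis

    def predict_proba(self, windows: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Blink probability in [0, 1] per window (inference mode)."""
        x, single = self._prepare(windows)
        probs = np.empty(len(x))
        for lo in range(0, len(x), batch_size):
            logits = self.forward(x[lo : lo + batch_size], train=False)
            probs[lo : lo + batch_size] = softmax(logits)[:, 1]
        return float(probs[0]) if single else probs

    __call__ = predict_proba


def _encoder_blocks(spec: ClassifierSpec, rng) -> list[Sequential]:
    """The 4 conv blocks shared by cnn3d and ae3d (conv + ReLU + dropout).

    Shape chain for ns=12 (layout (C, D, H, W), D = time):
    (1,12,48,48) -> (16,6,24,24) -> (32,3,12,12) -> (32,3,12,12) -> (32,3,6,6)
    """
    k, p = (5, 5, 5), (2, 2, 2)
    dr = spec.dropout_rate
    return [
        Sequential(Conv3d(1, 16, k, (2, 2, 2), p, rng), ReLU(), Dropout(dr)),
        Sequential(Conv3d(16, 32, k, (2, 2, 2), p, rng), ReLU(), Dropout(dr)),
        Sequential(Conv3d(32, 32, k, (1, 1, 1), p, rng), ReLU(), Dropout(dr)),
        Sequential(Conv3d(32, 32, k, (1, 2, 2), p, rng), ReLU(), Dropout(dr)),
    ]


def _flat_units(spec: ClassifierSpec) -> int:
    return 32 * (spec.ns // 4) * (EYE_SIZE // 8) * (EYE_SIZE // 8)


def _head(spec: ClassifierSpec, in_units: int, rng) -> Sequential:
    """Fully-connected classifier: repeated (dense, ReLU, dropout) blocks
    ending in 2-way logits."""
    layers: list[Layer] = []
    prev = in_units
    for units in spec.head_units:
        layers += [Dense(prev, units, rng), ReLU(), Dropout(spec.dropout_rate)]
        prev = units
    layers.append(Dense(prev, 2, rng))
    return Sequential(*layers)


class Simple3DCNN(BaseModel):
    """3D conv encoder -> latent dense layer -> fully-connected head."""

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.rng_seed)
        blocks = _encoder_blocks(spec, rng)
        latent = Sequential(
            Flatten(), Dense(_flat_units(spec), spec.latent_units, rng), ReLU()
        )
        self.net = Sequential(*blocks, latent, _head(spec, spec.latent_units, rng))
        logger.info("built cnn3d with %d parameters", self.n_params())

    def _all_layers(self):
        return [self.net]

    def params(self):
        return self.net.params()

    def forward(self, x, train=False):
        return self.net.forward(np.asarray(x, np.float32) / 255.0, train=train)

    def backward(self, dlogits):
        self.net.backward(dlogits, need_input_grad=False)


class AutoEncoder3D(BaseModel):
    """Skip-connected 3D conv autoencoder with a classifier on the latent.

    Encoder and head are identical to :class:`Simple3DCNN`; the decoder
    mirrors the encoder with three transposed-conv blocks, concatenating
    the outputs of encoder blocks 4, 2 and 1 onto its inputs, and ends
    with a conv + clipped ReLU (ceiling 255) so reconstructions are
    valid 8-bit intensities.
    """

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.rng_seed)
        ns = spec.ns
        hq = EYE_SIZE // 4  # 12
        self.enc = _encoder_blocks(spec, rng)
        flat = _flat_units(spec)
        self.latent = Sequential(
            Flatten(), Dense(flat, spec.latent_units, rng), ReLU()
        )
        self.head = _head(spec, spec.latent_units, rng)
        k, p = (5, 5, 5), (2, 2, 2)
        self.dec_dense = Sequential(Dense(spec.latent_units, flat, rng), ReLU())
        self._bottleneck_shape = (32, ns // 4, EYE_SIZE // 8, EYE_SIZE // 8)
        # decoder inputs are [latent-features ++ skip], hence doubled channels
        self.dec1 = Sequential(
            ConvTranspose3d(64, 32, k, (1, 2, 2), p, (ns // 4, hq, hq), rng),
            ReLU(),
        )
        self.dec2 = Sequential(
            ConvTranspose3d(
                64, 32, k, (2, 2, 2), p, (ns // 2, EYE_SIZE // 2, EYE_SIZE // 2), rng
            ),
            ReLU(),
        )
        self.dec3 = Sequential(
            ConvTranspose3d(48, 16, k, (2, 2, 2), p, (ns, EYE_SIZE, EYE_SIZE), rng),
            ReLU(),
        )
        self.dec_out = Sequential(
            Conv3d(16, 1, k, (1, 1, 1), p, rng), ClippedReLU(255.0)
        )
        logger.info("built ae3d with %d parameters", self.n_params())

    def _all_layers(self):
        return [
            *self.enc, self.latent, self.head,
            self.dec_dense, self.dec1, self.dec2, self.dec3, self.dec_out,
        ]

    def params(self):
        return [p for layer in self._all_layers() for p in layer.params()]

    def encode(self, x, train=False):
        """Run the encoder; returns (block outputs e1..e4, latent vector)."""
        outs = []
        h = x
        for block in self.enc:
            h = block.forward(h, train=train)
            outs.append(h)
        z = self.latent.forward(h, train=train)
        return outs, z

    def forward_full(self, x, train=False):
        """Returns (logits, reconstruction); caches wiring for backward."""
        x = np.asarray(x, np.float32) / 255.0
        (e1, e2, e3, e4), z = self.encode(x, train)
        logits = self.head.forward(z, train=train)
        d0 = self.dec_dense.forward(z, train=train)
        d0 = d0.reshape(len(d0), *self._bottleneck_shape)
        d1 = self.dec1.forward(np.concatenate([d0, e4], axis=1), train=train)
        d2 = self.dec2.forward(np.concatenate([d1, e2], axis=1), train=train)
        d3 = self.dec3.forward(np.concatenate([d2, e1], axis=1), train=train)
        recon = self.dec_out.forward(d3, train=train)
        self._shapes = dict(
            d1_ch=d0.shape[1], d2_ch=d1.shape[1], d3_ch=d2.shape[1]
        )
        return logits, recon

    def forward(self, x, train=False):
        logits, _ = self.forward_full(x, train=train)
        return logits

    def backward(self, dlogits, drecon=None):
        """Backprop the weighted objective; pass voxel grads via ``drecon``."""
        dz = self.head.backward(dlogits, need_input_grad=True)
        if drecon is not None:
            dd3 = self.dec_out.backward(drecon, need_input_grad=True)
            dcat3 = self.dec3.backward(dd3, need_input_grad=True)
            c3 = self._shapes["d3_ch"]
            dd2, de1_skip = dcat3[:, :c3], dcat3[:, c3:]
            dcat2 = self.dec2.backward(dd2, need_input_grad=True)
            c2 = self._shapes["d2_ch"]
            dd1, de2_skip = dcat2[:, :c2], dcat2[:, c2:]
            dcat1 = self.dec1.backward(dd1, need_input_grad=True)
            c1 = self._shapes["d1_ch"]
            dd0, de4_skip = dcat1[:, :c1], dcat1[:, c1:]
            dz = dz + self.dec_dense.backward(dd0.reshape(len(dd0), -1), True)
        else:
            de1_skip = de2_skip = de4_skip = 0.0
        de4 = self.latent.backward(dz, need_input_grad=True) + de4_skip
        de3 = self.enc[3].backward(de4, need_input_grad=True)
        de2 = self.enc[2].backward(de3, need_input_grad=True) + de2_skip
        de1 = self.enc[1].backward(de2, need_input_grad=True) + de1_skip
        self.enc[0].backward(de1, need_input_grad=False)

    def reconstruct(self, windows: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Reconstruction of raw 0-255 windows, same shape, values in [0, 255]."""
        x, single = self._prepare(windows)
        out = np.empty_like(x)
        for lo in range(0, len(x), batch_size):
            _, rec = self.forward_full(x[lo : lo + batch_size, 0][:, None])
            out[lo : lo + batch_size] = rec
        return out[0, 0] if single else out[:, 0]


class _ResidualBlock(Layer):
    """y = ReLU(x + conv(x)) with an identity shortcut."""

    def __init__(self, channels: int, kernel, rng):
        pad = tuple(k // 2 for k in kernel)
        self.conv = Conv3d(channels, channels, kernel, (1, 1, 1), pad, rng)
        self.relu = ReLU()

    def forward(self, x, train=False):
        return self.relu.forward(x + self.conv.forward(x, train), train)

    def backward(self, grad, need_input_grad=True):
        g = self.relu.backward(grad)
        return g + self.conv.backward(g, need_input_grad=True)

    def params(self):
        return self.conv.params()


class ResNet3D(BaseModel):
    """Compact 3D residual classifier: stem conv + one stack of four
    64-filter residual blocks + global average pooling + 2-way head.

    The first block convolves over time and space (3x3x3); the rest are
    spatial (1x3x3), keeping the parameter count near 2e5.
    """

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.rng_seed)
        self.stem = Sequential(
            Conv3d(1, 64, (3, 5, 5), (2, 4, 4), (1, 2, 2), rng), ReLU()
        )
        self.blocks = Sequential(
            _ResidualBlock(64, (3, 3, 3), rng),
            _ResidualBlock(64, (1, 3, 3), rng),
            _ResidualBlock(64, (1, 3, 3), rng),
            _ResidualBlock(64, (1, 3, 3), rng),
        )
        self.fc = Dense(64, 2, rng)
        logger.info("built resnet3d with %d parameters", self.n_params())

    def _all_layers(self):
        return [self.stem, self.blocks, self.fc]

    def params(self):
        return self.stem.params() + self.blocks.params() + self.fc.params()

    def forward(self, x, train=False):
        h = self.stem.forward(np.asarray(x, np.float32) / 255.0, train=train)
        h = self.blocks.forward(h, train=train)
        self._pool_shape = h.shape
        pooled = h.mean(axis=(2, 3, 4))  # global average pool
        return self.fc.forward(pooled, train=train)

    def backward(self, dlogits):
        dpool = self.fc.backward(dlogits, need_input_grad=True)
        n_vox = int(np.prod(self._pool_shape[2:]))
        dh = np.broadcast_to(
            dpool[:, :, None, None, None] / n_vox, self._pool_shape
        ).astype(np.float32)
        dh = self.blocks.backward(dh, need_input_grad=True)
        self.stem.backward(dh, need_input_grad=False)


_BUILDERS = {"cnn3d": Simple3DCNN, "ae3d": AutoEncoder3D, "resnet3d": ResNet3D}


def build_model(spec: ClassifierSpec) -> BaseModel:
    """Instantiate the architecture named in ``spec``."""
    return _BUILDERS[spec.architecture](spec)


def build_simple_cnn3d(spec: ClassifierSpec | None = None) -> Simple3DCNN:
    spec = spec or ClassifierSpec(architecture="cnn3d")
    if spec.architecture != "cnn3d":
        raise ValueError(f"spec names {spec.architecture}, not cnn3d")
    return Simple3DCNN(spec)


def build_autoencoder3d(spec: ClassifierSpec | None = None) -> AutoEncoder3D:
    spec = spec or ClassifierSpec(architecture="ae3d")
    if spec.architecture != "ae3d":
        raise ValueError(f"spec names {spec.architecture}, not ae3d")
    return AutoEncoder3D(spec)


def build_resnet3d(spec: ClassifierSpec | None = None) -> ResNet3D:
    spec = spec or ClassifierSpec(architecture="resnet3d")
    if spec.architecture != "resnet3d":
        raise ValueError(f"spec names {spec.architecture}, not resnet3d")
    return ResNet3D(spec)
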