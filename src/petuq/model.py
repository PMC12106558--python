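"""Residual U-Net backbone for low-dose PET reconstruction.

The network maps a normalized low-dose slice to a predicted full-dose slice.
A three-level encoder (3x3 conv + leaky ReLU, 2x2 max pool) at widths
(32, 64, 128) feeds a single bottleneck block; the symmetric decoder
concatenates nearest-neighbour-upsampled features with the matching encoder
output. A final 1x1 convolution with tanh activation produces a bounded
residual that is added to the input, so an untrained head is the identity
map and the network only has to learn the noise correction.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from . import nn


@dataclass(frozen=True)
class Architecture:
    """Descriptor of the U-Net topology and activation settings."""

    widths: tuple[int, int, int] = (32, 64, 128)
    kernel: int = 3
    leaky_slope: float = 0.01
    dropout_p: float = 0.0
    dtype: str = "float32"

    def __post_init__(self):
        if any(w <= 0 for w in self.widths):
            raise ValueError("channel widths must be positive")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["widths"] = list(self.widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Architecture":
        d = dict(d)
        d["widths"] = tuple(d["widths"])
        return cls(**d)


class ReconModel(nn.Module):
    """The residual U-Net f_theta; operates on NHWC float tensors."""

    #: downsampling factor implied by the three pooling stages
    DOWN_FACTOR = 8
    #: smallest input side that leaves a 2x2 bottleneck
    MIN_SIDE = 16

    def __init__(self, arch: Architecture, seed: int = 0):
        super().__init__()
        self.arch = arch
        dt = np.dtype(arch.dtype)
        rng = np.random.default_rng(seed)
        w1, w2, w3 = arch.widths
        k = arch.kernel

        def conv_params(name, cin, cout, ksize):
            fan_in = cin * ksize * ksize
            std = np.sqrt(2.0 / fan_in)
            w = rng.normal(0.0, std, size=(cout, cin, ksize, ksize)).astype(dt)
            b = np.zeros(cout, dtype=dt)
            return self.register(f"{name}.w", w), self.register(f"{name}.b", b)

        self.enc1 = conv_params("enc1", 1, w1, k)
        self.enc2 = conv_params("enc2", w1, w2, k)
        self.enc3 = conv_params("enc3", w2, w3, k)
        self.bottleneck = conv_params("bottleneck", w3, w3, k)
        self.dec3 = conv_params("dec3", w3 + w3, w3, k)
        self.dec2 = conv_params("dec2", w3 + w2, w2, k)
        self.dec1 = conv_params("dec1", w2 + w1, w1, k)
        self.head = conv_params("head", w1, 1, 1)

    # -- forward ----------------------------------------------------------

    def forward(
        self,
        x: nn.Tensor,
        train_mode: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ) -> nn.Tensor:
        """Predict the full-dose image for a normalized NCHW input.

        ``train_mode`` enables dropout sampling (only meaningful when the
        architecture declares ``dropout_p > 0``); a generator must then be
        supplied so stochastic passes are reproducible.
        """
        p = self.arch.dropout_p
        use_drop = train_mode and p > 0.0
        if use_drop and dropout_rng is None:
            raise ValueError("dropout sampling requires a random generator")
        slope = self.arch.leaky_slope

        def block(t, params):
            t = nn.leaky_relu(nn.conv2d(t, *params), slope)
            if use_drop:
                t = nn.spatial_dropout(t, p, dropout_rng)
            return t

        e1 = block(x, self.enc1)
        e2 = block(nn.max_pool2(e1), self.enc2)
        e3 = block(nn.max_pool2(e2), self.enc3)
        bott = nn.leaky_relu(nn.conv2d(nn.max_pool2(e3), *self.bottleneck), slope)
        d3 = block(nn.concat(nn.upsample2(bott), e3), self.dec3)
        d2 = block(nn.concat(nn.upsample2(d3), e2), self.dec2)
        d1 = block(nn.concat(nn.upsample2(d2), e1), self.dec1)
        residual = nn.tanh(nn.conv2d(d1, *self.head))
        return nn.add(x, residual)

    # -- array convenience ------------------------------------------------

    def predict(
        self,
        ld: np.ndarray,
        train_mode: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Forward a single normalized 2-D image (handles shape padding)."""
        arr = np.asarray(ld, dtype=self.arch.dtype)
        if arr.ndim != 2:
            raise ValueError("predict expects a single 2-D image")
        padded, crop = pad_to_multiple(arr, self.DOWN_FACTOR, min_side=16)
        x = nn.Tensor(padded[None, :, :, None])
        with nn.no_grad(), nn.buffer_reuse():
            nn.reset_slots()
            if train_mode and self.arch.dropout_p > 0.0:
                y = self.forward(x, train_mode=True, dropout_rng=dropout_rng)
            else:
                y = self.forward(x, train_mode=False)
        # copy: the forward output lives in pooled scratch
        return y.data[0, :, :, 0][crop].copy()

    def predict_batch(
        self,
        lds: np.ndarray,
        train_mode: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Forward a stack of normalized 2-D images (n, H, W) in one pass."""
        arr = np.asarray(lds, dtype=self.arch.dtype)
        if arr.ndim != 3:
            raise ValueError("predict_batch expects a (n, H, W) stack")
        padded0, crop = pad_to_multiple(arr[0], self.DOWN_FACTOR, min_side=16)
        stack = np.empty((arr.shape[0],) + padded0.shape + (1,), dtype=arr.dtype)
        stack[0, :, :, 0] = padded0
        for i in range(1, arr.shape[0]):
            stack[i, :, :, 0] = pad_to_multiple(arr[i], self.DOWN_FACTOR, 16)[0]
        x = nn.Tensor(stack)
        with nn.no_grad(), nn.buffer_reuse():
            nn.reset_slots()
            if train_mode and self.arch.dropout_p > 0.0:
                y = self.forward(x, train_mode=True, dropout_rng=dropout_rng)
            else:
                y = self.forward(x, train_mode=False)
        return y.data[:, :, :, 0][:, crop[0], crop[1]].copy()


def pad_to_multiple(
    img: np.ndarray, m: int, min_side: int = 0
) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Zero-pad a 2-D image symmetrically so both sides divide ``m``.

    Sides are additionally padded up to ``min_side`` (the network needs a
    bottleneck of at least 2x2, i.e. 16-pixel inputs). Returns the padded
    image and the slices that crop back to the original.
    """
    h, w = img.shape
    if h < 2 or w < 2:
        raise ValueError("image too small to process")
    th = max(h + (-h) % m, min_side)
    tw = max(w + (-w) % m, min_side)
    ph, pw = th - h, tw - w
    top, left = ph // 2, pw // 2
    out = np.pad(img, ((top, ph - top), (left, pw - left)))
    return out, (slice(top, top + h), slice(left, left + w))


def build_model(arch: Architecture | None = None, seed: int = 0) -> ReconModel:
    """Construct a residual U-Net with deterministic initial weights."""
    return ReconModel(arch or Architecture(), seed=seed)
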