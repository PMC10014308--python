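"""U-Net assembled from the layer primitives.

Standard encoder-decoder topology: ``depth`` encoder levels of two 3x3
convolutions + ReLU, each followed by 2x max pooling and a doubling of the
filter count; a two-convolution bottleneck; a symmetric decoder of 2x
transposed-convolution upsampling, skip concatenation with the matching
encoder feature map, and two convolutions; a final 1x1 convolution to class
logits.  'Same' padding throughout, so the output spatial shape equals the
input's (complete up-convolutional expansion).  Spatial input dimensions
must be divisible by ``2**depth``; callers pad and crop.
"""

from __future__ import annotations

import numpy as np

from lfseg.nn.layers import ConvND, MaxPoolND, ReLU, UpConvND, softmax


class _DoubleConv:
    def __init__(self, c_in, c_out, ndim, rng, dtype):
        self.conv1 = ConvND(c_in, c_out, ndim, 3, rng, dtype)
        self.relu1 = ReLU()
        self.conv2 = ConvND(c_out, c_out, ndim, 3, rng, dtype)
        self.relu2 = ReLU()
        self.layers = [self.conv1, self.relu1, self.conv2, self.relu2]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, d):
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d


class UNet:
    """Three-class (by default) U-Net over 2D or 3D inputs.

    Parameters
    ----------
    ndim
        2 or 3 spatial dimensions.
    depth
        Number of encoder levels (pooling steps).
    base_filters
        Filter count of the first encoder level; doubled per level.
    """

    def __init__(
        self,
        ndim: int = 2,
        n_classes: int = 3,
        depth: int = 4,
        base_filters: int = 64,
        in_channels: int = 1,
        seed: int = 0,
        dtype=np.float32,
    ) -> None:
        if ndim not in (2, 3):
            raise ValueError(f"ndim must be 2 or 3, got {ndim}")
        self.ndim = ndim
        self.n_classes = n_classes
        self.depth = depth
        self.base_filters = base_filters
        self.in_channels = in_channels
        self.dtype = dtype
        rng = np.random.default_rng(seed)

        self.enc_blocks: list[_DoubleConv] = []
        self.pools: list[MaxPoolND] = []
        c = in_channels
        for d in range(depth):
            f = base_filters * 2**d
            self.enc_blocks.append(_DoubleConv(c, f, ndim, rng, dtype))
            self.pools.append(MaxPoolND())
            c = f
        f_bott = base_filters * 2**depth
        self.bottleneck = _DoubleConv(c, f_bott, ndim, rng, dtype)

        self.upconvs: list[UpConvND] = []
        self.dec_blocks: list[_DoubleConv] = []
        c = f_bott
        for d in reversed(range(depth)):
            f = base_filters * 2**d
            self.upconvs.append(UpConvND(c, f, ndim, rng, dtype))
            self.dec_blocks.append(_DoubleConv(2 * f, f, ndim, rng, dtype))
            c = f
        self.head = ConvND(c, n_classes, ndim, 1, rng, dtype)

    # -- structure ---------------------------------------------------------

    @property
    def encoder_filters(self) -> list[int]:
        return [self.base_filters * 2**d for d in range(self.depth)]

    @property
    def bottleneck_filters(self) -> int:
        return self.base_filters * 2**self.depth

    def layers(self):
        for block in self.enc_blocks:
            yield from block.layers
        yield from self.pools
        yield from self.bottleneck.layers
        for up, block in zip(self.upconvs, self.dec_blocks):
            yield up
            yield from block.layers
        yield self.head

    def parameter_arrays(self) -> list[tuple[object, str]]:
        """(layer, key) pairs addressing every trainable array."""
        out = []
        for layer in self.layers():
            for key in layer.params:
                out.append((layer, key))
        return out

    def n_parameters(self) -> int:
        return sum(layer.params[k].size for layer, k in self.parameter_arrays())

    # -- passes ------------------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits for a batch ``(B, in_channels, *spatial)``."""
        if x.ndim != self.ndim + 2:
            raise ValueError(
                f"expected batch of {self.ndim}D patches (B, C, *spatial), got shape {x.shape}"
            )
        for s in x.shape[2:]:
            if s % (2**self.depth) != 0:
                raise ValueError(
                    f"spatial dims must be divisible by 2**depth = {2 ** self.depth}, got {x.shape[2:]}"
                )
        x = x.astype(self.dtype, copy=False)
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = [s.shape[1] for s in skips]
        for up, block, skip in zip(self.upconvs, self.dec_blocks, reversed(skips)):
            x = up.forward(x)
            x = np.concatenate([skip, x], axis=1)
            x = block.forward(x)
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        # walk the decoder in reverse application order: shallowest level first
        d_skips = []  # gradient into each skip connection, shallow -> deep
        for up, block, f in zip(
            reversed(self.upconvs), reversed(self.dec_blocks), self._skip_channels
        ):
            d = block.backward(d)
            d_skip, d_up = d[:, :f], d[:, f:]
            d_skips.append(d_skip)
            d = up.backward(d_up)
        d = self.bottleneck.backward(d)
        for block, pool, d_skip in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(d_skips)
        ):
            d = pool.backward(d)
            d = block.backward(d + d_skip)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities for a batch."""
        return softmax(self.forward(x), axis=1)

    # -- (de)serialization -------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {
            f"p{i}_{key}": layer.params[key]
            for i, (layer, key) in enumerate(self.parameter_arrays())
        }

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, (layer, key) in enumerate(self.parameter_arrays()):
            arr = np.asarray(state[f"p{i}_{key}"])
            if arr.shape != layer.params[key].shape:
                raise ValueError(f"checkpoint shape mismatch for p{i}_{key}")
            layer.params[key] = arr.astype(self.dtype)
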