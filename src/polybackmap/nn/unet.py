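"""The 1-D U-net mapping (S, k+3) inputs to (S, 3) bond-vector predictions.

Encoder: five down-sample blocks (strided convolution -> leaky ReLU ->
batch normalization), filter counts doubling from ``base_filters`` and
capped at ``max_filters``.  Decoder: five up-sample blocks (transposed
convolution -> ReLU, dropout on the first), with skip connections
concatenating each encoder level onto the matching decoder level.  The
head is a stride-1 convolution to 3 channels with a tanh, matching the
[-1, 1] target scaling.

The kernel width, leaky-ReLU slope and concatenation merge are
implementation choices recorded in every checkpoint.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .layers import (BatchNorm1d, Conv1d, ConvTranspose1d, Dropout,
                     LeakyReLU, ReLU, Tanh)

__all__ = ["NetworkConfig", "UNet", "build_unet", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class NetworkConfig:
    depth: int = 5
    base_filters: int = 64
    max_filters: int = 512
    kernel_size: int = 4
    stride: int = 2
    dropout_rate: float = 0.5
    negative_slope: float = 0.2
    output_channels: int = 3

    def encoder_filters(self):
        return [min(self.base_filters * 2 ** i, self.max_filters)
                for i in range(self.depth)]

    def decoder_filters(self):
        enc = self.encoder_filters()
        return [enc[self.depth - 2 - i] if i < self.depth - 1 else enc[0]
                for i in range(self.depth)]


class UNet:
    """Encoder/decoder CNN with skip connections (see module docstring)."""

    def __init__(self, config: NetworkConfig, k: int, seed: int = 0):
        self.config = config
        self.k = k
        self.rng = np.random.default_rng(seed)
        c = config
        enc = c.encoder_filters()
        dec = c.decoder_filters()

        self.downs = []
        c_in = k + 3
        for f in enc:
            self.downs.append([
                Conv1d(c_in, f, c.kernel_size, c.stride, self.rng),
                LeakyReLU(c.negative_slope),
                BatchNorm1d(f),
            ])
            c_in = f

        self.ups = []
        c_in = enc[-1]
        for i, f in enumerate(dec):
            block = [ConvTranspose1d(c_in, f, c.kernel_size, c.stride, self.rng),
                     ReLU()]
            if i == 0:
                block.append(Dropout(c.dropout_rate, self.rng))
            self.ups.append(block)
            if i < c.depth - 1:
                c_in = f + enc[c.depth - 2 - i]
            else:
                c_in = f
        self.head = Conv1d(c_in, c.output_channels, c.kernel_size, 1, self.rng)
        self.out_act = Tanh()

    # ------------------------------------------------------------------
    def params(self):
        out = []
        for block in self.downs + self.ups:
            for layer in block:
                out += layer.params()
        out += self.head.params()
        return out

    def _layers(self):
        for block in self.downs + self.ups:
            yield from block
        yield self.head
        yield self.out_act

    def zero_grad(self):
        for p in self.params():
            p.zero_grad()

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Forward pass; input (B, S, k+3), output (B, S, 3) in (-1, 1)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 3 or x.shape[2] != self.k + 3:
            raise ValueError(f"expected input (B, S, {self.k + 3}), got {x.shape}")
        S = x.shape[1]
        if S % (self.config.stride ** self.config.depth) != 0:
            raise ValueError(f"input length {S} not divisible by "
                             f"stride^depth = {self.config.stride ** self.config.depth}")
        depth = self.config.depth
        skips = []
        h = x
        for block in self.downs:
            for layer in block:
                h = layer.forward(h, training)
            skips.append(h)
        self._skip_channels = [s.shape[2] for s in skips]
        for i, block in enumerate(self.ups):
            for layer in block:
                h = layer.forward(h, training)
            if i < depth - 1:
                h = np.concatenate([h, skips[depth - 2 - i]], axis=2)
        h = self.head.forward(h, training)
        return self.out_act.forward(h, training)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(output); returns d(loss)/d(input)."""
        depth = self.config.depth
        dec = self.config.decoder_filters()
        g = self.out_act.backward(gy)
        g = self.head.backward(g)
        skip_grads = [None] * depth
        for i in reversed(range(depth)):
            if i < depth - 1:
                g_h = g[..., :dec[i]]
                skip_grads[depth - 2 - i] = g[..., dec[i]:]
            else:
                g_h = g
            for layer in reversed(self.ups[i]):
                g_h = layer.backward(g_h)
            g = g_h
        for i in reversed(range(depth)):
            if skip_grads[i] is not None:
                g = g + skip_grads[i]
            for layer in reversed(self.downs[i]):
                g = layer.backward(g)
        return g

    # ------------------------------------------------------------------
    def state_arrays(self):
        out = []
        for layer in self._layers():
            out += layer.state_arrays()
        return out

    def load_state_arrays(self, arrays):
        pos = 0
        for layer in self._layers():
            n = len(layer.state_arrays())
            layer.load_state_arrays(arrays[pos:pos + n])
            pos += n
        if pos != len(arrays):
            raise ValueError("checkpoint array count mismatch")


def build_unet(config: NetworkConfig, k: int, seed: int = 0) -> UNet:
    """Construct a U-net for ``k`` monomer types (input width k+3)."""
    if config.stride < 2 or config.depth < 1:
        raise ValueError("invalid network config")
    return UNet(config, k, seed=seed)


REQUIRED_METADATA = ("scheme_version", "vector_scale", "cg_scale", "k", "composition")


def save_checkpoint(model: UNet, path, metadata: dict) -> None:
    """Write weights plus a JSON metadata block to one ``.npz`` archive."""
    missing = [key for key in REQUIRED_METADATA if key not in metadata]
    if missing:
        raise ValueError(f"checkpoint metadata missing required keys: {missing}")
    meta = dict(metadata)
    meta["network_config"] = asdict(model.config)
    meta["model_k"] = model.k
    arrays = {f"arr_{i:04d}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path, expect: dict | None = None):
    """Load a checkpoint; returns (model, metadata).

    ``expect`` may pin metadata entries (e.g. ``{"k": 4}``); any mismatch
    is rejected with a diagnostic.
    """
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = [data[f"arr_{i:04d}"]
                  for i in range(len(data.files) - 1)]
    if expect:
        for key, val in expect.items():
            if meta.get(key) != val:
                raise ValueError(f"checkpoint metadata mismatch for {key!r}: "
                                 f"have {meta.get(key)!r}, expected {val!r}")
    config = NetworkConfig(**meta["network_config"])
    model = UNet(config, meta["model_k"])
    model.load_state_arrays(arrays)
    return model, meta
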