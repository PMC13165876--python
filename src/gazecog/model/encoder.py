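"""Multi-scale parallel 1-D convolutional encoder.

Four parallel streams with kernel widths 3/5/7/9 see the same windowed
multichannel input; each applies conv -> ReLU -> max-pool -> conv -> ReLU ->
global average pooling, and the stream outputs (32, 64, 16, 32 channels) are
concatenated into a 144-dimensional instance embedding. Padding is symmetric
zeros preserving length before pooling.
"""

from __future__ import annotations

import numpy as np

from . import nn

#: (kernel1, pad1, out1, pool, kernel2, pad2, out2) per stream
STREAMS = [
    (3, 1, 16, 2, 3, 1, 32),
    (5, 2, 32, 4, 5, 2, 64),
    (7, 3, 8, 2, 3, 1, 16),
    (9, 4, 16, 3, 5, 2, 32),
]

#: concatenated embedding dimension (32 + 64 + 16 + 32)
EMBED_DIM = sum(s[-1] for s in STREAMS)


class MSPCNNEncoder:
    """The shared multi-scale instance encoder (pure NumPy)."""

    def __init__(self, in_channels: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.params: dict[str, np.ndarray] = {}
        for i, (k1, _, f1, _, k2, _, f2) in enumerate(STREAMS):
            self.params[f"s{i}_W1"] = nn.he_init(rng, (f1, in_channels, k1),
                                                 in_channels * k1)
            self.params[f"s{i}_b1"] = np.zeros(f1, dtype=nn.DTYPE)
            self.params[f"s{i}_W2"] = nn.he_init(rng, (f2, f1, k2), f1 * k2)
            self.params[f"s{i}_b2"] = np.zeros(f2, dtype=nn.DTYPE)

    def forward(self, x: np.ndarray):
        """x: (B, C, W) -> embeddings (B, 144) plus backward caches."""
        x = x.astype(nn.DTYPE, copy=False)
        outs, caches = [], []
        for i, (k1, p1, f1, pool, k2, p2, f2) in enumerate(STREAMS):
            h, c1 = nn.conv1d_forward(x, self.params[f"s{i}_W1"],
                                      self.params[f"s{i}_b1"], p1)
            h, r1 = nn.relu_forward(h)
            h, cp = nn.maxpool1d_forward(h, pool)
            h, c2 = nn.conv1d_forward(h, self.params[f"s{i}_W2"],
                                      self.params[f"s{i}_b2"], p2)
            h, r2 = nn.relu_forward(h)
            z, gshape = nn.gap_forward(h)
            outs.append(z)
            caches.append((c1, r1, cp, c2, r2, gshape))
        return np.concatenate(outs, axis=1), caches

    def backward(self, dz: np.ndarray, caches) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        off = 0
        for i, (_, _, _, _, _, _, f2) in enumerate(STREAMS):
            c1, r1, cp, c2, r2, gshape = caches[i]
            d = nn.gap_backward(dz[:, off:off + f2], gshape)
            off += f2
            d = nn.relu_backward(d, r2)
            d, grads[f"s{i}_W2"], grads[f"s{i}_b2"] = nn.conv1d_backward(d, c2)
            d = nn.maxpool1d_backward(d, cp)
            d = nn.relu_backward(d, r1)
            _, grads[f"s{i}_W1"], grads[f"s{i}_b1"] = nn.conv1d_backward(d, c1)
        return grads

    def encode(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        """Inference-only embedding of many instances."""
        outs = [self.forward(x[i:i + batch])[0] for i in range(0, len(x), batch)]
        return np.concatenate(outs, axis=0) if outs else np.zeros((0, EMBED_DIM))


class MLPHead:
    """Instance-level classification head: 144 -> 64 -> 2."""

    def __init__(self, rng: np.random.Generator, in_dim: int = EMBED_DIM,
                 hidden: int = 64, n_classes: int = 2):
        self.params = {
            "W1": nn.he_init(rng, (hidden, in_dim), in_dim),
            "b1": np.zeros(hidden, dtype=nn.DTYPE),
            "W2": nn.he_init(rng, (n_classes, hidden), hidden),
            "b2": np.zeros(n_classes, dtype=nn.DTYPE),
        }

    def forward(self, z: np.ndarray):
        h, c1 = nn.linear_forward(z.astype(nn.DTYPE, copy=False),
                                  self.params["W1"], self.params["b1"])
        h, r = nn.relu_forward(h)
        logits, c2 = nn.linear_forward(h, self.params["W2"], self.params["b2"])
        return logits, (c1, r, c2)

    def backward(self, dlogits: np.ndarray, cache):
        c1, r, c2 = cache
        d, dW2, db2 = nn.linear_backward(dlogits, c2)
        d = nn.relu_backward(d, r)
        dz, dW1, db1 = nn.linear_backward(d, c1)
        return dz, {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2}
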