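"""Dynamic residual fusion of the two modal embeddings.

The image and tabular embeddings (each length L) are channel-interleaved
into O (length 2L, image at even indices, tabular at odd), passed through a
single-channel 1-D convolution with a residual connection, and combined with
an image-residual branch under softmax-constrained weights:

    m = w1 * (Conv(O) + O) + w2 * lift(f_i),    w1 + w2 = 1,

where lift(f_i) interleaves the image embedding with itself so its entries
align with O's even (image) channels.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Parameter, Tensor, cat

__all__ = ["cross_concat", "normalize_weights", "DynamicResidualFusion"]


def cross_concat(a: Tensor, b: Tensor) -> Tensor:
    """Channel interleaving: out[..., 0::2] = a, out[..., 1::2] = b."""
    if a.shape != b.shape:
        raise ValueError(f"cannot interleave shapes {a.shape} and {b.shape}")
    stacked = cat([a.expand_dims(-1), b.expand_dims(-1)], axis=a.ndim)
    return stacked.reshape(*a.shape[:-1], 2 * a.shape[-1])


def de_interleave(o: Tensor | np.ndarray) -> tuple:
    """Inverse of :func:`cross_concat` (even channels, odd channels)."""
    if isinstance(o, Tensor):
        return o[..., 0::2], o[..., 1::2]
    return o[..., 0::2], o[..., 1::2]


def normalize_weights(raw: Tensor) -> Tensor:
    """Two unconstrained logits -> convex weights (w1, w2) via softmax."""
    return raw.softmax(axis=-1)


class DynamicResidualFusion:
    """Trainable fusion: interleave, 1-D conv residual, weighted combination."""

    def __init__(self, rng: np.random.Generator, kernel_size: int = 3,
                 init_logits: tuple[float, float] = (0.0, 0.0)):
        if kernel_size % 2 == 0:
            raise ValueError("fusion kernel length must be odd")
        self.kernel_size = kernel_size
        self.kernel = Parameter(rng.normal(0.0, 0.1, size=kernel_size))
        self.bias = Parameter(np.zeros(1))
        self.logits = Parameter(np.array(init_logits, dtype=float))

    def weights(self) -> Tensor:
        return normalize_weights(self.logits)

    def conv1d_same(self, o: Tensor) -> Tensor:
        """Single-channel 1-D convolution with zero 'same' padding over the
        interleaved axis, expressed as a sum of shifted slices."""
        n, length = o.shape
        half = self.kernel_size // 2
        zeros_shape = None
        terms = []
        for tap in range(self.kernel_size):
            shift = tap - half  # contribution of o[j + shift] to output j
            if shift < 0:
                piece = o[:, : length + shift]
                padded = cat([Tensor(np.zeros((n, -shift))), piece], axis=1)
            elif shift > 0:
                piece = o[:, shift:]
                padded = cat([piece, Tensor(np.zeros((n, shift)))], axis=1)
            else:
                padded = o
            terms.append(padded * self.kernel[tap])
        out = terms[0]
        for t in terms[1:]:
            out = out + t
        return out + self.bias

    def fuse(self, f_i: Tensor, f_t: Tensor) -> Tensor:
        """(N, L) x (N, L) -> fused (N, 2L)."""
        o = cross_concat(f_i, f_t)
        branch = self.conv1d_same(o) + o
        image_lift = cross_concat(f_i, f_i)
        w = self.weights()
        return w[0] * branch + w[1] * image_lift

    __call__ = fuse

    def parameters(self) -> list[Parameter]:
        return [self.kernel, self.bias, self.logits]
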