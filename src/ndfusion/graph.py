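"""Adaptive cohort graph: thresholded cosine affinity + GCN classification.

Fused patient embeddings become graph nodes.  An affine map followed by
row-wise L2 normalization yields unit vectors whose Gram matrix W is the
cosine affinity; hard thresholding W at 0.95 gives the binary adjacency A
(self-loops are automatic since every row has cosine 1 with itself).  A
two-layer GCN with symmetric degree normalization classifies the nodes; the
logits are rescaled by trainable (alpha2, beta2) before the softmax.

The threshold is non-differentiable: within a forward pass the adjacency is
a constant and gradients flow through the node-feature path only.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Parameter, Tensor

__all__ = ["affine_normalize", "build_affinity", "threshold_adjacency",
           "to_edge_list", "normalized_adjacency", "GCNHead", "DEFAULT_THRESHOLD"]

DEFAULT_THRESHOLD = 0.95


def affine_normalize(m: Tensor, alpha1: Tensor | float, beta1: Tensor | float) -> Tensor:
    """Row-wise L2 normalization of alpha1 * m + beta1 (rows -> unit norm)."""
    z = m * alpha1 + beta1
    norms = ((z ** 2).sum(axis=1, keepdims=True)) ** 0.5
    if np.any(norms.data == 0):
        raise ValueError("degenerate embedding: a row of alpha1*m + beta1 is all zero")
    return z / norms


def build_affinity(n_matrix: Tensor) -> Tensor:
    """Cosine affinity W = N N^T of row-normalized features."""
    return n_matrix @ n_matrix.T


def threshold_adjacency(w: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Binary adjacency: A_ij = 1 iff W_ij >= threshold (boundary inclusive)."""
    w = np.asarray(w)
    return (w >= threshold).astype(np.int64)


def to_edge_list(a: np.ndarray) -> np.ndarray:
    """Edge index list of all (i, j) with A_ij = 1, in row-major order."""
    rows, cols = np.nonzero(np.asarray(a))
    return np.stack([rows, cols], axis=1)


def normalized_adjacency(edges: np.ndarray, n: int) -> np.ndarray:
    """Symmetric degree-normalized adjacency D^{-1/2} A D^{-1/2} from edges."""
    a = np.zeros((n, n))
    if len(edges):
        if edges.max() >= n or edges.min() < 0:
            raise ValueError("edge index out of range for the node count")
        a[edges[:, 0], edges[:, 1]] = 1.0
    deg = a.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv = 1.0 / np.sqrt(deg)
    dinv[~np.isfinite(dinv)] = 0.0
    return a * dinv[:, None] * dinv[None, :]


class GCNHead:
    """Affinity construction + multi-layer GCN + scaled softmax output."""

    def __init__(self, rng: np.random.Generator, in_dim: int,
                 hidden: int = 32, n_classes: int = 2, n_layers: int = 2,
                 threshold: float = DEFAULT_THRESHOLD):
        self.threshold = threshold
        widths = [in_dim] + [hidden] * (n_layers - 1) + [n_classes]
        self.weights = [
            Parameter(rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b)))
            for a, b in zip(widths[:-1], widths[1:])
        ]
        self.biases = [Parameter(np.zeros(b)) for b in widths[1:]]
        self.alpha1 = Parameter(np.array(1.0))
        self.beta1 = Parameter(np.array(0.0))
        self.alpha2 = Parameter(np.array(1.0))
        self.beta2 = Parameter(np.array(0.0))

    def build_graph(self, m: Tensor) -> tuple[Tensor, np.ndarray, np.ndarray]:
        """Return (W affinity [differentiable], A binary, E edge list)."""
        n_matrix = affine_normalize(m, self.alpha1, self.beta1)
        w = build_affinity(n_matrix)
        a = threshold_adjacency(w.data, self.threshold)
        return w, a, to_edge_list(a)

    def gcn(self, m: Tensor, edges: np.ndarray) -> Tensor:
        """Message passing on the node features; adjacency held constant."""
        n = m.shape[0]
        ahat = Tensor(normalized_adjacency(edges, n))
        h = m
        for i, (wgt, b) in enumerate(zip(self.weights, self.biases)):
            h = ahat @ h @ wgt + b
            if i < len(self.weights) - 1:
                h = h.silu()
        return h

    def __call__(self, m: Tensor) -> tuple[Tensor, Tensor, np.ndarray]:
        """Classify nodes: returns (probabilities (N,2), W, A)."""
        w, a, edges = self.build_graph(m)
        logits = self.alpha2 * self.gcn(m, edges) + self.beta2
        return logits.softmax(axis=1), w, a

    def parameters(self) -> list[Parameter]:
        return (self.weights + self.biases
                + [self.alpha1, self.beta1, self.alpha2, self.beta2])


class DenseHead:
    """FC classification head replacing the graph module (ablation)."""

    def __init__(self, rng: np.random.Generator, in_dim: int,
                 hidden: int = 32, n_classes: int = 2):
        self.w1 = Parameter(rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, hidden)))
        self.b1 = Parameter(np.zeros(hidden))
        self.w2 = Parameter(rng.normal(0.0, np.sqrt(2.0 / hidden), size=(hidden, n_classes)))
        self.b2 = Parameter(np.zeros(n_classes))

    def __call__(self, m: Tensor) -> Tensor:
        h = (m @ self.w1 + self.b1).silu()
        return (h @ self.w2 + self.b2).softmax(axis=1)

    def parameters(self) -> list[Parameter]:
        return [self.w1, self.b1, self.w2, self.b2]
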