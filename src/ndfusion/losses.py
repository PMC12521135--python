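"""The three training objectives and their weighted combination.

* CSDM (cosine-similarity distribution matching): KL divergence between the
  softmax-over-cohort cross-modal cosine similarity distributions and the
  one-hot matching target (sample i's image pairs with sample i's record),
  averaged over both directions.
* GE (graph-edge) loss: Frobenius distance between the predicted adjacency
  and the label-derived block adjacency.  During training it is evaluated on
  the pre-threshold affinity (clamped to [0, 1]) so it stays differentiable;
  at evaluation it can be reported on the binary adjacency.
* CE: standard cross-entropy on the softmax class probabilities.

Total = lambda1 * CSDM + lambda2 * GE + lambda3 * CE with default weights
(0.2, 0.4, 0.4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor

__all__ = ["LossWeights", "csdm_loss", "build_label_adjacency", "ge_loss",
           "ce_loss", "total_loss"]

#: Smoothing added to the one-hot target inside the logarithm (an exact
#: one-hot target makes the KL divergence infinite).
CSDM_EPSILON = 1e-8
#: Default softmax temperature for the similarity distributions.
DEFAULT_TAU = 0.02
#: Floor for predicted probabilities inside the cross-entropy log.
CE_CLIP = 1e-12


@dataclass(frozen=True)
class LossWeights:
    """Non-negative weights of the three loss terms."""

    lambda1: float = 0.2   # CSDM
    lambda2: float = 0.4   # GE
    lambda3: float = 0.4   # CE

    def __post_init__(self) -> None:
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("loss weights must be non-negative")


def _row_normalize(x: Tensor) -> Tensor:
    norms = ((x ** 2).sum(axis=1, keepdims=True)) ** 0.5
    return x / (norms + 1e-12)


def csdm_loss(f_img: Tensor, f_tab: Tensor, tau: float = DEFAULT_TAU,
              epsilon: float = CSDM_EPSILON) -> Tensor:
    """Cross-modal similarity-distribution-matching loss.

    ``p_i2t`` row i is the softmax over j of cos(f_img_i, f_tab_j)/tau;
    the target q is the identity pattern smoothed by ``epsilon`` inside the
    log.  Returns (1/2n) * sum_i [KL(p_i2t_i || q_i) + KL(p_t2i_i || q_i)].
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    n = f_img.shape[0]
    if f_tab.shape[0] != n:
        raise ValueError("modal feature batches differ in size")
    if n == 1:
        warnings.warn("CSDM loss is degenerate for a single sample; returning 0")
        return Tensor(0.0)
    ni = _row_normalize(f_img)
    nt = _row_normalize(f_tab)
    sim = (ni @ nt.T) * (1.0 / tau)        # (n, n) cosine / tau
    q = Tensor(np.eye(n) + epsilon)

    def _kl(p: Tensor) -> Tensor:
        return (p * (p.log() - q.log())).sum()

    p_i2t = sim.softmax(axis=1)
    p_t2i = sim.T.softmax(axis=1)
    return (_kl(p_i2t) + _kl(p_t2i)) * (1.0 / (2 * n))


def build_label_adjacency(y: np.ndarray) -> np.ndarray:
    """Ground-truth adjacency: A*_ij = 1 iff y_i == y_j (block by class)."""
    y = np.asarray(y).reshape(-1)
    return (y[:, None] == y[None, :]).astype(np.float64)


def ge_loss(a_pred: Tensor | np.ndarray, a_true: np.ndarray) -> Tensor:
    """Frobenius distance ||A - A*||_F between predicted and label adjacency."""
    a_pred = a_pred if isinstance(a_pred, Tensor) else Tensor(np.asarray(a_pred, float))
    a_true = np.asarray(a_true, dtype=np.float64)
    if a_pred.shape != a_true.shape:
        raise ValueError(f"adjacency shapes differ: {a_pred.shape} vs {a_true.shape}")
    diff = a_pred - Tensor(a_true)
    return (((diff ** 2).sum()) + 1e-24) ** 0.5


def ce_loss(y_hat: Tensor, y: np.ndarray, clip: float = CE_CLIP) -> Tensor:
    """Mean negative log-probability of the true class.

    ``y_hat`` holds per-class probabilities (rows sum to 1); probabilities
    are floored at ``clip`` inside the log.
    """
    y = np.asarray(y).astype(int).reshape(-1)
    n, k = y_hat.shape
    if len(y) != n:
        raise ValueError("label count does not match prediction rows")
    if not np.allclose(y_hat.data.sum(axis=1), 1.0, atol=1e-5):
        raise ValueError("prediction rows must sum to 1")
    onehot = np.zeros((n, k))
    onehot[np.arange(n), y] = 1.0
    p_true = (y_hat * Tensor(onehot)).sum(axis=1)
    # clip via max(p, clip) expressed with a constant mask (clip only ever
    # binds where p is numerically zero, where no useful gradient exists)
    mask = p_true.data < clip
    if mask.any():
        p_true = p_true * Tensor((~mask).astype(float)) + Tensor(mask * clip)
    return -(p_true.log().mean())


def total_loss(l_csdm: Tensor | float, l_ge: Tensor | float, l_ce: Tensor | float,
               weights: LossWeights = LossWeights()) -> Tensor:
    """Weighted sum lambda1*CSDM + lambda2*GE + lambda3*CE."""
    l_csdm = l_csdm if isinstance(l_csdm, Tensor) else Tensor(l_csdm)
    l_ge = l_ge if isinstance(l_ge, Tensor) else Tensor(l_ge)
    l_ce = l_ce if isinstance(l_ce, Tensor) else Tensor(l_ce)
    return l_csdm * weights.lambda1 + l_ge * weights.lambda2 + l_ce * weights.lambda3
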