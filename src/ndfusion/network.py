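"""End-to-end multimodal graph network.

Assembles the three stages — feature processing, dynamic residual fusion,
adaptive-graph classification — plus the ablation variants used to probe
each stage's contribution:

* ``use_refiners=False``  : plain CNN/FC encoders (no state-space blocks);
* ``use_fusion=False``    : direct concatenation [f_i, f_t] instead of DRF;
* ``use_graph=False``     : FC head instead of the cohort graph;
* ``modality='image'/'tabular'`` : single-modality input masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Parameter, Tensor, cat
from .encoders import EncoderConfig, FeatureProcessor
from .fusion import DynamicResidualFusion, cross_concat
from .graph import DEFAULT_THRESHOLD, DenseHead, GCNHead
from .losses import (LossWeights, build_label_adjacency, ce_loss, csdm_loss,
                     ge_loss, total_loss, DEFAULT_TAU)

__all__ = ["ModelConfig", "MultimodalGraphNet"]


@dataclass
class ModelConfig:
    """Model hyperparameters (architecture + loss)."""

    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    fusion_kernel: int = 3
    fusion_init_logits: tuple[float, float] = (0.0, 0.0)
    graph_threshold: float = DEFAULT_THRESHOLD
    graph_hidden: int = 32
    graph_layers: int = 2
    loss_weights: LossWeights = field(default_factory=LossWeights)
    tau: float = DEFAULT_TAU
    ge_on_binary: bool = False   # training default: differentiable GE on W
    # ablation switches
    use_refiners: bool = True
    use_fusion: bool = True
    use_graph: bool = True
    modality: str = "both"       # "both" | "image" | "tabular"

    def __post_init__(self) -> None:
        if self.modality not in ("both", "image", "tabular"):
            raise ValueError("modality must be 'both', 'image' or 'tabular'")


def _clamp01(w: Tensor) -> Tensor:
    """Clamp to [0, 1]; gradient is zero outside the interval (hard clamp)."""
    inside = ((w.data > 0.0) & (w.data < 1.0)).astype(float)
    const = (w.data >= 1.0).astype(float)
    return w * Tensor(inside) + Tensor(const)


class MultimodalGraphNet:
    """The full classifier; forward passes run over a cohort/batch at once
    because the graph stage couples samples."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = cfg = config or ModelConfig()
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
        self.processor = FeatureProcessor(cfg.encoder, rng, use_refiners=cfg.use_refiners)
        self.fusion = DynamicResidualFusion(rng, cfg.fusion_kernel, cfg.fusion_init_logits)
        fused_dim = 2 * cfg.encoder.embed_dim
        if cfg.use_graph:
            self.head = GCNHead(rng, fused_dim, cfg.graph_hidden,
                                n_layers=cfg.graph_layers, threshold=cfg.graph_threshold)
        else:
            self.head = DenseHead(rng, fused_dim, cfg.graph_hidden)

    # -- forward ---------------------------------------------------------------
    def forward(self, volumes: np.ndarray | None, tabular: np.ndarray | None) -> dict:
        """Run the network on a batch.

        Returns a dict with ``probs`` (N, 2) plus the intermediates needed by
        the losses: ``f_i``, ``f_t``, ``W``, ``A``.
        """
        cfg = self.config
        vol_t = Tensor(volumes) if (volumes is not None and cfg.modality != "tabular") else None
        tab_t = Tensor(tabular) if (tabular is not None and cfg.modality != "image") else None
        if vol_t is None and tab_t is None:
            raise ValueError("at least one modality must be provided")
        f_i, f_t = self.processor.extract(vol_t, tab_t)

        if f_i is not None and f_t is not None:
            if cfg.use_fusion:
                m = self.fusion(f_i, f_t)
            else:
                m = cat([f_i, f_t], axis=1)   # direct concatenation ablation
        else:
            f = f_i if f_i is not None else f_t
            m = cross_concat(f, f)            # lift single modality to 2L

        out = {"f_i": f_i, "f_t": f_t, "m": m}
        if cfg.use_graph:
            probs, w, a = self.head(m)
            out.update(probs=probs, W=w, A=a)
        else:
            out.update(probs=self.head(m), W=None, A=None)
        return out

    def losses(self, out: dict, labels: np.ndarray, eval_mode: bool = False) -> dict:
        """Compute the three loss terms and their weighted total."""
        cfg = self.config
        n = len(labels)
        if out["f_i"] is not None and out["f_t"] is not None and n > 1:
            l_csdm = csdm_loss(out["f_i"], out["f_t"], tau=cfg.tau)
        else:
            l_csdm = Tensor(0.0)
        if out["W"] is not None:
            a_true = build_label_adjacency(labels)
            if cfg.ge_on_binary or eval_mode:
                l_ge = ge_loss(np.asarray(out["A"], float), a_true)
            else:
                l_ge = ge_loss(_clamp01(out["W"]), a_true)
            # scale-free: normalize by n so batch and cohort graphs compare
            l_ge = l_ge * (1.0 / n)
        else:
            l_ge = Tensor(0.0)
        l_ce = ce_loss(out["probs"], labels)
        return {
            "csdm": l_csdm, "ge": l_ge, "ce": l_ce,
            "total": total_loss(l_csdm, l_ge, l_ce, cfg.loss_weights),
        }

    def predict_proba(self, volumes: np.ndarray | None, tabular: np.ndarray | None
                      ) -> np.ndarray:
        """Positive-class probabilities for an evaluation cohort (graph built
        over that cohort)."""
        return self.forward(volumes, tabular)["probs"].data[:, 1].copy()

    # -- parameters ------------------------------------------------------------
    def parameters(self) -> list[Parameter]:
        params = self.processor.parameters()
        if self.config.use_fusion and self.config.modality == "both":
            params += self.fusion.parameters()
        params += self.head.parameters()
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state does not match the parameter list")
        for p, arr in zip(params, state):
            if p.data.shape != np.asarray(arr).shape:
                raise ValueError("parameter shape mismatch in state")
            p.data = np.asarray(arr, dtype=np.float64).copy()
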