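"""Multi-modal feature processing: per-modality encoders + state-space refiners.

Each modality is first embedded (3-D CNN for the image volume, FC stack for
the 4-variable clinical vector) and then refined by a selective state-space
sequence block, i.e. f_theta(x) = SSM_theta(Encoder_theta(x)) with separate
parameters per modality.  The embedding length L is shared across modalities
so downstream fusion can interleave them channel-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Parameter, Tensor, conv3d, maxpool3d

__all__ = ["EncoderConfig", "ImageEncoder", "TabularEncoder", "SSMBlock",
           "FeatureProcessor"]


@dataclass
class EncoderConfig:
    """Architecture hyperparameters for both encoders and the SSM refiners.

    Defaults target full-resolution volumes (20 x 256 x 256); tests use
    smaller volumes with fewer stages.
    """

    embed_dim: int = 64
    image_channels: tuple[int, ...] = (8, 16, 32, 64)
    kernel_size: int = 3
    pool_factor: int = 2
    groupnorm_groups: int = 4
    tabular_hidden: tuple[int, ...] = (32,)
    tabular_in: int = 4
    ssm_token_dim: int = 8
    ssm_state_dim: int = 4

    def __post_init__(self) -> None:
        if self.embed_dim % self.ssm_token_dim != 0:
            raise ValueError("embed_dim must be divisible by ssm_token_dim")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.w = Parameter(_kaiming(rng, (n_in, n_out), n_in))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]


class GroupNorm:
    """Group normalization over (channel-group, spatial) per sample."""

    def __init__(self, channels: int, groups: int, eps: float = 1e-5):
        if channels % groups != 0:
            groups = 1
        self.groups, self.eps = groups, eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))

    def __call__(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        spatial = x.shape[2:]
        g = self.groups
        xg = x.reshape(n, g, c // g, *spatial)
        axes = tuple(range(2, xg.ndim))
        mu = xg.mean(axis=axes, keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=axes, keepdims=True)
        xn = (xg - mu) / ((var + self.eps) ** 0.5)
        xn = xn.reshape(n, c, *spatial)
        shape = (1, c) + (1,) * len(spatial)
        return xn * self.gamma.reshape(shape) + self.beta.reshape(shape)

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]


class ImageEncoder:
    """Stacked 3-D conv stages (conv -> group norm -> SiLU -> max pool),
    global average pooling, and a linear projection to the embedding."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        k = config.kernel_size
        self.convs: list[tuple[Parameter, Parameter]] = []
        self.norms: list[GroupNorm] = []
        c_in = 1
        for c_out in config.image_channels:
            w = Parameter(_kaiming(rng, (c_out, c_in, k, k, k), c_in * k ** 3))
            b = Parameter(np.zeros(c_out))
            self.convs.append((w, b))
            self.norms.append(GroupNorm(c_out, config.groupnorm_groups))
            c_in = c_out
        self.proj = Linear(rng, c_in, config.embed_dim)

    def __call__(self, volumes: Tensor) -> Tensor:
        """volumes: (N, D, H, W) -> embeddings (N, L)."""
        x = volumes.reshape(volumes.shape[0], 1, *volumes.shape[1:])
        pad = self.config.kernel_size // 2
        for stage, ((w, b), norm) in enumerate(zip(self.convs, self.norms)):
            try:
                x = conv3d(x, w, b, padding=pad)
                x = norm(x).silu()
                x = maxpool3d(x, self.config.pool_factor)
            except ValueError as err:
                raise ValueError(f"image encoder stage {stage}: {err}") from err
        x = x.mean(axis=(2, 3, 4))  # global average pool -> (N, C)
        return self.proj(x)

    def parameters(self) -> list[Parameter]:
        params = []
        for (w, b), norm in zip(self.convs, self.norms):
            params += [w, b] + norm.parameters()
        return params + self.proj.parameters()


class TabularEncoder:
    """FC stack mapping the 4 selected clinical variables to the embedding."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        widths = (config.tabular_in,) + tuple(config.tabular_hidden) + (config.embed_dim,)
        self.layers = [Linear(rng, a, b) for a, b in zip(widths[:-1], widths[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.config.tabular_in:
            raise ValueError(
                f"expected {self.config.tabular_in} tabular features, got {x.shape[-1]}"
            )
        for layer in self.layers[:-1]:
            x = layer(x).silu()
        return self.layers[-1](x)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]


class SSMBlock:
    """Selective state-space refiner with a gated residual.

    The length-L embedding is reshaped into T = L/d tokens of width d and run
    through a discretized input-dependent linear recurrence (per channel c,
    state size S):

        dt_t   = softplus(x_t W_dt + b_dt)                (N, d)
        B_t    = x_t W_B,  C_t = x_t W_C                  (N, S)
        h_t    = exp(dt_t[c] * A[c]) * h_{t-1} + dt_t[c] * B_t * x_t[c]
        y_t[c] = <C_t, h_t[c]> + D[c] * x_t[c]

    with A[c] < 0 (parameterized as -exp(A_log)).  The output is
    x + sigmoid(g) * y per channel, so zero selective parameters leave the
    embedding unchanged.
    """

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        d, s = config.ssm_token_dim, config.ssm_state_dim
        self.config = config
        self.a_log = Parameter(np.log(np.tile(np.arange(1, s + 1, dtype=float), (d, 1))))
        self.w_dt = Parameter(_kaiming(rng, (d, d), d) * 0.1)
        self.b_dt = Parameter(np.zeros(d))
        self.w_b = Parameter(_kaiming(rng, (d, s), d) * 0.1)
        self.w_c = Parameter(_kaiming(rng, (d, s), d) * 0.1)
        self.d_skip = Parameter(np.zeros(d))
        self.gate = Parameter(np.zeros(d))

    def __call__(self, embedding: Tensor) -> Tensor:
        if not np.all(np.isfinite(embedding.data)):
            raise ValueError("non-finite embedding passed to the SSM refiner")
        cfg = self.config
        n = embedding.shape[0]
        d, s = cfg.ssm_token_dim, cfg.ssm_state_dim
        t_len = embedding.shape[1] // d
        if t_len * d != embedding.shape[1]:
            raise ValueError("embedding length not divisible by the token width")
        x = embedding.reshape(n, t_len, d)

        a = -self.a_log.exp()                      # (d, S), strictly negative
        h = Tensor(np.zeros((n, d, s)))
        ys = []
        for t in range(t_len):
            xt = x[:, t, :]                        # (N, d)
            dt = (xt @ self.w_dt + self.b_dt).softplus()      # (N, d)
            bt = xt @ self.w_b                     # (N, S)
            ct = xt @ self.w_c                     # (N, S)
            dte = dt.reshape(n, d, 1)
            abar = (dte * a.reshape(1, d, s)).exp()           # (N, d, S)
            h = abar * h + dte * bt.reshape(n, 1, s) * xt.reshape(n, d, 1)
            yt = (h * ct.reshape(n, 1, s)).sum(axis=2) + self.d_skip * xt
            ys.append(yt.reshape(n, 1, d))
        y = ys[0] if t_len == 1 else _cat_tokens(ys)
        out = x + self.gate.sigmoid() * y
        return out.reshape(n, t_len * d)

    def parameters(self) -> list[Parameter]:
        return [self.a_log, self.w_dt, self.b_dt, self.w_b, self.w_c,
                self.d_skip, self.gate]


def _cat_tokens(ys):
    from ._autodiff import cat
    return cat(ys, axis=1)


class FeatureProcessor:
    """The full feature-processing stage: both encoders + both refiners.

    ``use_refiners=False`` drops the state-space blocks (the plain-encoder
    ablation).
    """

    def __init__(self, config: EncoderConfig, rng: np.random.Generator,
                 use_refiners: bool = True):
        self.config = config
        self.use_refiners = use_refiners
        self.image_encoder = ImageEncoder(config, rng)
        self.tabular_encoder = TabularEncoder(config, rng)
        self.image_refiner = SSMBlock(config, rng)
        self.tabular_refiner = SSMBlock(config, rng)

    def extract(self, volumes: Tensor | None, tabular: Tensor | None
                ) -> tuple[Tensor | None, Tensor | None]:
        """Return (f_i, f_t); either input may be None under a modality mask."""
        f_i = f_t = None
        if volumes is not None:
            f_i = self.image_encoder(volumes)
            if self.use_refiners:
                f_i = self.image_refiner(f_i)
        if tabular is not None:
            f_t = self.tabular_encoder(tabular)
            if self.use_refiners:
                f_t = self.tabular_refiner(f_t)
        return f_i, f_t

    def parameters(self) -> list[Parameter]:
        params = self.image_encoder.parameters() + self.tabular_encoder.parameters()
        if self.use_refiners:
            params += self.image_refiner.parameters() + self.tabular_refiner.parameters()
        return params
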