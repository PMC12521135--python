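"""Synthetic multimodal stroke cohorts.

Real cohorts of pontine infarction with paired DWI volumes and clinical
records are hospital-proprietary, so this module generates surrogate cohorts
whose *clinical* variables reproduce published class-conditional summary
statistics (means/SDs of age, length of stay, admission/discharge NIHSS;
exact counts for gender, thrombolysis and vertebrobasilar artery stenosis),
and whose *volumes* carry a controllable class-dependent lesion signal
(a hyperintense sphere inside an ellipsoidal brainstem phantom).

The outcome of interest is early neurological deterioration (ND), defined as
a rise of at least 2 points in the total NIHSS score between the initial and
the maximal neurological deficit.  Generation is label-first: the class is
assigned, then features are drawn from class-conditional distributions and
the maximal NIHSS is constructed so the ND rule reproduces the class.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy.stats import norm

__all__ = [
    "ClinicalRecord",
    "CohortConfig",
    "derive_nd_label",
    "derive_nihss_correlations",
    "sample_clinical",
    "render_volume",
    "normalize_volume",
    "standardize_tabular",
    "tabular_matrix",
    "records_to_frame",
    "generate_cohort",
]

# NIHSS totals range 0-42 by construction of the scale.
NIHSS_MAX_SCORE = 42.0
AGE_BOUNDS = (18.0, 100.0)
LOHS_BOUNDS = (1.0, 90.0)

#: Model input features (in column order). Gender, age, thrombolysis and the
#: maximal NIHSS are recorded but not fed to the classifier.
TABULAR_FEATURES = ("lohs", "nihss_admission", "nihss_discharge", "vas")
_CONTINUOUS_INPUTS = ("lohs", "nihss_admission", "nihss_discharge")


@dataclass
class ClinicalRecord:
    """One patient's clinical variables plus the derived ND label."""

    patient_id: str
    gender: int              # 1 = male, 0 = female
    age: float               # years
    lohs: float              # length of hospital stay, days
    thrombolysis: int        # 1 = received thrombolysis
    nihss_admission: float
    nihss_max: float         # maximal deficit during the stay
    nihss_discharge: float
    vas: int                 # vertebrobasilar artery stenosis present
    nd_label: int            # 1 = neurological deterioration

    def __post_init__(self) -> None:
        if min(self.nihss_admission, self.nihss_max, self.nihss_discharge) < 0:
            raise ValueError("NIHSS scores must be non-negative")
        if self.lohs <= 0:
            raise ValueError("length of stay must be positive")
        if self.nd_label != derive_nd_label(self.nihss_admission, self.nihss_max):
            raise ValueError("nd_label inconsistent with the NIHSS deterioration rule")


@dataclass
class ClassStats:
    """Class-conditional distribution parameters for one outcome class."""

    n: int
    age_mean: float
    age_sd: float
    lohs_mean: float
    lohs_sd: float
    nihss_adm_mean: float
    nihss_adm_sd: float
    nihss_dis_mean: float
    nihss_dis_sd: float
    nihss_diff_sd: float     # SD of (discharge - admission); fixes the joint
    n_male: int
    n_thrombolysis: int
    n_vas: int


# Published cohort summary (386 pontine infarction patients; 126 ND-positive).
POSITIVE_STATS = ClassStats(
    n=126, age_mean=69.92, age_sd=10.96, lohs_mean=16.40, lohs_sd=8.11,
    nihss_adm_mean=5.02, nihss_adm_sd=2.23, nihss_dis_mean=6.75, nihss_dis_sd=2.48,
    nihss_diff_sd=2.39, n_male=77, n_thrombolysis=14, n_vas=31,
)
NEGATIVE_STATS = ClassStats(
    n=260, age_mean=69.96, age_sd=48.16, lohs_mean=13.05, lohs_sd=6.71,
    nihss_adm_mean=4.91, nihss_adm_sd=3.11, nihss_dis_mean=3.93, nihss_dis_sd=2.58,
    nihss_diff_sd=1.66, n_male=160, n_thrombolysis=28, n_vas=30,
)
# Note: the published negative-class age SD (48.16) is implausibly large for a
# mean of 69.96 (likely a typo in the source table) but is reproduced as
# printed; the generated ages are clipped to AGE_BOUNDS.


@dataclass
class CohortConfig:
    """Everything that determines a generated cohort.

    ``effect_scale`` rescales the between-class separation of the model's
    input features and the lesion contrast around their pooled values:
    0 gives a label-free (null) cohort, 1 the published separation.
    """

    n_total: int = 386
    n_positive: int = 126
    positive: ClassStats = field(default_factory=lambda: dataclasses.replace(POSITIVE_STATS))
    negative: ClassStats = field(default_factory=lambda: dataclasses.replace(NEGATIVE_STATS))
    nihss_corr_pos: float | None = None   # None -> derived from the SDs
    nihss_corr_neg: float | None = None
    volume_shape: tuple[int, int, int] = (20, 256, 256)
    lesion_radius_range: tuple[float, float] = (1.5, 3.0)
    lesion_contrast_pos: float = 3.0
    lesion_contrast_neg: float = 1.0
    noise_sd: float = 0.5
    effect_scale: float = 1.0
    exact_count_binaries: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_positive <= self.n_total):
            raise ValueError("n_positive must lie in [0, n_total]")
        if min(self.volume_shape) < 2 * self.lesion_radius_range[1]:
            raise ValueError("volume dimensions must exceed the lesion diameter")
        for rho in (self.nihss_corr_pos, self.nihss_corr_neg):
            if rho is not None and not -1.0 < rho < 1.0:
                raise ValueError("NIHSS correlations must lie in (-1, 1)")

    def stats_for(self, class_label: int) -> ClassStats:
        return self.positive if class_label == 1 else self.negative

    def correlation_for(self, class_label: int) -> float:
        override = self.nihss_corr_pos if class_label == 1 else self.nihss_corr_neg
        if override is not None:
            return override
        s = self.stats_for(class_label)
        return derive_nihss_correlations(s.nihss_adm_sd, s.nihss_dis_sd, s.nihss_diff_sd)


def derive_nd_label(nihss_admission: float, nihss_max: float) -> int:
    """Neurological deterioration: >= 2-point NIHSS rise from admission to maximum."""
    if nihss_admission < 0 or nihss_max < 0:
        raise ValueError("NIHSS scores must be non-negative")
    return int(nihss_max - nihss_admission >= 2)


def derive_nihss_correlations(sd_adm: float, sd_dis: float, sd_diff: float) -> float:
    """Correlation of (admission, discharge) NIHSS implied by the three SDs.

    From Var(D - A) = Var(A) + Var(D) - 2*rho*SD(A)*SD(D):
    rho = (sd_adm^2 + sd_dis^2 - sd_diff^2) / (2 * sd_adm * sd_dis).
    """
    rho = (sd_adm ** 2 + sd_dis ** 2 - sd_diff ** 2) / (2.0 * sd_adm * sd_dis)
    if not -1.0 < rho < 1.0:
        raise ValueError(
            f"marginal SDs ({sd_adm}, {sd_dis}) and change SD ({sd_diff}) imply "
            f"correlation {rho:.3f} outside (-1, 1)"
        )
    return rho


# ---------------------------------------------------------------------------
# clipped-normal moment calibration
#
# Clipping a Gaussian at plausibility bounds shifts its mean and shrinks its
# SD, so sampling directly at the published parameters would not recover the
# published moments.  The generator therefore solves for pre-clip (mu, sigma)
# such that the post-clip moments equal the targets, and for a pre-clip
# correlation of the NIHSS pair such that the post-clip SD of the change
# matches the published value.
# ---------------------------------------------------------------------------

def clipped_normal_moments(mu: float, sigma: float, lo: float, hi: float
                           ) -> tuple[float, float]:
    """Mean and SD of clip(X, lo, hi) for X ~ Normal(mu, sigma), closed form."""
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    pa, pb = norm.cdf(a), norm.cdf(b)
    fa, fb = norm.pdf(a), norm.pdf(b)
    mid = pb - pa
    m1 = lo * pa + hi * (1 - pb) + mu * mid - sigma * (fb - fa)
    # E[X^2 ; lo<X<hi] with x = mu + sigma z
    mid2 = (mu ** 2 * mid + 2 * mu * sigma * (fa - fb)
            + sigma ** 2 * (mid + a * fa - b * fb))
    m2 = lo ** 2 * pa + hi ** 2 * (1 - pb) + mid2
    var = max(m2 - m1 ** 2, 0.0)
    return m1, np.sqrt(var)


@lru_cache(maxsize=None)
def _calibrate_clipped_normal(target_mean: float, target_sd: float,
                              lo: float, hi: float) -> tuple[float, float]:
    """Pre-clip (mu, sigma) whose clipped moments hit the targets.

    If the target SD is unattainable on [lo, hi] (it exceeds the half-range,
    the SD of the extreme two-point distribution), only the mean is matched
    and the SD is left as printed.
    """
    if not lo < target_mean < hi:
        raise ValueError(f"target mean {target_mean} outside bounds ({lo}, {hi})")

    def residual(params):
        mu, log_sigma = params
        m, s = clipped_normal_moments(mu, float(np.exp(log_sigma)), lo, hi)
        return [m - target_mean, s - target_sd]

    if target_sd < (hi - lo) / 2:
        sol, info, ier, _ = optimize.fsolve(
            residual, [target_mean, np.log(target_sd)], full_output=True)
        if ier == 1 and max(np.abs(info["fvec"])) < 1e-8:
            return float(sol[0]), float(np.exp(sol[1]))
    # fall back: match the mean only, at the printed sigma
    mu = optimize.brentq(
        lambda m: clipped_normal_moments(m, target_sd, lo, hi)[0] - target_mean,
        lo - 10 * target_sd, hi + 10 * target_sd)
    return float(mu), float(target_sd)


def _clipped_cross_moment(mu_x, sd_x, mu_y, sd_y, rho, lo, hi) -> float:
    """E[clip(X) * clip(Y)] for a bivariate normal, by 1-D quadrature over the
    driver of X (the inner conditional expectation is closed form)."""

    def integrand(u):
        x = np.clip(mu_x + sd_x * u, lo, hi)
        cm = mu_y + sd_y * rho * u
        cs = sd_y * np.sqrt(max(1 - rho ** 2, 1e-12))
        ey = clipped_normal_moments(cm, cs, lo, hi)[0]
        return x * ey * norm.pdf(u)

    kinks = sorted(np.clip([(lo - mu_x) / sd_x, (hi - mu_x) / sd_x], -8, 8))
    pts = [-8.0, *kinks, 8.0]
    total = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        if b > a:
            total += integrate.quad(integrand, a, b, limit=100)[0]
    return total


@lru_cache(maxsize=None)
def _calibrate_nihss_joint(adm_mean: float, adm_sd: float, dis_mean: float,
                           dis_sd: float, diff_sd: float
                           ) -> tuple[float, float, float, float, float]:
    """Calibrated (mu_a, sd_a, mu_d, sd_d, rho) for the clipped NIHSS pair.

    Marginals are calibrated first; the pre-clip correlation is then solved
    so the post-clip SD of (discharge - admission) equals ``diff_sd``.
    """
    lo, hi = 0.0, NIHSS_MAX_SCORE
    mu_a, sd_a = _calibrate_clipped_normal(adm_mean, adm_sd, lo, hi)
    mu_d, sd_d = _calibrate_clipped_normal(dis_mean, dis_sd, lo, hi)
    ma, sa = clipped_normal_moments(mu_a, sd_a, lo, hi)
    md, sd_ = clipped_normal_moments(mu_d, sd_d, lo, hi)

    def diff_sd_of(rho):
        exy = _clipped_cross_moment(mu_a, sd_a, mu_d, sd_d, rho, lo, hi)
        cov = exy - ma * md
        return np.sqrt(max(sa ** 2 + sd_ ** 2 - 2 * cov, 1e-12)) - diff_sd

    rho0 = derive_nihss_correlations(adm_sd, dis_sd, diff_sd)
    try:
        rho = optimize.brentq(diff_sd_of, -0.995, 0.995, xtol=1e-10)
    except ValueError:
        rho = rho0  # printed diff SD unattainable after clipping; keep derived
    return mu_a, sd_a, mu_d, sd_d, float(rho)


def _pooled(cfg: CohortConfig, attr: str) -> float:
    wp = cfg.n_positive / cfg.n_total if cfg.n_total else 0.5
    return wp * getattr(cfg.positive, attr) + (1 - wp) * getattr(cfg.negative, attr)


def _effective_mean(cfg: CohortConfig, class_label: int, attr: str) -> float:
    """Class mean shrunk toward the pooled mean by (1 - effect_scale)."""
    mu = getattr(cfg.stats_for(class_label), attr)
    if cfg.effect_scale == 1.0:
        return mu
    pooled = _pooled(cfg, attr)
    return pooled + cfg.effect_scale * (mu - pooled)


def _binary_count(cfg: CohortConfig, class_label: int, attr: str, n_class: int) -> int:
    """Exact success count for a binary feature, scaled to the class size."""
    s = cfg.stats_for(class_label)
    p_class = getattr(s, attr) / s.n
    # effect_scale shrinks the class probability toward the pooled probability
    sp, sn = cfg.positive, cfg.negative
    pooled = (getattr(sp, attr) + getattr(sn, attr)) / (sp.n + sn.n)
    p = pooled + cfg.effect_scale * (p_class - pooled)
    return int(round(p * n_class))


def sample_clinical(class_label: int, n: int, rng: np.random.Generator,
                    config: CohortConfig | None = None,
                    start_index: int = 0) -> list[ClinicalRecord]:
    """Draw ``n`` clinical records of one outcome class.

    Continuous variables come from class-conditional Gaussians (clipped to
    plausibility bounds); admission and discharge NIHSS are drawn jointly
    from a bivariate Gaussian whose correlation reproduces the published SD
    of the NIHSS change.  The maximal NIHSS is then constructed so that the
    deterioration rule yields ``class_label``: positives add
    ``max(2, round(|half-normal, scale 2|))`` to the admission score and
    negatives add a fair coin flip (0 or 1 points).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = config or CohortConfig()
    s = cfg.stats_for(class_label)

    # per-feature pre-clip parameters calibrated so post-clip moments match
    mu_age, sd_age = _calibrate_clipped_normal(s.age_mean, s.age_sd, *AGE_BOUNDS)
    age = np.clip(rng.normal(mu_age, sd_age, n), *AGE_BOUNDS)
    mu_lohs, sd_lohs = _calibrate_clipped_normal(
        _effective_mean(cfg, class_label, "lohs_mean"), s.lohs_sd, *LOHS_BOUNDS)
    lohs = np.clip(rng.normal(mu_lohs, sd_lohs, n), *LOHS_BOUNDS)

    adm_target = _effective_mean(cfg, class_label, "nihss_adm_mean")
    dis_target = _effective_mean(cfg, class_label, "nihss_dis_mean")
    rho_override = cfg.nihss_corr_pos if class_label == 1 else cfg.nihss_corr_neg
    if rho_override is not None:
        mu_a, sd_a = _calibrate_clipped_normal(adm_target, s.nihss_adm_sd,
                                               0.0, NIHSS_MAX_SCORE)
        mu_d, sd_d = _calibrate_clipped_normal(dis_target, s.nihss_dis_sd,
                                               0.0, NIHSS_MAX_SCORE)
        rho = rho_override
    else:
        mu_a, sd_a, mu_d, sd_d, rho = _calibrate_nihss_joint(
            adm_target, s.nihss_adm_sd, dis_target, s.nihss_dis_sd, s.nihss_diff_sd)
    mean = np.array([mu_a, mu_d])
    cov = np.array([
        [sd_a ** 2, rho * sd_a * sd_d],
        [rho * sd_a * sd_d, sd_d ** 2],
    ])
    adm, dis = np.clip(
        rng.multivariate_normal(mean, cov, size=n, method="cholesky"),
        0.0, NIHSS_MAX_SCORE,
    ).T

    if class_label == 1:
        rise = np.maximum(2.0, np.round(np.abs(rng.normal(0.0, 2.0, n))))
    else:
        rise = rng.integers(0, 2, n).astype(float)
    nmax = np.clip(adm + rise, 0.0, NIHSS_MAX_SCORE + 10.0)
    if class_label == 1:
        # guard against float cancellation: (adm + rise) - adm can fall a few
        # ulp short of the requested rise, which would flip the label rule
        short = (nmax - adm) < 2.0
        nmax[short] = adm[short] + 2.5

    if cfg.exact_count_binaries:
        n_class = s.n
        counts = {
            "gender": _binary_count(cfg, class_label, "n_male", n_class),
            "thrombolysis": _binary_count(cfg, class_label, "n_thrombolysis", n_class),
            "vas": _binary_count(cfg, class_label, "n_vas", n_class),
        }
        binaries = {}
        for name, k in counts.items():
            k_scaled = int(round(k * n / n_class))
            if k_scaled > n:
                raise ValueError(f"exact count for {name} ({k_scaled}) exceeds n={n}")
            vec = np.zeros(n, dtype=int)
            vec[: k_scaled] = 1
            binaries[name] = vec[rng.permutation(n)]
    else:
        sp, sn = cfg.positive, cfg.negative
        binaries = {}
        for name, attr in (("gender", "n_male"), ("thrombolysis", "n_thrombolysis"),
                           ("vas", "n_vas")):
            p_class = getattr(s, attr) / s.n
            pooled = (getattr(sp, attr) + getattr(sn, attr)) / (sp.n + sn.n)
            p = pooled + cfg.effect_scale * (p_class - pooled)
            binaries[name] = (rng.random(n) < p).astype(int)

    prefix = "P" if class_label == 1 else "N"
    records = []
    for i in range(n):
        records.append(ClinicalRecord(
            patient_id=f"{prefix}{start_index + i:06d}",
            gender=int(binaries["gender"][i]),
            age=float(age[i]),
            lohs=float(lohs[i]),
            thrombolysis=int(binaries["thrombolysis"][i]),
            nihss_admission=float(adm[i]),
            nihss_max=float(nmax[i]),
            nihss_discharge=float(dis[i]),
            vas=int(binaries["vas"][i]),
            nd_label=class_label,
        ))
    return records


def render_volume(class_label: int, rng: np.random.Generator,
                  config: CohortConfig | None = None) -> np.ndarray:
    """Render one synthetic volume: ellipsoidal phantom + noise + lesion.

    The lesion is a hyperintense sphere at a random interior position; its
    intensity contrast is class-dependent (scaled by ``effect_scale`` around
    the class-pooled contrast) so the image modality carries a tunable
    amount of label signal.
    """
    cfg = config or CohortConfig()
    d, h, w = cfg.volume_shape
    r_min, r_max = cfg.lesion_radius_range
    if 2 * r_max > min(d, h, w):
        raise ValueError("lesion diameter exceeds the volume extent")

    zz, yy, xx = np.meshgrid(
        np.linspace(-1, 1, d), np.linspace(-1, 1, h), np.linspace(-1, 1, w),
        indexing="ij",
    )
    body = (zz ** 2 + yy ** 2 + xx ** 2) <= 1.0
    vol = np.where(body, 1.0, 0.0)
    vol = vol + rng.normal(0.0, cfg.noise_sd, size=(d, h, w)) * body

    radius = rng.uniform(r_min, r_max)
    margin = int(np.ceil(radius))
    center = np.array([
        rng.uniform(margin, dim - margin) if dim - margin > margin else dim / 2.0
        for dim in (d, h, w)
    ])
    zi, yi, xi = np.meshgrid(np.arange(d), np.arange(h), np.arange(w), indexing="ij")
    lesion = ((zi - center[0]) ** 2 + (yi - center[1]) ** 2 + (xi - center[2]) ** 2) <= radius ** 2

    pooled = 0.5 * (cfg.lesion_contrast_pos + cfg.lesion_contrast_neg)
    contrast = cfg.lesion_contrast_pos if class_label == 1 else cfg.lesion_contrast_neg
    contrast = pooled + cfg.effect_scale * (contrast - pooled)
    vol[lesion] += contrast
    return vol


def normalize_volume(volume: np.ndarray) -> np.ndarray:
    """Z-score intensities within the nonzero foreground mask."""
    out = volume.astype(np.float64).copy()
    mask = out != 0
    if not mask.any():
        raise ValueError("volume has no foreground voxels")
    fg = out[mask]
    sd = fg.std()
    if sd == 0:
        raise ValueError("foreground intensity is constant; cannot normalize")
    out[mask] = (fg - fg.mean()) / sd
    return out


def records_to_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def tabular_matrix(records: list[ClinicalRecord]) -> np.ndarray:
    """Raw n x 4 matrix of the model's input features (unstandardized)."""
    df = records_to_frame(records)
    return df.loc[:, list(TABULAR_FEATURES)].to_numpy(dtype=np.float64)


def standardize_tabular(records: list[ClinicalRecord],
                        train_stats: dict[str, tuple[float, float]]) -> np.ndarray:
    """Z-score the continuous input features with training-split statistics.

    ``train_stats`` maps each continuous feature name to its training
    (mean, sd); the binary stenosis indicator passes through unchanged.
    """
    x = tabular_matrix(records)
    for j, name in enumerate(TABULAR_FEATURES):
        if name not in _CONTINUOUS_INPUTS:
            continue
        mean, sd = train_stats[name]
        if sd == 0:
            raise ValueError(f"feature {name!r} has zero training SD")
        x[:, j] = (x[:, j] - mean) / sd
    return x


def train_feature_stats(records: list[ClinicalRecord]) -> dict[str, tuple[float, float]]:
    """Per-feature (mean, sd) of the continuous inputs, from a training split."""
    x = tabular_matrix(records)
    stats = {}
    for j, name in enumerate(TABULAR_FEATURES):
        if name in _CONTINUOUS_INPUTS:
            stats[name] = (float(x[:, j].mean()), float(x[:, j].std()))
    return stats


def generate_cohort(config: CohortConfig | None = None,
                    include_volumes: bool = True,
                    ) -> tuple[list[ClinicalRecord], np.ndarray | None, np.ndarray]:
    """Generate a full cohort: records, normalized volumes, labels.

    Returns exactly ``n_positive`` positive and ``n_total - n_positive``
    negative samples in a seeded shuffled order.  Volumes are returned as a
    single float32 array of shape (n, D, H, W), already intensity-normalized
    (or ``None`` when ``include_volumes`` is false).
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    n_neg = cfg.n_total - cfg.n_positive
    records: list[ClinicalRecord] = []
    if cfg.n_positive:
        records += sample_clinical(1, cfg.n_positive, rng, cfg)
    if n_neg:
        records += sample_clinical(0, n_neg, rng, cfg, start_index=cfg.n_positive)

    order = rng.permutation(cfg.n_total)
    records = [records[i] for i in order]
    labels = np.array([r.nd_label for r in records], dtype=int)

    volumes = None
    if include_volumes:
        volumes = np.empty((cfg.n_total, *cfg.volume_shape), dtype=np.float32)
        for i, r in enumerate(records):
            volumes[i] = normalize_volume(render_volume(r.nd_label, rng, cfg))
    return records, volumes, labels
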