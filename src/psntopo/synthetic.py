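"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The generative model is deliberately simple: a binary class label shifts the
mean of a subset of informative features, features live in equicorrelated
blocks (one shared latent factor per block), and everything else is Gaussian
noise. A "platform pair" applies a per-feature monotone distortion plus
independent measurement noise to one shared latent signal, emulating the same
cohort measured with two technologies (e.g. microarray and RNA-seq), which is
what the cross-cohort transfer harness exercises.

Class imbalance defaults to 4:1 (prevalence 0.2), the imbalance of the
death-from-disease outcome the method was designed around; the progression
outcome corresponds to prevalence 1/3 (2:1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from psntopo.io_formats import ExpressionMatrix, OutcomeTable

OUTCOME_NAME = "event"


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort.

    effect_size is the standardized mean shift (in units of noise_sd) applied
    to informative features between classes; block_rho the within-block
    feature correlation induced by a shared latent factor.
    """

    n_samples: int = 200
    n_features: int = 2000
    n_informative: int = 100
    effect_size: float = 1.0
    class_prevalence: float = 0.2
    n_blocks: int = 10
    block_rho: float = 0.6
    noise_sd: float = 1.0
    sample_scale_sd: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.class_prevalence < 1:
            raise ValueError("class_prevalence must lie in (0, 1)")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        n_pos = round(self.class_prevalence * self.n_samples)
        if n_pos < 2 or self.n_samples - n_pos < 2:
            raise ValueError("infeasible prevalence: need >= 2 samples per class")
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_blocks < 1 or self.n_blocks > self.n_features:
            raise ValueError("n_blocks must lie in [1, n_features]")
        if self.sample_scale_sd < 0:
            raise ValueError("sample_scale_sd must be non-negative")


def _labels(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Exactly round(prevalence * n) positive labels, shuffled."""
    n_pos = round(config.class_prevalence * config.n_samples)
    y = np.zeros(config.n_samples, dtype=int)
    y[:n_pos] = 1
    rng.shuffle(y)
    return y


def _latent_signal(config: CohortConfig, y: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Noise-free p x n latent signal: class mean-shift + block factors.

    Informative features are the first ``n_informative`` (the generator
    records no secret: recovering them is the selection module's job). Each
    gets a random +/- sign so the class signal is not a single direction.
    Block factors give within-block correlation ~``block_rho`` once the
    idiosyncratic noise (variance (1 - rho) * noise_sd^2) is added.

    The block-factor component is multiplied by a per-sample lognormal scale
    (sigma ``sample_scale_sd``), emulating sample-level heterogeneity in
    global signal strength (tumour purity, RNA quality). This is what gives
    the patient similarity network its hubs: high-scale samples correlate
    strongly with many others, so the soft-thresholded degree distribution
    becomes heavy-tailed (approximately scale-free), as the pipeline assumes.
    """
    p, n = config.n_features, config.n_samples
    shift = np.zeros((p, n))
    signs = rng.choice([-1.0, 1.0], size=config.n_informative)
    shift[: config.n_informative, :] = (
        signs[:, None] * config.effect_size * config.noise_sd * y[None, :]
    )
    block_of = np.arange(p) % config.n_blocks
    factors = rng.standard_normal((config.n_blocks, n))
    s = config.sample_scale_sd
    scale = np.exp(s * rng.standard_normal(n) - s * s / 2.0)
    shared = (
        math.sqrt(config.block_rho) * config.noise_sd
        * factors[block_of, :] * scale[None, :]
    )
    return shift + shared


def _idiosyncratic(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    sd = math.sqrt(1.0 - config.block_rho) * config.noise_sd
    return sd * rng.standard_normal((config.n_features, config.n_samples))


def _ids(prefix: str, k: int) -> list[str]:
    width = len(str(k))
    return [f"{prefix}{i:0{width}d}" for i in range(k)]


def generate_cohort(config: CohortConfig) -> tuple[ExpressionMatrix, OutcomeTable]:
    """One cohort: features x samples matrix plus a binary outcome table.

    Pure function of the config: the same seed reproduces the data bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    y = _labels(config, rng)
    values = _latent_signal(config, y, rng) + _idiosyncratic(config, rng)
    samples = _ids("S", config.n_samples)
    features = _ids("F", config.n_features)
    expr = ExpressionMatrix(values, features, samples, platform_tag="synthetic")
    outcomes = OutcomeTable(samples, {OUTCOME_NAME: y})
    return expr, outcomes


def generate_platform_pair(
    config: CohortConfig,
    distortion: str = "affine",
    view_noise_sd: float | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, OutcomeTable]:
    """Two platform views of one latent cohort, for the transfer harness.

    Both matrices derive from the same latent signal + block-noise matrix.
    View A adds independent measurement noise; view B first applies a
    per-feature distortion — ``affine`` (positive scale + offset, Pearson
    preserved) or ``rank-monotone`` (strictly increasing cubic, Spearman
    preserved) — then adds its own independent noise. ``view_noise_sd``
    defaults to half the cohort noise_sd.
    """
    if distortion not in ("affine", "rank-monotone"):
        raise ValueError(f"unknown distortion '{distortion}'")
    if view_noise_sd is None:
        view_noise_sd = 0.5 * config.noise_sd
    rng = np.random.default_rng(config.seed)
    y = _labels(config, rng)
    latent = _latent_signal(config, y, rng) + _idiosyncratic(config, rng)
    p, n = latent.shape

    noise_a = view_noise_sd * rng.standard_normal((p, n))
    view_a = latent + noise_a

    if distortion == "affine":
        scale = rng.uniform(0.5, 2.0, size=p)[:, None]
        offset = rng.uniform(-1.0, 1.0, size=p)[:, None]
        distorted = scale * latent + offset
    else:  # strictly increasing, non-linear, per-feature
        curv = rng.uniform(0.05, 0.3, size=p)[:, None]
        distorted = latent + curv * latent ** 3
    noise_b = view_noise_sd * rng.standard_normal((p, n))
    view_b = distorted + noise_b

    samples = _ids("S", n)
    features = _ids("F", p)
    expr_a = ExpressionMatrix(view_a, features, samples, platform_tag="platformA")
    expr_b = ExpressionMatrix(view_b, list(features), list(samples),
                              platform_tag="platformB")
    outcomes = OutcomeTable(samples, {OUTCOME_NAME: y})
    return expr_a, expr_b, outcomes
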