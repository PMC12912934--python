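"""Adversarial synthetic benchmark for plasticity-index estimators.

Generates a deliberately "messy" study: 10 sample groups whose clean
signal is log-normal (so raw scales, skew and a positive mean-variance
association arise naturally), overlaid with additive heavy-tailed
Student-t noise, symmetric point contamination (outliers), and random
missingness, with unbalanced group sizes. Ten environmental variables
(z1..z10) are drawn per group through a Gaussian copula with three
correlated blocks, mimicking interdependent ecological drivers.

Ground truth for every pair of groups is the standardized effect of the
clean log-normal signal: |mu_i - mu_j| / sqrt((sigma_i^2 + sigma_j^2)/2)
from the closed-form log-normal moments. Noise, contamination and
missingness are nuisance processes an estimator has to survive; they are
deliberately excluded from the truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .effect_size import GroupSample
from .exceptions import InvalidInputError

__all__ = [
    "SimConfig",
    "SimulatedStudy",
    "block_correlation",
    "lognormal_moments",
    "ground_truth_effect",
    "generate_study",
    "pairwise_table",
    "to_tidy",
]

#: default copula block structure of the 10 environmental variables
DEFAULT_ENV_BLOCKS = (
    ("z4", "z5", "z7"),
    ("z1", "z2", "z8", "z9", "z10"),
    ("z3", "z6"),
)


def block_correlation(
    axis_names: tuple[str, ...],
    blocks=DEFAULT_ENV_BLOCKS,
    rho: float = 0.7,
) -> np.ndarray:
    """Correlation matrix with ``rho`` inside each block, 0 between blocks."""
    n = len(axis_names)
    corr = np.eye(n)
    pos = {name: i for i, name in enumerate(axis_names)}
    for block in blocks:
        for a, b in itertools.combinations(block, 2):
            corr[pos[a], pos[b]] = corr[pos[b], pos[a]] = rho
    return corr


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults define the benchmark's study conditions.

    Per-group log-normal parameters are spaced so group means span
    roughly two orders of magnitude; the log-scale SD grows with the
    location (``hetero_slope``), which makes larger-mean groups noisier
    both relatively and absolutely. Noise and contamination scale with
    each group's clean SD, so "messiness" is proportionate.
    """

    n_groups: int = 10
    n_min: int = 85  # replicate draws per group before missingness
    n_max: int = 160
    meanlog_min: float = 4.5  # log-scale locations, spaced across groups
    meanlog_max: float = 6.6
    sdlog_base: float = 0.4  # log-scale SD of the smallest-mean group
    hetero_slope: float = 0.4  # extra log-SD from smallest to largest group
    noise_scale_frac: float = 0.8  # t-noise scale as fraction of clean SD
    t_df: float = 3.0  # heavy-tail df of the additive noise
    contamination_rate: tuple[float, ...] = (
        0.03, 0.06, 0.02, 0.08, 0.04, 0.05, 0.07, 0.03, 0.06, 0.04,
    )
    contamination_amp: float = 7.0  # outlier offset in units of clean SD
    missing_rate: float = 0.08
    env_axes: tuple[str, ...] = tuple(f"z{i}" for i in range(1, 11))
    env_blocks: tuple = DEFAULT_ENV_BLOCKS
    env_rho: float = 0.7
    seed: int = 0

    def __post_init__(self):
        rates = np.asarray(self.contamination_rate, dtype=float)
        if rates.size != self.n_groups:
            raise InvalidInputError(
                f"need one contamination rate per group "
                f"({self.n_groups}), got {rates.size}"
            )
        for name, val in [("contamination_rate", rates),
                          ("missing_rate", np.array([self.missing_rate]))]:
            if np.any((val < 0) | (val > 1)):
                raise InvalidInputError(f"{name} must lie in [0, 1]")
        corr = self.correlation_matrix()
        eig = np.linalg.eigvalsh(corr)
        if eig.min() < -1e-10:
            raise InvalidInputError(
                f"copula correlation matrix is not positive semi-definite "
                f"(min eigenvalue {eig.min():.3g})"
            )

    def correlation_matrix(self) -> np.ndarray:
        return block_correlation(self.env_axes, self.env_blocks, self.env_rho)

    def group_params(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-group (meanlog, sdlog) of the clean log-normal signal."""
        frac = (
            np.linspace(0.0, 1.0, self.n_groups)
            if self.n_groups > 1
            else np.zeros(1)
        )
        meanlog = self.meanlog_min + frac * (self.meanlog_max - self.meanlog_min)
        sdlog = self.sdlog_base + frac * self.hetero_slope
        return meanlog, sdlog


@dataclass(frozen=True)
class SimulatedStudy:
    """One realized benchmark dataset."""

    labels: tuple[str, ...]
    groups: tuple[GroupSample, ...]
    env: pd.DataFrame  # one row per group, one column per z axis
    truth: pd.DataFrame  # columns: group_a, group_b, truth
    config: SimConfig


def lognormal_moments(meanlog: float, sdlog: float) -> tuple[float, float]:
    """Closed-form (mean, variance) of a log-normal distribution."""
    mean = np.exp(meanlog + sdlog**2 / 2.0)
    var = (np.exp(sdlog**2) - 1.0) * np.exp(2.0 * meanlog + sdlog**2)
    return float(mean), float(var)


def ground_truth_effect(
    pair: tuple[int, int],
    config: SimConfig,
    weights: tuple[float, float] | None = None,
) -> float:
    """True standardized effect between two groups of the clean signal.

    |mu_i - mu_j| / sigma_pool with equal-weight pooling of the true
    variances by default (true moments carry no sample size); pass
    ``weights=(n_i, n_j)`` for (n-1)-weighted pooling instead.
    """
    i, j = pair
    meanlog, sdlog = config.group_params()
    mi, vi = lognormal_moments(meanlog[i], sdlog[i])
    mj, vj = lognormal_moments(meanlog[j], sdlog[j])
    if weights is None:
        pool = np.sqrt((vi + vj) / 2.0)
    else:
        wi, wj = weights[0] - 1.0, weights[1] - 1.0
        pool = np.sqrt((wi * vi + wj * vj) / (wi + wj))
    return float(abs(mi - mj) / pool)


def generate_study(config: SimConfig | None = None, seed: int | None = None) -> SimulatedStudy:
    """Draw one benchmark dataset; reproducible from the seed.

    ``seed`` overrides ``config.seed`` when given.
    """
    config = config or SimConfig()
    if seed is not None:
        config = replace(config, seed=int(seed))
    rng = np.random.default_rng(config.seed)
    meanlog, sdlog = config.group_params()
    rates = np.asarray(config.contamination_rate, dtype=float)

    groups, labels = [], []
    for g in range(config.n_groups):
        n = int(rng.integers(config.n_min, config.n_max + 1))
        clean = rng.lognormal(meanlog[g], sdlog[g], size=n)
        _, var_clean = lognormal_moments(meanlog[g], sdlog[g])
        sigma = np.sqrt(var_clean)
        values = clean + config.noise_scale_frac * sigma * rng.standard_t(
            config.t_df, size=n
        )
        outlier = rng.random(n) < rates[g]
        signs = rng.choice([-1.0, 1.0], size=n)
        values = values + outlier * signs * config.contamination_amp * sigma
        keep = rng.random(n) >= config.missing_rate
        if keep.sum() < 2:  # pathological configs only
            keep[:2] = True
        groups.append(GroupSample(values[keep]))
        labels.append(f"S{g + 1}")

    corr = config.correlation_matrix()
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(config.env_axes)))
    z = rng.standard_normal((config.n_groups, len(config.env_axes))) @ chol.T
    env = pd.DataFrame(
        norm.cdf(z), index=labels, columns=list(config.env_axes)
    )

    rows = [
        {
            "group_a": labels[i],
            "group_b": labels[j],
            "truth": ground_truth_effect((i, j), config),
        }
        for i, j in itertools.combinations(range(config.n_groups), 2)
    ]
    truth = pd.DataFrame(rows)
    return SimulatedStudy(
        labels=tuple(labels),
        groups=tuple(groups),
        env=env,
        truth=truth,
        config=config,
    )


def pairwise_table(
    study: SimulatedStudy,
    n_axes: int = 10,
    scale: float = 1.0,
    exact: bool = True,
) -> pd.DataFrame:
    """All-pairs estimates versus ground truth.

    For every unordered pair of groups: Hedges' g from the samples, the
    classical one-dimensional index on the raw z1 values (group means as
    the phenotypic extremes), and *ESPI = |g| / Euclidean distance over
    the first ``n_axes`` environmental variables (min-max normalized
    across the study's groups). ``scale`` multiplies the raw trait
    values first — the lever of the unit-sensitivity experiment.
    """
    from .effect_size import hedges_g
    from .pipeline import original_espi

    if not 1 <= n_axes <= len(study.config.env_axes):
        raise InvalidInputError(f"n_axes must be in [1, {len(study.config.env_axes)}]")
    axes = list(study.config.env_axes[:n_axes])
    # min-max per axis over the study's groups; a constant axis contributes
    # zero distance (pairs then surface as degenerate, not as a crash)
    env = study.env[axes].to_numpy(dtype=float)
    lo, hi = env.min(axis=0), env.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    norm = (env - lo) / span
    points = {label: norm[i] for i, label in enumerate(study.labels)}
    truth_map = {
        (r.group_a, r.group_b): r.truth for r in study.truth.itertuples()
    }
    z1 = study.env[study.config.env_axes[0]]

    rows = []
    for i, j in itertools.combinations(range(len(study.labels)), 2):
        la, lb = study.labels[i], study.labels[j]
        a = GroupSample(study.groups[i].values * scale)
        b = GroupSample(study.groups[j].values * scale)
        eff = hedges_g(a, b, exact=exact)
        dist = float(np.linalg.norm(points[la] - points[lb]))
        espi_star = abs(eff.g) / dist if dist > 0 else np.nan
        if a.mean >= b.mean:
            x_hi, x_lo, e_hi, e_lo = a.mean, b.mean, z1[la], z1[lb]
        else:
            x_hi, x_lo, e_hi, e_lo = b.mean, a.mean, z1[lb], z1[la]
        espi_orig = (
            original_espi(x_hi, x_lo, e_hi, e_lo) if e_hi != e_lo else np.nan
        )
        rows.append(
            {
                "group_a": la,
                "group_b": lb,
                "g": eff.g,
                "abs_g": abs(eff.g),
                "se": eff.se,
                "distance": dist,
                "espi_star": espi_star,
                "espi_original": espi_orig,
                "truth": truth_map[(la, lb)],
                "degenerate": not np.isfinite(espi_star),
            }
        )
    return pd.DataFrame(rows)


def to_tidy(study: SimulatedStudy, trait: str = "sim_trait") -> pd.DataFrame:
    """Long-format table compatible with the analysis pipeline's reader."""
    frames = []
    for label, group in zip(study.labels, study.groups):
        df = pd.DataFrame({"condition_id": label, "trait": trait,
                           "value": group.values, "day": 0})
        for axis in study.config.env_axes:
            df[axis] = study.env.loc[label, axis]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
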