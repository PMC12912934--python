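"""Standardized effect sizes for two independent groups.

Implements the numerator machinery of the environmentally standardized
plasticity index: Cohen's d with the pooled standard deviation, the
small-sample unbiasing factor J(v) (exact Gamma form and the usual
rational approximation), Hedges' g = d * J(v), the "true" (exact,
noncentral-t based) standard error of g, and pivotal confidence
intervals obtained by inverting the noncentral t distribution.

Conventions
-----------
* Sample standard deviations use the n - 1 denominator throughout, so
  that the (n_i - 1) weights of the pooled SD are coherent.
* d and g keep their sign; the plasticity index takes |g| downstream.
* v = n1 + n2 - 2 degrees of freedom; n_harmonic = 2 n1 n2 / (n1 + n2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .exceptions import DegenerateVarianceError, InvalidInputError

__all__ = [
    "GroupSample",
    "EffectSize",
    "pooled_sd",
    "cohens_d",
    "correction_factor_exact",
    "correction_factor_approx",
    "hedges_g",
    "true_standard_error",
    "noncentral_ci",
]


@dataclass(frozen=True)
class GroupSample:
    """Replicate measurements of one trait under one condition.

    Parameters
    ----------
    values
        Trait measurements (any real units). Must be finite; use
        :meth:`from_values` to drop missing entries first.
    """

    values: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise InvalidInputError("values must be one-dimensional")
        if arr.size < 2:
            raise InvalidInputError(
                f"a group needs at least 2 replicates, got {arr.size}"
            )
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError(
                "values contain missing/non-finite entries; "
                "use GroupSample.from_values to drop them"
            )
        object.__setattr__(self, "values", arr)

    @classmethod
    def from_values(cls, values) -> "GroupSample":
        """Build a group, silently dropping NaN/inf entries."""
        arr = np.asarray(values, dtype=float)
        return cls(arr[np.isfinite(arr)])

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        """Sample standard deviation (n - 1 denominator)."""
        return float(self.values.std(ddof=1))


@dataclass(frozen=True)
class EffectSize:
    """Full record of a two-group standardized mean difference."""

    d: float
    s_pooled: float
    v: int
    j: float
    g: float
    se: float
    ci_low: float
    ci_high: float
    ci_level: float
    n1: int
    n2: int
    n_harmonic: float = field(default=0.0)


def pooled_sd(a: GroupSample, b: GroupSample) -> float:
    """Pooled standard deviation with (n_i - 1) weights.

    Returns 0.0 when both groups are constant; callers that need to
    standardize must treat that as degenerate (``cohens_d`` raises).
    """
    v = a.n + b.n - 2
    num = (a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2
    return float(np.sqrt(num / v))


def cohens_d(a: GroupSample, b: GroupSample) -> float:
    """Cohen's d = (mean(a) - mean(b)) / pooled SD, sign preserved."""
    sp = pooled_sd(a, b)
    if sp == 0.0:
        raise DegenerateVarianceError(
            "pooled standard deviation is zero; standardized effect undefined"
        )
    return (a.mean - b.mean) / sp


def _check_v(v: int) -> int:
    if int(v) != v or v < 2:
        raise InvalidInputError(f"degrees of freedom must be an integer >= 2, got {v}")
    return int(v)


def correction_factor_exact(v: int) -> float:
    """Exact small-sample unbiasing factor J(v).

    J(v) = Gamma(v/2) / (sqrt(v/2) * Gamma((v-1)/2)), evaluated through
    log-Gamma for numerical stability at large v. Monotonically
    increasing in v with limit 1.
    """
    v = _check_v(v)
    return float(
        np.exp(special.gammaln(v / 2) - special.gammaln((v - 1) / 2))
        / np.sqrt(v / 2)
    )


def correction_factor_approx(v: int) -> float:
    """Rational approximation J(v) ~= 1 - 3/(4v - 1), adequate for v >= 10."""
    v = _check_v(v)
    return 1.0 - 3.0 / (4.0 * v - 1.0)


def harmonic_n(n1: int, n2: int) -> float:
    """Harmonic mean sample size n~ = 2 n1 n2 / (n1 + n2)."""
    return 2.0 * n1 * n2 / (n1 + n2)


def true_standard_error(g: float, n1: int, n2: int, j: float | None = None) -> float:
    """Exact ("true") standard error of Hedges' g.

    Derived from the noncentral-t sampling distribution of the t
    statistic: with v = n1 + n2 - 2, n~ the harmonic mean n and J = J(v),

        Var(g) = J^2 * v/(v-2) * (2/n~) * (1 + delta^2 n~/2) - delta^2,

    where the unknown population effect delta is replaced by the
    observed g. Requires v > 2 for the variance to exist.
    """
    v = n1 + n2 - 2
    if v <= 2:
        raise InvalidInputError(f"true SE requires n1 + n2 - 2 > 2, got v={v}")
    if j is None:
        j = correction_factor_exact(v)
    nh = harmonic_n(n1, n2)
    var = j**2 * (v / (v - 2)) * (2.0 / nh) * (1.0 + g**2 * nh / 2.0) - g**2
    return float(np.sqrt(max(var, 0.0)))


def noncentral_ci(
    g: float, n1: int, n2: int, level: float = 0.95, j: float | None = None
) -> tuple[float, float]:
    """Pivotal noncentral-t confidence interval for a standardized effect.

    Inverts the noncentral t distribution: finds the noncentrality
    parameters lambda_L, lambda_U for which the observed statistic
    t = d * sqrt(n~/2) sits at the upper and lower (1-level)/2 tail
    probabilities, then maps lambda back to the effect-size scale by
    dividing by sqrt(n~/2). The interval brackets g (and has exact
    coverage for the population effect).
    """
    if not 0.0 < level < 1.0:
        raise InvalidInputError(f"confidence level must be in (0, 1), got {level}")
    v = n1 + n2 - 2
    _check_v(v)
    if j is None:
        j = correction_factor_exact(v)
    nh = harmonic_n(n1, n2)
    scale = np.sqrt(nh / 2.0)
    t_obs = (g / j) * scale  # observed t statistic, g/J = d
    alpha = 1.0 - level
    lam_low = special.nctdtrinc(v, 1.0 - alpha / 2.0, t_obs)
    lam_high = special.nctdtrinc(v, alpha / 2.0, t_obs)
    if not (np.isfinite(lam_low) and np.isfinite(lam_high)):
        raise ArithmeticError(
            f"noncentrality inversion failed: t={t_obs:.6g}, v={v}, "
            f"quantiles=({alpha / 2:.4g}, {1 - alpha / 2:.4g})"
        )
    return float(lam_low / scale), float(lam_high / scale)


def hedges_g(
    a: GroupSample,
    b: GroupSample,
    exact: bool = True,
    ci_level: float = 0.95,
) -> EffectSize:
    """Hedges' g = d * J(v) with its SE and noncentral-t CI.

    ``exact=True`` (default) uses the Gamma-function correction factor;
    ``exact=False`` uses the 1 - 3/(4v-1) approximation.
    """
    d = cohens_d(a, b)  # raises on degenerate variance
    sp = pooled_sd(a, b)
    v = a.n + b.n - 2
    j = correction_factor_exact(v) if exact else correction_factor_approx(v)
    g = d * j
    se = true_standard_error(g, a.n, b.n, j) if v > 2 else float("nan")
    lo, hi = noncentral_ci(g, a.n, b.n, level=ci_level, j=j)
    return EffectSize(
        d=d,
        s_pooled=sp,
        v=v,
        j=j,
        g=g,
        se=se,
        ci_low=lo,
        ci_high=hi,
        ci_level=ci_level,
        n1=a.n,
        n2=b.n,
        n_harmonic=harmonic_n(a.n, b.n),
    )
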