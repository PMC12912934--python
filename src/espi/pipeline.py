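"""The day-by-day trait plasticity workflow.

For one trait at one time point the procedure is:

1. screen all condition pairs with heteroscedasticity-robust tests
   (Welch's one-way ANOVA as the omnibus, Games-Howell post hoc);
2. take the pair with the greatest statistical difference (smallest
   post hoc p-value; significance annotates, never gates);
3. compute Hedges' g between the two groups and the Euclidean distance
   between their normalized environmental coordinates;
4. report *ESPI = |g| / distance with the g-confidence interval mapped
   onto the same scale.

The classical one-dimensional index (max - min phenotype over the raw
environmental difference) is provided as the comparison baseline, and a
Gaussian curve can be fitted to the resulting per-day index series to
summarize when plasticity peaks.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .effect_size import EffectSize, GroupSample, hedges_g
from .environment import EnvPoint, euclidean_distance
from .exceptions import (
    DegenerateVarianceError,
    FitConvergenceError,
    InvalidInputError,
    ZeroDistanceError,
)

_log = logging.getLogger(__name__)

__all__ = [
    "ConditionGroup",
    "PairScreenResult",
    "EspiResult",
    "GaussianFit",
    "welch_anova",
    "games_howell",
    "select_max_difference_pair",
    "compute_espi",
    "original_espi",
    "espi_time_series",
    "fit_gaussian_time",
]


@dataclass(frozen=True)
class ConditionGroup:
    """Replicates of one trait under one condition at one time point."""

    condition_id: str
    sample: GroupSample
    env: EnvPoint
    trait: str = ""
    time: float | str | None = None


@dataclass(frozen=True)
class PairScreenResult:
    """One pairwise comparison from the significance screen."""

    pair: tuple[str, str]
    statistic: float
    p_value: float
    df: float
    significant: bool


@dataclass(frozen=True)
class EspiResult:
    """One trait x time-point plasticity record.

    ``error`` is set (and numeric fields are NaN) for degenerate cells
    — e.g. the selected conditions share environmental coordinates, or
    every group is constant — so that batch runs keep one row per cell.
    """

    trait: str
    time: float | str | None
    pair: tuple[str, str]
    g: float
    effect: EffectSize | None
    distance: float
    espi: float
    espi_ci_low: float
    espi_ci_high: float
    screen_p: float
    error: str | None = None


@dataclass(frozen=True)
class GaussianFit:
    """Gaussian summary a*exp(-(t-mu)^2/(2 sigma^2)) of an index-vs-time series."""

    amplitude: float
    peak_time: float
    width: float
    rss: float
    ill_conditioned: bool = False

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.amplitude * np.exp(
            -((t - self.peak_time) ** 2) / (2.0 * self.width**2)
        )


def _moments(groups: list[GroupSample]):
    means = np.array([g.mean for g in groups])
    variances = np.array([g.sd**2 for g in groups])
    ns = np.array([g.n for g in groups], dtype=float)
    return means, variances, ns


def welch_anova(groups: list[GroupSample]) -> tuple[float, float]:
    """Welch's heteroscedastic one-way ANOVA.

    Returns ``(F, p)`` with Welch-Satterthwaite denominator degrees of
    freedom. Any zero-variance group is degenerate for this statistic.
    """
    if len(groups) < 2:
        raise InvalidInputError("Welch ANOVA needs at least two groups")
    means, variances, ns = _moments(groups)
    if np.any(variances == 0.0):
        raise DegenerateVarianceError("zero-variance group in Welch ANOVA")
    k = len(groups)
    w = ns / variances
    w_sum = w.sum()
    grand = (w * means).sum() / w_sum
    num = ((w * (means - grand) ** 2).sum()) / (k - 1)
    h = ((1.0 - w / w_sum) ** 2 / (ns - 1.0)).sum()
    den = 1.0 + 2.0 * (k - 2.0) / (k**2 - 1.0) * h
    f = num / den
    df2 = (k**2 - 1.0) / (3.0 * h)
    p = float(stats.f.sf(f, k - 1, df2))
    return float(f), p


def _gh_stats(means, variances, ns):
    """Vectorized Games-Howell q statistics and Welch-Satterthwaite df.

    Returns index pairs (i, j), studentized-range statistics and per-pair
    df for all unordered pairs; shared with the null-simulation harness.
    """
    k = len(means)
    idx = np.array(list(itertools.combinations(range(k), 2)))
    i, j = idx[:, 0], idx[:, 1]
    vi, vj = variances[i] / ns[i], variances[j] / ns[j]
    se2 = vi + vj
    q = np.abs(means[i] - means[j]) / np.sqrt(se2 / 2.0)
    df = se2**2 / (vi**2 / (ns[i] - 1.0) + vj**2 / (ns[j] - 1.0))
    return idx, q, df


def games_howell(
    groups: list[GroupSample],
    labels: list[str] | None = None,
    alpha: float = 0.05,
) -> list[PairScreenResult]:
    """Games-Howell post hoc test on all unordered pairs.

    Unequal-variance standard errors, Welch-Satterthwaite per-pair df,
    p-values from the studentized range distribution with k groups.
    """
    if len(groups) < 2:
        raise InvalidInputError("Games-Howell needs at least two groups")
    if labels is None:
        labels = [str(i) for i in range(len(groups))]
    if len(labels) != len(groups):
        raise InvalidInputError("labels must match groups")
    means, variances, ns = _moments(groups)
    if np.any(variances == 0.0):
        raise DegenerateVarianceError("zero-variance group in Games-Howell")
    k = len(groups)
    idx, q, df = _gh_stats(means, variances, ns)
    p = stats.studentized_range.sf(q, k, df)
    return [
        PairScreenResult(
            pair=(labels[a], labels[b]),
            statistic=float(qv),
            p_value=float(np.clip(pv, 0.0, 1.0)),
            df=float(d),
            significant=bool(pv <= alpha),
        )
        for (a, b), qv, pv, d in zip(idx, q, p, df)
    ]


def select_max_difference_pair(screen: list[PairScreenResult]) -> tuple[str, str]:
    """Pair with the greatest statistical difference.

    Smallest p-value; ties broken by largest |statistic|, then by
    lexicographic condition ids. Significance is never required — the
    extreme pair of a null screen is still returned.
    """
    if not screen:
        raise InvalidInputError("empty screen")
    best = min(
        screen,
        key=lambda r: (r.p_value, -abs(r.statistic), tuple(sorted(r.pair))),
    )
    return best.pair


def compute_espi(
    a: ConditionGroup,
    b: ConditionGroup,
    exact: bool = True,
    ci_level: float = 0.95,
    screen_p: float = float("nan"),
    distance_fn=euclidean_distance,
) -> EspiResult:
    """*ESPI between two condition groups.

    espi = |g| / distance on normalized environmental coordinates.
    The g-confidence interval is mapped to the index scale by the same
    positive constant 1/distance (the environmental coordinates are
    design levels, treated as known); when g < 0 the interval is
    mirrored together with the numerator. ``distance_fn`` swaps in an
    alternative metric (e.g. Mahalanobis) on the same points.
    """
    dist = distance_fn(a.env, b.env)
    if dist == 0.0:
        raise ZeroDistanceError(
            f"conditions {(a.condition_id, b.condition_id)} share environmental "
            "coordinates; *ESPI undefined",
            (a.condition_id, b.condition_id),
        )
    eff = hedges_g(a.sample, b.sample, exact=exact, ci_level=ci_level)
    if eff.g >= 0:
        lo, hi = eff.ci_low, eff.ci_high
    else:
        lo, hi = -eff.ci_high, -eff.ci_low
    return EspiResult(
        trait=a.trait,
        time=a.time,
        pair=(a.condition_id, b.condition_id),
        g=eff.g,
        effect=eff,
        distance=dist,
        espi=abs(eff.g) / dist,
        espi_ci_low=lo / dist,
        espi_ci_high=hi / dist,
        screen_p=screen_p,
    )


def original_espi(X: float, x: float, E: float, e: float) -> float:
    """Classical one-dimensional plasticity index (X - x) / (E - e).

    X and x are the extreme phenotypic values and E, e their raw
    environmental values. Deliberately scale-dependent: it is the
    baseline the standardized index is compared against.
    """
    if E == e:
        raise ZeroDistanceError("environmental values coincide; index undefined")
    return (X - x) / (E - e)


def _analyze_cell(
    groups: list[ConditionGroup], alpha, exact, ci_level, distance_fn
) -> EspiResult:
    trait, time = groups[0].trait, groups[0].time

    def failed(reason, pair=("", "")):
        nan = float("nan")
        return EspiResult(
            trait=trait, time=time, pair=pair, g=nan, effect=None,
            distance=nan, espi=nan, espi_ci_low=nan, espi_ci_high=nan,
            screen_p=nan, error=reason,
        )

    usable = [g for g in groups if g.sample.sd > 0.0]
    dropped = len(groups) - len(usable)
    if dropped:
        _log.warning(
            "trait=%s time=%s: dropped %d zero-variance condition(s)",
            trait, time, dropped,
        )
    if len(usable) < 2:
        return failed("fewer than two conditions with nonzero variance")
    labels = [g.condition_id for g in usable]
    screen = games_howell([g.sample for g in usable], labels, alpha=alpha)
    pair = select_max_difference_pair(screen)
    by_id = {g.condition_id: g for g in usable}
    a, b = by_id[pair[0]], by_id[pair[1]]
    screen_p = next(r.p_value for r in screen if r.pair == pair)
    try:
        return compute_espi(
            a, b, exact=exact, ci_level=ci_level, screen_p=screen_p,
            distance_fn=distance_fn,
        )
    except ZeroDistanceError:
        return failed("selected pair has zero environmental distance", pair)


def espi_time_series(
    data: list[ConditionGroup],
    alpha: float = 0.05,
    exact: bool = True,
    ci_level: float = 0.95,
    distance_fn=euclidean_distance,
) -> list[EspiResult]:
    """Run the full screen-select-standardize workflow per trait x time.

    Cells that cannot be analyzed (all-constant groups, coincident
    environments) yield an :class:`EspiResult` with ``error`` set
    instead of aborting the run. Output is ordered by (trait, time).
    """
    cells: dict[tuple, list[ConditionGroup]] = {}
    for g in data:
        cells.setdefault((g.trait, g.time), []).append(g)
    results = []
    for key in sorted(cells, key=lambda k: (str(k[0]), str(k[1]))):
        results.append(
            _analyze_cell(cells[key], alpha, exact, ci_level, distance_fn)
        )
    return results


def fit_gaussian_time(series, espis=None) -> GaussianFit:
    """Least-squares Gaussian fit to an index-versus-time series.

    Accepts ``[(time, value), ...]`` or two arrays. Initialization is
    deterministic: amplitude at the series maximum, peak at its time,
    width half the time span. A fitted width larger than ten times the
    observed span flags the fit as ill-conditioned (e.g. a constant
    series carries no peak information).
    """
    if espis is None:
        arr = np.asarray(list(series), dtype=float)
        t, y = arr[:, 0], arr[:, 1]
    else:
        t = np.asarray(list(series), dtype=float)
        y = np.asarray(list(espis), dtype=float)
    if t.size < 4:
        raise InvalidInputError("Gaussian fit needs at least 4 time points")
    span = float(t.max() - t.min())
    p0 = (float(y.max()), float(t[np.argmax(y)]), max(span / 2.0, 1e-6))

    def model(tt, a, mu, sigma):
        return a * np.exp(-((tt - mu) ** 2) / (2.0 * sigma**2))

    try:
        popt, _ = optimize.curve_fit(model, t, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitConvergenceError(
            f"Gaussian fit did not converge from p0={p0}: {exc}", p0=p0
        ) from exc
    a, mu, sigma = popt
    sigma = abs(float(sigma))
    rss = float(np.sum((y - model(t, a, mu, sigma)) ** 2))
    return GaussianFit(
        amplitude=float(a),
        peak_time=float(mu),
        width=sigma,
        rss=rss,
        ill_conditioned=bool(sigma > 10.0 * max(span, 1e-12)),
    )
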