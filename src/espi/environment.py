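"""Environmental-space geometry.

Conditions live in an n-dimensional space of numeric environmental axes
(temperature, irradiance, nutrient load, ...). Each axis is min-max
normalized to [0, 1] *within the experiment* — the reference set is the
conditions actually present — so that Euclidean distances between
conditions are invariant to the raw units of every axis. Distances
therefore range from 0 to sqrt(n_axes), and cross-study comparisons
must report the axis count and ranges used (both are recorded on the
space and echoed into result files).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = [
    "EnvironmentSpace",
    "EnvPoint",
    "build_space",
    "euclidean_distance",
    "mahalanobis_distance",
]


@dataclass(frozen=True)
class EnvironmentSpace:
    """Per-axis min/max of an experiment's environmental design.

    Axis order is fixed at construction and carried into every point and
    output derived from the space.
    """

    axis_names: tuple[str, ...]
    axis_min: np.ndarray
    axis_max: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.axis_min, dtype=float)
        hi = np.asarray(self.axis_max, dtype=float)
        names = tuple(self.axis_names)
        if not (lo.shape == hi.shape == (len(names),)):
            raise InvalidInputError("axis_min/axis_max must match axis_names")
        const = np.flatnonzero(~(hi > lo))
        if const.size:
            bad = ", ".join(names[i] for i in const)
            raise InvalidInputError(
                f"environmental axis has no variation across conditions: {bad}"
            )
        object.__setattr__(self, "axis_names", names)
        object.__setattr__(self, "axis_min", lo)
        object.__setattr__(self, "axis_max", hi)

    @property
    def n_axes(self) -> int:
        return len(self.axis_names)

    def point(self, raw) -> "EnvPoint":
        """Normalize raw coordinates (array or {axis: value} mapping)."""
        if isinstance(raw, dict):
            missing = set(self.axis_names) - raw.keys()
            if missing:
                raise InvalidInputError(f"missing axes: {sorted(missing)}")
            raw = [raw[name] for name in self.axis_names]
        arr = np.asarray(raw, dtype=float)
        if arr.shape != (self.n_axes,):
            raise InvalidInputError(
                f"expected {self.n_axes} coordinates, got shape {arr.shape}"
            )
        normalized = (arr - self.axis_min) / (self.axis_max - self.axis_min)
        return EnvPoint(space=self, raw=arr, normalized=normalized)


@dataclass(frozen=True)
class EnvPoint:
    """A condition's coordinates, raw and min-max normalized."""

    space: EnvironmentSpace
    raw: np.ndarray
    normalized: np.ndarray


def build_space(conditions, axis_names=None) -> EnvironmentSpace:
    """Build an :class:`EnvironmentSpace` from a table of condition coordinates.

    Parameters
    ----------
    conditions
        DataFrame (one row per condition, one column per axis) or a 2-D
        array with ``axis_names`` given separately. Min and max are taken
        over the conditions present, not over hypothetical design ranges.
    """
    if isinstance(conditions, pd.DataFrame):
        axis_names = tuple(map(str, conditions.columns))
        values = conditions.to_numpy(dtype=float)
    else:
        values = np.asarray(conditions, dtype=float)
        if axis_names is None:
            raise InvalidInputError("axis_names required for array input")
        axis_names = tuple(axis_names)
    if values.ndim != 2 or values.shape[1] != len(axis_names):
        raise InvalidInputError("conditions must be 2-D with one column per axis")
    if values.shape[0] < 2:
        raise InvalidInputError("at least two conditions are required")
    return EnvironmentSpace(
        axis_names=axis_names,
        axis_min=values.min(axis=0),
        axis_max=values.max(axis=0),
    )


def euclidean_distance(p: EnvPoint, q: EnvPoint) -> float:
    """Euclidean distance on normalized coordinates.

    Both points must come from the same space (same axes in the same
    order). The result lies in [0, sqrt(n_axes)].
    """
    if p.space.axis_names != q.space.axis_names:
        raise InvalidInputError(
            f"points live in different spaces: {p.space.axis_names} "
            f"vs {q.space.axis_names}"
        )
    return float(np.linalg.norm(p.normalized - q.normalized))


def mahalanobis_distance(p: EnvPoint, q: EnvPoint, conditions) -> float:
    """Mahalanobis distance on normalized coordinates.

    Optional alternative metric that discounts correlated axes. The
    covariance is estimated from the normalized coordinates of the
    conditions table given (usually all conditions of the experiment);
    a pseudo-inverse is used so rank-deficient designs degrade to the
    metric on the spanned subspace instead of failing.
    """
    if p.space.axis_names != q.space.axis_names:
        raise InvalidInputError("points live in different spaces")
    space = p.space
    if isinstance(conditions, pd.DataFrame):
        conditions = conditions[list(space.axis_names)].to_numpy(dtype=float)
    raw = np.asarray(conditions, dtype=float)
    norm = (raw - space.axis_min) / (space.axis_max - space.axis_min)
    cov = np.cov(norm, rowvar=False)
    vi = np.linalg.pinv(np.atleast_2d(cov))
    diff = p.normalized - q.normalized
    return float(np.sqrt(diff @ vi @ diff))
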