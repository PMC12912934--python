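"""Tidy-data ingestion, result serialization and run configuration.

The only input dialect is long ("tidy") format: one measured replicate
per row, with columns naming the trait, the measured value, the
condition identifier, an optional time point, and one column per
environmental axis. A thin ``melt_wide`` helper converts wide exports;
plate-map parsing is out of scope.

Result CSVs carry a commented header (lines starting with ``#``)
recording the config hash, seed, and the environmental axis names and
raw ranges, so that any cross-study comparison can be caveated with the
exact axis count and type used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .effect_size import GroupSample
from .environment import EnvironmentSpace, build_space
from .exceptions import InvalidInputError
from .pipeline import ConditionGroup, EspiResult

_log = logging.getLogger(__name__)

__all__ = [
    "ColumnMapping",
    "RunConfig",
    "load_tidy_table",
    "results_frame",
    "write_results",
    "melt_wide",
    "load_run_config",
]


@dataclass(frozen=True)
class ColumnMapping:
    """Names of the tidy-table columns holding each role."""

    trait: str = "trait"
    value: str = "value"
    condition: str = "condition_id"
    time: str | None = "day"
    env: tuple[str, ...] = ()


@dataclass(frozen=True)
class RunConfig:
    """Everything one analysis run depends on (for provenance hashing)."""

    data: str = ""
    columns: ColumnMapping = field(default_factory=ColumnMapping)
    alpha: float = 0.05
    ci_level: float = 0.95
    correction: str = "exact"  # or "approx"
    metric: str = "euclidean"  # or "mahalanobis"
    seed: int = 0
    out: str = "results.csv"
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0 or not 0.0 < self.ci_level < 1.0:
            raise InvalidInputError("alpha and ci_level must lie in (0, 1)")
        if self.correction not in ("exact", "approx"):
            raise InvalidInputError("correction must be 'exact' or 'approx'")
        if self.metric not in ("euclidean", "mahalanobis"):
            raise InvalidInputError("metric must be 'euclidean' or 'mahalanobis'")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def load_run_config(path) -> RunConfig:
    """Read a YAML or JSON run configuration."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    cols = raw.pop("columns", {})
    if isinstance(cols, dict):
        cols["env"] = tuple(cols.get("env", ()))
        raw["columns"] = ColumnMapping(**cols)
    return RunConfig(**raw)


def load_tidy_table(
    source, mapping: ColumnMapping
) -> tuple[list[ConditionGroup], EnvironmentSpace]:
    """Read a tidy table into validated condition groups.

    ``source`` is a CSV/TSV path or an existing DataFrame. Rows with a
    missing trait value are dropped (the count is logged). Every
    condition must map to exactly one set of environmental coordinates;
    groups left with fewer than 2 replicates are skipped with a log
    entry rather than failing the run.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        path = Path(source)
        if not path.exists():
            raise InvalidInputError(f"input file not found: {path}")
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep, comment="#")

    needed = [mapping.trait, mapping.value, mapping.condition, *mapping.env]
    if mapping.time is not None:
        needed.append(mapping.time)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise InvalidInputError(f"missing required column(s): {missing}")
    if not mapping.env:
        raise InvalidInputError("at least one environmental axis column is required")

    n_before = len(df)
    df = df[pd.to_numeric(df[mapping.value], errors="coerce").notna()].copy()
    df[mapping.value] = df[mapping.value].astype(float)
    if len(df) < n_before:
        _log.info("dropped %d row(s) with missing trait values", n_before - len(df))

    # one environment per condition, across all traits/times
    env_cols = list(mapping.env)
    coords = df[[mapping.condition, *env_cols]].drop_duplicates()
    dup = coords[mapping.condition].duplicated(keep=False)
    if dup.any():
        bad = sorted(coords.loc[dup, mapping.condition].unique())
        raise InvalidInputError(
            f"condition(s) mapped to multiple environmental coordinates: {bad}"
        )
    coords = coords.set_index(mapping.condition)
    space = build_space(coords[env_cols])
    points = {
        cid: space.point(row.to_numpy(dtype=float))
        for cid, row in coords.iterrows()
    }

    keys = [mapping.trait, mapping.condition]
    if mapping.time is not None:
        keys.insert(1, mapping.time)
    groups = []
    for key, sub in df.groupby(keys, sort=True):
        trait = key[0]
        time = key[1] if mapping.time is not None else None
        cid = key[-1]
        values = sub[mapping.value].to_numpy(dtype=float)
        if values.size < 2:
            _log.warning(
                "skipping trait=%s time=%s condition=%s: fewer than 2 replicates",
                trait, time, cid,
            )
            continue
        groups.append(
            ConditionGroup(
                condition_id=str(cid),
                sample=GroupSample.from_values(values),
                env=points[cid],
                trait=str(trait),
                time=time,
            )
        )
    return groups, space


_RESULT_COLUMNS = [
    "trait", "time", "condition_a", "condition_b", "g", "se",
    "g_ci_low", "g_ci_high", "distance", "espi",
    "espi_ci_low", "espi_ci_high", "screen_p", "error",
]


def results_frame(results: list[EspiResult]) -> pd.DataFrame:
    """Flatten pipeline results to a table with a stable column order."""
    rows = []
    for r in results:
        rows.append(
            {
                "trait": r.trait,
                "time": r.time,
                "condition_a": r.pair[0],
                "condition_b": r.pair[1],
                "g": r.g,
                "se": r.effect.se if r.effect else np.nan,
                "g_ci_low": r.effect.ci_low if r.effect else np.nan,
                "g_ci_high": r.effect.ci_high if r.effect else np.nan,
                "distance": r.distance,
                "espi": r.espi,
                "espi_ci_low": r.espi_ci_low,
                "espi_ci_high": r.espi_ci_high,
                "screen_p": r.screen_p,
                "error": r.error or "",
            }
        )
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def write_results(
    results: list[EspiResult],
    path,
    space: EnvironmentSpace | None = None,
    config: RunConfig | None = None,
) -> None:
    """Write results as CSV with a provenance header.

    Header comment lines record the config hash, seed, and each axis
    with its raw min/max — the metadata needed to caveat any
    cross-study comparison of the index.
    """
    path = Path(path)
    lines = []
    if config is not None:
        lines.append(f"# config_hash: {config.hash()}")
        lines.append(f"# seed: {config.seed}")
    if space is not None:
        lines.append(f"# n_axes: {space.n_axes}")
        for name, lo, hi in zip(space.axis_names, space.axis_min, space.axis_max):
            lines.append(f"# axis: {name} min={lo:g} max={hi:g}")
    frame = results_frame(results)
    with path.open("w") as fh:
        for line in lines:
            fh.write(line + "\n")
        frame.to_csv(fh, index=False)


def melt_wide(df: pd.DataFrame, id_vars, value_name="value", var_name="trait"):
    """Convenience wrapper to melt wide exports into the tidy dialect."""
    return df.melt(id_vars=id_vars, value_name=value_name, var_name=var_name)
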