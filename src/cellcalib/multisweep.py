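"""Two-parameter multilevel grid search against target data.

The sweep minimizes an error metric between black-box output and a target
vector over a sequence of refining grids.  Each level lays an
``n × n`` grid over the box ``center · (1 ± percent)`` per axis (endpoints
inclusive, clipped below at the parameter's lower bound), evaluates the
black box at every grid cell, and recenters the next level on the best cell
while shrinking ``percent`` geometrically (``percent_k = percent_0 ·
shrink_factor^k``).  Grid search needs no gradients, which suits stochastic
agent-based simulators where finite-difference gradients are unreliable.

Every grid cell is evaluated with the same base seed (common random
numbers), so for a runner that is deterministic given its seed the error
surface is a deterministic function of the parameters and the whole sweep is
bitwise reproducible.  A failed simulation scores ``+inf`` rather than
aborting the level.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .blackbox import BlackBoxError, BlackBoxModel, run_model
from .config_io import ConfigError
from .quantify import METRICS, TargetData

__all__ = [
    "SweepError",
    "SweepConfig",
    "GridLevel",
    "SweepResult",
    "build_grid",
    "run_level",
    "run_sweep",
    "load_sweep_yaml",
    "save_heatmap",
]

_AGGREGATIONS = {"mean": np.mean, "median": np.median}


class SweepError(Exception):
    """Sweep-level failure (e.g. every cell of a grid failed)."""


class SweepConfig(BaseModel):
    """Settings for a two-parameter multilevel sweep.

    ``param_names`` are black-box parameter names (dotted settings paths for
    external simulators, plain names for in-process fixture models);
    ``initial_point`` is the level-0 grid center; ``percent_per_direction``
    the half-width of the search box as a fraction of the center value.
    """

    param_names: tuple[str, str]
    initial_point: tuple[float, float]
    points_per_direction: int = Field(ge=1)
    percent_per_direction: float = Field(gt=0, le=1)
    n_levels: int = Field(ge=1, default=1)
    shrink_factor: float = Field(gt=0, lt=1, default=0.5)
    lower_bounds: tuple[float, float] = (0.0, 0.0)
    error_metric: str = "sse"
    replicate_aggregation: str = "mean"

    @field_validator("param_names")
    @classmethod
    def _distinct(cls, v):
        if v[0] == v[1]:
            raise ValueError("param_names must be distinct")
        return v

    @field_validator("error_metric")
    @classmethod
    def _known_metric(cls, v):
        if v not in METRICS:
            raise ValueError(f"unknown error metric {v!r}; choose from {sorted(METRICS)}")
        return v

    @field_validator("replicate_aggregation")
    @classmethod
    def _known_aggregation(cls, v):
        if v not in _AGGREGATIONS:
            raise ValueError(f"unknown aggregation {v!r}; choose from {sorted(_AGGREGATIONS)}")
        return v


@dataclass
class GridLevel:
    """One evaluated grid: its geometry, per-cell errors and best cell."""

    index: int
    center: dict[str, float]
    percent: float
    axis_values: tuple[np.ndarray, np.ndarray]
    cells: list[tuple[dict[str, float], float]]
    best: tuple[dict[str, float], float]


@dataclass
class SweepResult:
    """Full audit trail of a sweep: every level, the final estimate and the
    trajectory of grid centers."""

    levels: list[GridLevel]
    estimate: dict[str, float]
    trajectory: list[dict[str, float]]

    @property
    def best_error(self) -> float:
        return self.levels[-1].best[1]


def build_grid(
    center: Sequence[float],
    percent: float,
    n: int,
    lower_bounds: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Axis values for one grid level.

    Per axis: ``n`` values linearly spaced over ``[c·(1−percent),
    c·(1+percent)]``, endpoints inclusive, clipped below at the lower bound.
    ``n = 1`` returns just the center.  An axis whose values all clip to one
    point collapses to a single value with a warning.
    """
    if n < 1:
        raise ValueError("points per direction must be >= 1")
    if not 0 < percent <= 1:
        raise ValueError("percent per direction must be in (0, 1]")
    if lower_bounds is None:
        lower_bounds = (-np.inf, -np.inf)
    axes = []
    for c, lb in zip(center, lower_bounds):
        if n == 1:
            axes.append(np.array([float(c)]))
            continue
        axis = np.linspace(c * (1 - percent), c * (1 + percent), n)
        axis = np.maximum(axis, lb)
        if np.all(axis == axis[0]):
            warnings.warn(
                f"grid axis at center {c} collapsed to the single value {axis[0]} "
                f"after clipping at {lb}",
                stacklevel=2,
            )
            axis = axis[:1]
        axes.append(axis)
    return axes[0], axes[1]


def _aggregate(metrics: list, how: str) -> np.ndarray:
    stacked = np.stack([np.asarray(m, dtype=float) for m in metrics])
    return _AGGREGATIONS[how](stacked, axis=0)


def run_level(
    model: BlackBoxModel,
    param_names: Sequence[str],
    axes: tuple[np.ndarray, np.ndarray],
    target: TargetData,
    seed: int = 0,
    *,
    error_metric: str = "sse",
    replicate_aggregation: str = "mean",
    index: int = 0,
    percent: float = 0.0,
    center: dict[str, float] | None = None,
) -> GridLevel:
    """Evaluate every cell of one grid and return the level with its best cell.

    Cells are visited in row-major order (first axis outermost); the best
    cell is the strict argmin, with ties broken by visiting order.  A cell
    whose simulation fails scores ``+inf`` with a warning; if every cell
    fails the level raises :class:`SweepError`.
    """
    name1, name2 = param_names
    metric_fn = METRICS[error_metric]
    cells: list[tuple[dict[str, float], float]] = []
    for v1 in axes[0]:
        for v2 in axes[1]:
            params = {name1: float(v1), name2: float(v2)}
            try:
                metrics = run_model(model, params, seed=seed)
                aggregated = _aggregate(metrics, replicate_aggregation)
                error = float(metric_fn(aggregated, target))
            except (BlackBoxError, ConfigError, ValueError) as exc:
                warnings.warn(
                    f"simulation failed at {params}: {exc}", stacklevel=2
                )
                error = float("inf")
            cells.append((params, error))
    errors = np.array([e for _, e in cells])
    if not np.any(np.isfinite(errors)):
        raise SweepError("every grid cell failed to evaluate")
    best_i = int(np.argmin(errors))  # first minimum in row-major order
    if center is None:
        center = {name1: float(np.mean(axes[0])), name2: float(np.mean(axes[1]))}
    return GridLevel(
        index=index,
        center=center,
        percent=percent,
        axis_values=axes,
        cells=cells,
        best=cells[best_i],
    )


def run_sweep(
    model: BlackBoxModel,
    config: SweepConfig,
    target: TargetData,
    seed: int = 0,
    out_dir: str | Path | None = None,
    heatmaps: bool = False,
) -> SweepResult:
    """Run the full multilevel sweep and return its audit trail.

    Level ``k+1`` is centered on level ``k``'s best cell with search width
    ``percent_per_direction · shrink_factor^(k+1)``; the estimate is the
    best cell of the last level.  With ``out_dir`` set, each level's grid is
    persisted as ``level_<k>_grid.csv`` plus ``level_<k>_best.json``, the
    final estimate as ``estimate.json``, and (optionally) a PNG error
    heatmap per level.
    """
    name1, name2 = config.param_names
    center = {name1: config.initial_point[0], name2: config.initial_point[1]}
    percent = config.percent_per_direction
    levels: list[GridLevel] = []
    trajectory: list[dict[str, float]] = [dict(center)]
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    for k in range(config.n_levels):
        axes = build_grid(
            (center[name1], center[name2]),
            percent,
            config.points_per_direction,
            config.lower_bounds,
        )
        level = run_level(
            model,
            config.param_names,
            axes,
            target,
            seed=seed,
            error_metric=config.error_metric,
            replicate_aggregation=config.replicate_aggregation,
            index=k,
            percent=percent,
            center=dict(center),
        )
        levels.append(level)
        if out_path is not None:
            _persist_level(level, config, out_path, heatmaps)
        center = dict(level.best[0])
        trajectory.append(dict(center))
        percent *= config.shrink_factor

    estimate = dict(levels[-1].best[0])
    result = SweepResult(levels=levels, estimate=estimate, trajectory=trajectory)
    if out_path is not None:
        payload = {
            "estimate": estimate,
            "error": levels[-1].best[1],
            "n_levels": len(levels),
        }
        (out_path / "estimate.json").write_text(json.dumps(payload, indent=2))
    return result


def _persist_level(
    level: GridLevel, config: SweepConfig, out_path: Path, heatmaps: bool
) -> None:
    name1, name2 = config.param_names
    frame = pd.DataFrame(
        [(p[name1], p[name2], e) for p, e in level.cells],
        columns=[name1, name2, "error"],
    )
    frame.to_csv(out_path / f"level_{level.index}_grid.csv", index=False)
    best_params, best_error = level.best
    (out_path / f"level_{level.index}_best.json").write_text(
        json.dumps({"params": best_params, "error": best_error}, indent=2)
    )
    if heatmaps:
        save_heatmap(level, (name1, name2), out_path / f"level_{level.index}_heatmap.png")


def save_heatmap(
    level: GridLevel, param_names: Sequence[str], path: str | Path
) -> Path:
    """Export one level's error surface as a PNG heatmap."""
    from matplotlib.figure import Figure

    ax1, ax2 = level.axis_values
    errors = np.array([e for _, e in level.cells]).reshape(len(ax1), len(ax2))
    fig = Figure(figsize=(5, 4))
    ax = fig.add_subplot()
    mesh = ax.pcolormesh(ax2, ax1, errors, shading="nearest")
    fig.colorbar(mesh, ax=ax, label="error")
    ax.set_xlabel(param_names[1])
    ax.set_ylabel(param_names[0])
    ax.set_title(f"level {level.index}")
    path = Path(path)
    fig.savefig(path, dpi=100, bbox_inches="tight")
    return path


def load_sweep_yaml(path: str | Path) -> tuple[SweepConfig, dict]:
    """Load a sweep YAML file.

    Keys mirror :class:`SweepConfig` fields; extra keys (``target: {file:
    ...}``, ``config``, ``replicates``) are returned in the extras dict for
    the caller to wire up.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SweepError(f"sweep file {path} must be a YAML mapping")
    known = set(SweepConfig.model_fields)
    config = SweepConfig(**{k: v for k, v in raw.items() if k in known})
    extras = {k: v for k, v in raw.items() if k not in known}
    return config, extras
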