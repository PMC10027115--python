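"""Reduce simulation output snapshots to metric vectors, and error metrics.

Snapshots use a plain tabular dialect: one CSV per saved time point with
header ``id,x,y,z`` (one row per cell, positions in µm), optionally
accompanied by ``substrate_<name>.csv`` files (``i,j,k,value``) holding a
substance concentration field on the voxel grid.  Snapshot order within an
output directory is lexicographic filename order, which matches zero-padded
output numbering.

The calibration objective is the summed squared error (SSE),
``sum((s_i - t_i)^2)``.  For population snapshots with no natural pairing
between simulated and target cells (e.g. final cell coordinates), use
:func:`quantile_sse`, which sorts both samples (equal sizes) or reduces both
to 21 empirical quantiles (unequal sizes) before summing — a
permutation-invariant quantile-matching comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnapshotError",
    "Snapshot",
    "TargetData",
    "read_snapshot",
    "read_substrate",
    "list_snapshots",
    "final_cell_count",
    "final_coordinates",
    "cell_count_series",
    "sse",
    "quantile_sse",
    "METRICS",
    "read_target",
]

_REQUIRED_COLUMNS = ("id", "x", "y", "z")


class SnapshotError(Exception):
    """Snapshot file missing, malformed, or schema-violating."""


@dataclass
class Snapshot:
    """One saved simulation state: a cell table and optional substance field."""

    cells: pd.DataFrame  # columns id, x, y, z
    time: float | None = None
    substrate: pd.DataFrame | None = None  # columns i, j, k, value

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class TargetData:
    """The reference vector a calibration minimizes error against."""

    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("target data must be non-empty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("target data must be finite")


def read_snapshot(path: str | Path) -> Snapshot:
    """Parse one cell-snapshot CSV (header ``id,x,y,z``).

    An empty table (header only) is valid — e.g. every cell died.  A missing
    required column or a non-numeric coordinate raises
    :class:`SnapshotError` naming the column.
    """
    path = Path(path)
    if not path.exists():
        raise SnapshotError(f"snapshot file not found: {path}")
    cells = pd.read_csv(path)
    for col in _REQUIRED_COLUMNS:
        if col not in cells.columns:
            raise SnapshotError(f"{path.name}: missing required column {col!r}")
    for col in ("x", "y", "z"):
        values = pd.to_numeric(cells[col], errors="coerce")
        if values.isna().any() and len(cells):
            raise SnapshotError(f"{path.name}: non-numeric values in column {col!r}")
        cells[col] = values.astype(float)
    time = float(cells["time"].iloc[0]) if "time" in cells.columns and len(cells) else None
    return Snapshot(cells=cells, time=time)


def read_substrate(path: str | Path) -> pd.DataFrame:
    """Parse a substance-field CSV with columns ``i,j,k,value``."""
    path = Path(path)
    field = pd.read_csv(path)
    for col in ("i", "j", "k", "value"):
        if col not in field.columns:
            raise SnapshotError(f"{path.name}: missing required column {col!r}")
    return field


def list_snapshots(output_dir: str | Path) -> list[Path]:
    """Cell-snapshot files in ``output_dir``, lexicographic order."""
    output_dir = Path(output_dir)
    if not output_dir.is_dir():
        raise SnapshotError(f"output directory not found: {output_dir}")
    paths = sorted(
        p
        for p in output_dir.iterdir()
        if p.suffix == ".csv" and not p.name.startswith("substrate_")
    )
    if not paths:
        raise SnapshotError(f"no snapshot files in {output_dir}")
    return paths


def _last_snapshot(output_dir: str | Path) -> Snapshot:
    return read_snapshot(list_snapshots(output_dir)[-1])


def final_cell_count(output_dir: str | Path) -> int:
    """Number of cells in the last snapshot of a run."""
    return _last_snapshot(output_dir).n_cells


def final_coordinates(output_dir: str | Path, axis: str = "y") -> np.ndarray:
    """The ``axis`` coordinate of every cell in the last snapshot, in cell-id order."""
    if axis not in ("x", "y", "z"):
        raise ValueError(f"axis must be one of x, y, z (got {axis!r})")
    cells = _last_snapshot(output_dir).cells
    return cells.sort_values("id")[axis].to_numpy(dtype=float)


def cell_count_series(output_dir: str | Path) -> np.ndarray:
    """Cell count of every snapshot in order — a population growth curve."""
    return np.array(
        [read_snapshot(p).n_cells for p in list_snapshots(output_dir)], dtype=float
    )


# ---------------------------------------------------------------------------
# Error metrics


def _target_values(target) -> np.ndarray:
    if isinstance(target, TargetData):
        return target.values
    return np.asarray(target, dtype=float)


def sse(simulated: Sequence[float], target) -> float:
    """Summed squared error between two equal-length vectors."""
    s = np.asarray(simulated, dtype=float)
    t = _target_values(target)
    if s.shape != t.shape:
        raise ValueError(
            f"length mismatch: simulated {s.shape} vs target {t.shape}"
        )
    return float(np.sum((s - t) ** 2))


def quantile_sse(simulated: Sequence[float], target) -> float:
    """Permutation-invariant SSE for unpaired samples.

    Equal sizes: both samples sorted ascending, then SSE (quantile matching).
    Unequal sizes: both reduced to 21 empirical quantiles (0, 5, ..., 100%).
    """
    s = np.sort(np.asarray(simulated, dtype=float))
    t = np.sort(_target_values(target))
    if s.size != t.size:
        q = np.linspace(0.0, 1.0, 21)
        s = np.quantile(s, q)
        t = np.quantile(t, q)
    return float(np.sum((s - t) ** 2))


METRICS = {"sse": sse, "quantile_sse": quantile_sse, "sorted_sse": quantile_sse}


def read_target(path: str | Path) -> TargetData:
    """Read target data from a single-column CSV with an optional header."""
    path = Path(path)
    raw = pd.read_csv(path, header=None)
    first = raw.iloc[0, 0]
    try:
        float(first)
    except (TypeError, ValueError):
        raw = raw.iloc[1:]
    values = pd.to_numeric(raw.iloc[:, 0], errors="raise").to_numpy(dtype=float)
    return TargetData(values=values)
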