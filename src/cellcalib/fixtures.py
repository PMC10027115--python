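"""Self-contained fixture models: every pipeline stage is testable without
an external simulator.

Two reference problems are provided.

* **Logistic growth** — the population curve
  ``N(t) = K·N0 / (N0 + (K − N0)·exp(−r·t))`` with carrying capacity ``K``,
  initial population ``N0`` and proliferation rate ``r``.  Deterministic, so
  calibration against a target curve generated from known ``(r, K)`` has an
  exact global optimum.
* **Chemotaxis** — a biased persistent random walk in a static linear
  gradient pointing in +y.  Each cell's heading blends a persistent random
  unit vector ``ξ`` (re-drawn with probability ``dt/τ`` per step) with the
  unit gradient direction, weighted by the migration bias ``b ∈ [0, 1]``:
  ``d = normalize((1 − b)·ξ + b·ĝ)``; displacement is ``speed·d·dt`` and
  positions are clamped to the domain walls.  ``b = 0`` is a pure
  persistent random walk, ``b = 1`` deterministic gradient following.  All
  random draws are made up front from the scenario seed, so with a fixed
  seed the final positions vary smoothly with ``(speed, b)`` — a common-
  random-numbers scheme that makes grid calibration well behaved.

The fixtures deliberately omit the mechanics a full cell-based simulator
would add (reaction-diffusion of the attractant, cell-cell forces, volume
and cycle dynamics): they exist to exercise the calibration machinery, not
to model biology.  A mock executable honoring the external-runner contract
(``<exe> <settings.xml>`` in a workspace, snapshots under ``output/``) and a
settings-file writer complete the end-to-end test surface.
"""

from __future__ import annotations

import dataclasses
import os
import stat
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .blackbox import BlackBoxModel
from .quantify import TargetData

__all__ = [
    "LogisticParams",
    "ChemotaxisScenario",
    "logistic_growth",
    "simulate_chemotaxis",
    "make_logistic_model",
    "make_chemotaxis_model",
    "make_raw_xml_updater",
    "make_mock_executable",
    "generate_target",
    "write_fixture_settings",
    "DEFAULT_TIME_GRID",
]

#: Default observation grid for the logistic fixture: t = 0..100 min, step 1.
DEFAULT_TIME_GRID = np.arange(0.0, 101.0, 1.0)


@dataclass
class LogisticParams:
    """Parameters of the logistic growth curve."""

    K: float  # carrying capacity (agents)
    r: float  # proliferation rate (1/min)
    N0: float = 10.0  # initial population (agents)
    t_grid: np.ndarray = field(default_factory=lambda: DEFAULT_TIME_GRID.copy())

    def __post_init__(self):
        if self.K <= 0 or self.N0 <= 0 or self.r <= 0:
            raise ValueError("K, N0 and r must all be positive")
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        if self.t_grid.size == 0 or np.any(np.diff(self.t_grid) <= 0):
            raise ValueError("t_grid must be non-empty and strictly increasing")


def logistic_growth(params: LogisticParams) -> np.ndarray:
    """Evaluate ``N(t) = K·N0 / (N0 + (K − N0)·exp(−r·t))`` on the grid."""
    K, N0, r, t = params.K, params.N0, params.r, params.t_grid
    return K * N0 / (N0 + (K - N0) * np.exp(-r * t))


@dataclass
class ChemotaxisScenario:
    """A biased persistent random walk toward a +y attractant source.

    Cells start in a ``start_band``-wide strip along the low-y wall; the
    gradient is static and linear, pointing at the opposite wall.
    """

    speed: float  # µm/min
    migration_bias: float  # dimensionless, in [0, 1]
    n_cells: int = 100
    x_min: float = -250.0  # µm
    x_max: float = 250.0
    y_min: float = -250.0
    y_max: float = 250.0
    start_band: float = 20.0  # µm strip at the low-y wall where cells start
    persistence_time: float = 1.0  # min
    dt: float = 0.1  # min
    duration: float = 120.0  # min
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.migration_bias <= 1.0:
            raise ValueError(f"migration_bias must be in [0, 1], got {self.migration_bias}")
        if min(self.speed, self.persistence_time, self.dt, self.duration) <= 0:
            raise ValueError("speed, persistence_time, dt and duration must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError("domain bounds must satisfy max > min")
        if self.dt > self.persistence_time:
            raise ValueError(
                f"dt ({self.dt}) must not exceed persistence_time "
                f"({self.persistence_time}): persistence discretization unstable"
            )


def simulate_chemotaxis(
    scenario: ChemotaxisScenario, return_initial: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Simulate the walk and return final positions, shape ``(n_cells, 2)``.

    With ``return_initial=True`` returns ``(initial, final)``.  All
    randomness (initial placement, headings, re-draw times) is drawn up
    front from the scenario seed, so the number of RNG draws does not depend
    on speed or bias and results are reproducible and parameter-smooth.
    """
    s = scenario
    rng = np.random.default_rng(s.seed)
    n_steps = int(round(s.duration / s.dt))

    x = rng.uniform(s.x_min, s.x_max, s.n_cells)
    y = s.y_min + rng.uniform(0.0, s.start_band, s.n_cells)
    initial = np.column_stack([x, y]).copy()
    theta = rng.uniform(0.0, 2.0 * np.pi, s.n_cells)
    redraw_u = rng.random((n_steps, s.n_cells))
    redraw_theta = rng.uniform(0.0, 2.0 * np.pi, (n_steps, s.n_cells))

    b = s.migration_bias
    p_redraw = s.dt / s.persistence_time
    step = s.speed * s.dt
    for t in range(n_steps):
        mask = redraw_u[t] < p_redraw
        theta = np.where(mask, redraw_theta[t], theta)
        dx = (1.0 - b) * np.cos(theta)
        dy = (1.0 - b) * np.sin(theta) + b
        norm = np.hypot(dx, dy)
        norm[norm == 0.0] = 1.0  # degenerate cancellation: cell rests this step
        x = np.clip(x + step * dx / norm, s.x_min, s.x_max)
        y = np.clip(y + step * dy / norm, s.y_min, s.y_max)

    final = np.column_stack([x, y])
    return (initial, final) if return_initial else final


# ---------------------------------------------------------------------------
# In-process black-box models


def make_logistic_model(
    t_grid: np.ndarray | None = None, n0: float = 10.0, replicates: int = 1
) -> BlackBoxModel:
    """Logistic growth as an in-process black box.

    Parameters are ``r`` and ``K``; the metric vector is the population
    curve on the observation grid.
    """
    grid = DEFAULT_TIME_GRID.copy() if t_grid is None else np.asarray(t_grid, float)

    def runner(workdir, params, seed=0):
        p = LogisticParams(K=params["K"], r=params["r"], N0=n0, t_grid=grid)
        return logistic_growth(p)

    return BlackBoxModel(runner=runner, replicates=replicates)


def make_chemotaxis_model(
    template: ChemotaxisScenario | None = None, replicates: int = 1
) -> BlackBoxModel:
    """The chemotaxis walk as an in-process black box.

    Parameters are ``speed`` and ``bias``; the metric vector is the final y
    coordinate of every cell.  The replicate seed overrides the template's.
    """
    base = template or ChemotaxisScenario(speed=1.0, migration_bias=0.5)

    def runner(workdir, params, seed=0):
        scenario = dataclasses.replace(
            base, speed=params["speed"], migration_bias=params["bias"], seed=seed
        )
        return simulate_chemotaxis(scenario)[:, 1]

    return BlackBoxModel(runner=runner, replicates=replicates)


def make_raw_xml_updater() -> Callable:
    """Updater whose parameter names are raw XML element paths.

    Unlike :func:`cellcalib.blackbox.make_config_updater` this performs no
    schema validation; it exists to drive elements the schema deliberately
    leaves as passthrough, e.g. ``user_parameters/growth_rate``.
    """
    from lxml import etree

    def updater(config_file: Path, params: dict) -> None:
        tree = etree.parse(str(config_file))
        root = tree.getroot()
        for path, value in params.items():
            el = root.find(path)
            if el is None:
                raise KeyError(f"element {path!r} not found in {config_file}")
            el.text = repr(float(value))
        tree.write(str(config_file), xml_declaration=True, encoding="utf-8")

    return updater


# ---------------------------------------------------------------------------
# Target data


def generate_target(
    model: str, true_params: dict, seed: int = 0, path: str | Path | None = None
) -> TargetData:
    """Generate target data from a fixture model at known true parameters.

    ``logistic`` expects ``{"r": ..., "K": ...}`` and yields the growth
    curve on the default grid; ``chemotaxis`` expects ``{"speed": ...,
    "bias": ...}`` and yields the final y coordinates of one seeded run.
    With ``path`` set the vector is also written as a single-column CSV.
    """
    if model == "logistic":
        params = LogisticParams(K=true_params["K"], r=true_params["r"])
        values = logistic_growth(params)
    elif model == "chemotaxis":
        scenario = ChemotaxisScenario(
            speed=true_params["speed"],
            migration_bias=true_params["bias"],
            seed=seed,
        )
        values = simulate_chemotaxis(scenario)[:, 1]
    else:
        raise ValueError(f"unknown fixture model {model!r}")
    if path is not None:
        np.savetxt(path, values, fmt="%.17g")
    return TargetData(values=values)


# ---------------------------------------------------------------------------
# Fixture settings files

_SETTINGS_TEMPLATE = """<?xml version="1.0" encoding="utf-8"?>
<PhysiCell_settings version="sample">
    <!-- fixture settings file: edits must survive round-tripping -->
    <domain>
        <x_min units="micron">{x_min}</x_min>
        <y_min units="micron">{y_min}</y_min>
        <z_min units="micron">-10</z_min>
        <x_max units="micron">{x_max}</x_max>
        <y_max units="micron">{y_max}</y_max>
        <z_max units="micron">10</z_max>
        <dx units="micron">20</dx>
        <dy units="micron">20</dy>
        <dz units="micron">20</dz>
        <use_2D>true</use_2D>
    </domain>
    <overall>
        <max_time units="min">{max_time}</max_time>
        <time_units>min</time_units>
        <space_units>micron</space_units>
        <dt_diffusion units="min">0.01</dt_diffusion>
        <dt_mechanics units="min">{dt_mechanics}</dt_mechanics>
        <dt_phenotype units="min">6</dt_phenotype>
    </overall>
    <microenvironment_setup>
        <variable name="oxygen" units="mmHg" ID="0">
            <physical_parameter_set>
                <diffusion_coefficient units="micron^2/min">100000.0</diffusion_coefficient>
                <decay_rate units="1/min">0.1</decay_rate>
            </physical_parameter_set>
            <initial_condition units="mmHg">38.0</initial_condition>
            <Dirichlet_boundary_condition units="mmHg" enabled="true">38.0</Dirichlet_boundary_condition>
        </variable>
    </microenvironment_setup>
    <cell_definitions>
        <cell_definition name="default" ID="0">
            <phenotype>
                <cycle code="5" name="live">
                    <phase_transition_rates units="1/min">
                        <rate start_index="0" end_index="0" fixed_duration="false">0.00072</rate>
                    </phase_transition_rates>
                </cycle>
                <death>
                    <model code="100" name="apoptosis">
                        <phase_durations units="min">
                            <duration index="0" fixed_duration="true">516</duration>
                        </phase_durations>
                    </model>
                </death>
                <volume>
                    <total units="micron^3">2494</total>
                    <fluid_fraction units="dimensionless">0.75</fluid_fraction>
                    <nuclear units="micron^3">540</nuclear>
                    <fluid_change_rate units="1/min">0.05</fluid_change_rate>
                    <cytoplasmic_biomass_change_rate units="1/min">0.0045</cytoplasmic_biomass_change_rate>
                    <nuclear_biomass_change_rate units="1/min">0.0055</nuclear_biomass_change_rate>
                    <calcified_fraction units="dimensionless">0.05</calcified_fraction>
                    <calcification_rate units="1/min">0.0042</calcification_rate>
                    <relative_rupture_volume units="dimensionless">2.0</relative_rupture_volume>
                </volume>
                <mechanics>
                    <cell_cell_adhesion_strength units="micron/min">0.4</cell_cell_adhesion_strength>
                    <cell_cell_repulsion_strength units="micron/min">10.0</cell_cell_repulsion_strength>
                    <relative_maximum_adhesion_distance units="dimensionless">1.25</relative_maximum_adhesion_distance>
                </mechanics>
                <motility>
                    <speed units="micron/min">{speed}</speed>
                    <persistence_time units="min">{persistence_time}</persistence_time>
                    <migration_bias units="dimensionless">{migration_bias}</migration_bias>
                    <options>
                        <enabled>true</enabled>
                        <use_2D>true</use_2D>
                        <chemotaxis>
                            <enabled>true</enabled>
                            <substrate>oxygen</substrate>
                            <direction>1</direction>
                        </chemotaxis>
                    </options>
                </motility>
            </phenotype>
            <custom_data>
                <sample units="dimensionless">1.0</sample>
            </custom_data>
        </cell_definition>
    </cell_definitions>
    <user_parameters>
        <random_seed type="int" units="dimensionless">{random_seed}</random_seed>
        <growth_rate type="double" units="1/min">{growth_rate}</growth_rate>
        <carrying_capacity type="double" units="dimensionless">{carrying_capacity}</carrying_capacity>
        <initial_population type="double" units="dimensionless">{initial_population}</initial_population>
    </user_parameters>
</PhysiCell_settings>
"""


def write_fixture_settings(
    path: str | Path,
    *,
    speed: float = 2.0,
    migration_bias: float = 0.9,
    persistence_time: float = 1.0,
    max_time: float = 120.0,
    dt_mechanics: float = 0.1,
    x_min: float = -250.0,
    x_max: float = 250.0,
    y_min: float = -250.0,
    y_max: float = 250.0,
    growth_rate: float = 0.1,
    carrying_capacity: float = 1000.0,
    initial_population: float = 10.0,
    random_seed: int = 0,
) -> Path:
    """Write a complete fixture settings file.

    Values are substituted verbatim, so out-of-range values (e.g.
    ``migration_bias=1.5``) produce a file that the schema rejects — useful
    for constraint tests.
    """
    path = Path(path)
    path.write_text(
        _SETTINGS_TEMPLATE.format(
            speed=speed,
            migration_bias=migration_bias,
            persistence_time=persistence_time,
            max_time=max_time,
            dt_mechanics=dt_mechanics,
            x_min=x_min,
            x_max=x_max,
            y_min=y_min,
            y_max=y_max,
            growth_rate=growth_rate,
            carrying_capacity=carrying_capacity,
            initial_population=initial_population,
            random_seed=random_seed,
        )
    )
    return path


# ---------------------------------------------------------------------------
# Mock external executables

_MOCK_LOGISTIC = '''\
#!{python}
"""Mock simulator executable (logistic growth fixture).

Reads growth parameters from the settings file's user_parameters block and
writes one cell-snapshot CSV per time point under output/.
"""
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from cellcalib.fixtures import LogisticParams, logistic_growth

root = etree.parse(sys.argv[1]).getroot()


def user_param(name, default):
    el = root.find(f"user_parameters/{{name}}")
    return float(el.text) if el is not None and el.text else default


r = user_param("growth_rate", 0.1)
K = user_param("carrying_capacity", 1000.0)
n0 = user_param("initial_population", 10.0)
max_time = float(root.find("overall/max_time").text)
t_grid = np.arange(0.0, max_time + 1e-9, 1.0)
curve = logistic_growth(LogisticParams(K=K, r=r, N0=n0, t_grid=t_grid))

out = Path("output")
out.mkdir(exist_ok=True)
for i, n in enumerate(np.round(curve).astype(int)):
    n = max(int(n), 0)
    pd.DataFrame(
        {{
            "id": np.arange(n),
            "x": np.zeros(n),
            "y": np.zeros(n),
            "z": np.zeros(n),
        }}
    ).to_csv(out / f"cells_{{i:08d}}.csv", index=False)
'''

_MOCK_CHEMOTAXIS = '''\
#!{python}
"""Mock simulator executable (chemotaxis fixture).

Maps the settings file's motility block onto the biased persistent random
walk and writes initial/final cell snapshots under output/.  The replicate
seed arrives through the CALIB_SEED environment variable.
"""
import os
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from cellcalib.config_io import load_config
from cellcalib.fixtures import ChemotaxisScenario, simulate_chemotaxis

config = load_config(sys.argv[1])
motility = config.cell("default").motility
domain = config.domain
seed = int(os.environ.get("CALIB_SEED", "0"))

scenario = ChemotaxisScenario(
    speed=motility.speed,
    migration_bias=motility.migration_bias,
    persistence_time=motility.persistence_time,
    x_min=domain.x_min,
    x_max=domain.x_max,
    y_min=domain.y_min,
    y_max=domain.y_max,
    dt=config.overall.dt_mechanics,
    duration=config.overall.max_time,
    seed=seed,
)
initial, final = simulate_chemotaxis(scenario, return_initial=True)

out = Path("output")
out.mkdir(exist_ok=True)
for index, positions in ((0, initial), (1, final)):
    pd.DataFrame(
        {{
            "id": np.arange(len(positions)),
            "x": positions[:, 0],
            "y": positions[:, 1],
            "z": np.zeros(len(positions)),
        }}
    ).to_csv(out / f"cells_{{index:08d}}.csv", index=False)
'''


def make_mock_executable(model: str, out_dir: str | Path) -> Path:
    """Write an executable mock-simulator script honoring the child-process
    contract (``<exe> <settings.xml>`` in a workspace, snapshots under
    ``output/``) and return its path."""
    templates = {"logistic": _MOCK_LOGISTIC, "chemotaxis": _MOCK_CHEMOTAXIS}
    if model not in templates:
        raise ValueError(f"unknown fixture model {model!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"mock_{model}.py"
    path.write_text(templates[model].format(python=sys.executable))
    path.chmod(path.stat().st_mode | stat.S_IXUSR | stat.S_IXGRP | stat.S_IXOTH)
    return path
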