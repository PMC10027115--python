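"""Wrap any simulator as a parameter-to-metric black box.

A calibration loop needs exactly three things from a simulator: update its
settings file with candidate parameter values, run it, and reduce its output
to a numeric metric vector.  :class:`BlackBoxModel` composes those three
stages — the updater and processor are optional, so a model can be as thin as
a bare executable — and :func:`run_model` executes the composition for a
requested number of replicates, each in an isolated working directory with a
deterministic per-replicate seed (``seed + replicate_index``).

Runner contract
---------------
A runner is a callable invoked with the replicate's working directory.  It
may additionally accept ``params``, ``seed`` and ``timeout`` keyword
arguments (detected by signature inspection).  It either

* writes snapshot files under ``<workdir>/output/`` and returns ``None``
  (the external-executable contract: ``<exe> <config-file>`` run inside the
  workspace), in which case the processor reduces the output directory to a
  metric vector — or, with no processor, the sorted output-directory listing
  is returned as a surrogate metric; or
* returns a numeric vector directly (in-process fixture models), which is
  used as the metric as-is.
"""

from __future__ import annotations

import inspect
import math
import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from lxml import etree

__all__ = [
    "BlackBoxError",
    "RunnerNotFoundError",
    "RunnerFailedError",
    "OutputError",
    "BlackBoxModel",
    "run_model",
    "make_external_runner",
    "make_config_updater",
]


class BlackBoxError(Exception):
    """Base error for black-box execution failures."""


class RunnerNotFoundError(BlackBoxError):
    """The runner executable does not exist or is not executable."""


class RunnerFailedError(BlackBoxError):
    """The runner exited non-zero or timed out; carries captured output."""

    def __init__(self, message: str, status: int | None = None, output: str = ""):
        self.status = status
        self.output = output
        tail = ("\n" + output[-2000:]) if output else ""
        super().__init__(message + tail)


class OutputError(BlackBoxError):
    """The processor found no usable output."""


@dataclass
class BlackBoxModel:
    """A simulator wrapped as a map from parameter sets to metric vectors.

    Parameters
    ----------
    runner:
        Required; see the runner contract in the module docstring.
    updater:
        Optional ``(config_path, params) -> None`` applied to the workspace
        copy of ``config_path`` before the runner starts.
    processor:
        Optional ``(output_dir) -> metric vector`` applied after a
        file-writing runner finishes.
    replicates:
        Number of independent runs per parameter set (>= 1); replicate ``i``
        receives seed ``seed + i``.
    config_path:
        Source settings file; copied into each workspace as ``settings.xml``.
    seed_path:
        Raw XML path (relative to the document root, e.g.
        ``user_parameters/random_seed``) where the replicate seed is written
        into the workspace settings file.  When unset, in-process runners
        receive the seed as a keyword argument and child processes through
        the ``CALIB_SEED`` environment variable.
    timeout:
        Wall-clock limit in seconds for external runners (None = unlimited).
    keep_failed:
        Failed workspaces are kept on disk for debugging (successful ones
        are always removed).
    """

    runner: Callable
    updater: Callable[[Path, dict], None] | None = None
    processor: Callable[[Path], Sequence] | None = None
    replicates: int = 1
    config_path: Path | None = None
    seed_path: str | None = None
    timeout: float | None = None
    keep_failed: bool = True

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.config_path is not None:
            self.config_path = Path(self.config_path)


def _check_params(params: dict) -> None:
    for name, value in params.items():
        if not isinstance(name, str) or not name:
            raise ValueError(f"parameter names must be non-empty strings: {name!r}")
        if not math.isfinite(float(value)):
            raise ValueError(f"parameter {name!r} has non-finite value {value!r}")


def _write_seed(config_file: Path, seed_path: str, seed: int) -> None:
    tree = etree.parse(str(config_file))
    el = tree.getroot().find(seed_path)
    if el is None:
        raise BlackBoxError(f"seed path {seed_path!r} not found in {config_file}")
    el.text = str(seed)
    tree.write(str(config_file), xml_declaration=True, encoding="utf-8")


def _call_runner(model: BlackBoxModel, workdir: Path, params: dict, seed: int):
    kwargs = {}
    try:
        sig = inspect.signature(model.runner)
        accepts = set(sig.parameters)
        has_var = any(
            p.kind is inspect.Parameter.VAR_KEYWORD for p in sig.parameters.values()
        )
    except (TypeError, ValueError):
        accepts, has_var = set(), False
    if "params" in accepts or has_var:
        kwargs["params"] = dict(params)
    if "seed" in accepts or has_var:
        kwargs["seed"] = seed
    if ("timeout" in accepts or has_var) and model.timeout is not None:
        kwargs["timeout"] = model.timeout
    return model.runner(workdir, **kwargs)


def run_model(
    model: BlackBoxModel, params: dict, seed: int = 0
) -> list[np.ndarray | list[str]]:
    """Run ``model`` at ``params`` and return one metric vector per replicate.

    Each replicate runs in a fresh temporary working directory (isolated from
    any concurrent call); replicate ``i`` uses seed ``seed + i``, so results
    for deterministic-given-seed runners are reproducible call to call.
    """
    _check_params(params)
    exe = getattr(model.runner, "executable", None)
    if exe is not None:
        exe = Path(exe)
        if not exe.exists():
            raise RunnerNotFoundError(f"runner executable not found: {exe}")
        if not os.access(exe, os.X_OK):
            raise RunnerNotFoundError(f"runner executable not executable: {exe}")

    metrics: list[np.ndarray | list[str]] = []
    for i in range(model.replicates):
        rep_seed = seed + i
        workdir = Path(tempfile.mkdtemp(prefix="cellcalib_"))
        try:
            config_file: Path | None = None
            if model.config_path is not None:
                config_file = workdir / "settings.xml"
                shutil.copy(model.config_path, config_file)
            if model.updater is not None:
                if config_file is None:
                    raise BlackBoxError("model has an updater but no config_path")
                model.updater(config_file, dict(params))
            if model.seed_path is not None and config_file is not None:
                _write_seed(config_file, model.seed_path, rep_seed)

            returned = _call_runner(model, workdir, params, rep_seed)

            if returned is not None:
                metric = np.asarray(returned, dtype=float)
                if not np.all(np.isfinite(metric)):
                    raise OutputError("runner returned non-finite metric values")
            else:
                outdir = workdir / "output"
                if model.processor is not None:
                    if not outdir.is_dir():
                        raise OutputError(f"no output directory at {outdir}")
                    metric = np.asarray(model.processor(outdir), dtype=float)
                    if not np.all(np.isfinite(metric)):
                        raise OutputError("processor returned non-finite values")
                else:
                    # bare model: surrogate metric is the output listing
                    metric = (
                        sorted(p.name for p in outdir.iterdir())
                        if outdir.is_dir()
                        else []
                    )
            metrics.append(metric)
        except Exception:
            if not model.keep_failed:
                shutil.rmtree(workdir, ignore_errors=True)
            raise
        else:
            shutil.rmtree(workdir, ignore_errors=True)
    return metrics


def make_external_runner(executable: str | Path, args: Sequence[str] = ()) -> Callable:
    """Build a runner that launches ``executable`` as a child process.

    The child is invoked as ``<exe> <workdir>/settings.xml <args...>`` with
    the workspace as its current directory and is expected to write its
    snapshots under ``<workdir>/output/``.  The replicate seed is exported as
    ``CALIB_SEED``.  Non-zero exit or timeout raises
    :class:`RunnerFailedError` carrying the captured output tail.
    """
    executable = Path(executable)
    arg_list = [str(a) for a in args]

    def runner(workdir: Path, seed: int | None = None, timeout: float | None = None):
        config_file = Path(workdir) / "settings.xml"
        env = os.environ.copy()
        if seed is not None:
            env["CALIB_SEED"] = str(seed)
        cmd = [str(executable), str(config_file), *arg_list]
        try:
            proc = subprocess.run(
                cmd,
                cwd=workdir,
                env=env,
                capture_output=True,
                text=True,
                timeout=timeout,
            )
        except FileNotFoundError as exc:
            raise RunnerNotFoundError(f"runner executable not found: {executable}") from exc
        except subprocess.TimeoutExpired as exc:
            raise RunnerFailedError(
                f"runner timed out after {timeout} s", output=str(exc.stdout or "")
            ) from exc
        if proc.returncode != 0:
            raise RunnerFailedError(
                f"runner exited with status {proc.returncode}",
                status=proc.returncode,
                output=(proc.stdout or "") + (proc.stderr or ""),
            )
        return None

    runner.executable = executable
    runner.args = arg_list
    return runner


def make_config_updater() -> Callable[[Path, dict], None]:
    """Default updater: parameter names are dotted settings-field paths.

    Each ``name -> value`` pair is applied with
    :func:`cellcalib.config_io.update_field` and the file is rewritten in
    place, so constraint violations surface before the simulator starts.
    """
    from . import config_io

    def updater(config_file: Path, params: dict) -> None:
        config = config_io.load_config(config_file)
        for dotted, value in params.items():
            config_io.update_field(config, dotted, value)
        config_io.write_config(config, config_file)

    return updater
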