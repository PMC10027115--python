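"""Read, validate, edit and write PhysiCell-style XML settings files.

PhysiCell models are configured through an XML settings file describing the
simulation domain, global timestepping, diffusing substances and per-cell-type
phenotype blocks (cycle, death, volume, mechanics, motility).  Parameter
sweeps repeatedly edit these files, so edits must be type-safe: every numeric
field carries a physical constraint (positivity, or a [0, 1] range for
fractions and the migration bias) that is enforced both at load time and on
every update.

The parser keeps the full lxml document alongside the validated records, so
content it does not model (comments, ``user_parameters``, options blocks,
attributes, whitespace) is written back untouched.  Numeric text is only
rewritten when the stored value actually differs from what the file says,
which makes ``load -> write`` a byte-preserving operation on unmodified
files.

Field addressing for edits uses a flat dotted-path dialect::

    domain/<field>
    overall/<field>
    substance/<name>/<field>
    cell/<name>/<block>/<field>     # block in cycle|death|volume|mechanics|motility

e.g. ``cell/default/motility/speed``.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Annotated, Iterator

from lxml import etree
from pydantic import BaseModel, Field, ValidationError, model_validator

__all__ = [
    "ConfigError",
    "ConstraintError",
    "PathError",
    "DomainConfig",
    "OverallConfig",
    "SubstanceConfig",
    "CycleConfig",
    "DeathConfig",
    "VolumeConfig",
    "MechanicsConfig",
    "MotilityConfig",
    "CellConfig",
    "SimulationConfig",
    "load_config",
    "update_field",
    "write_config",
]


# ---------------------------------------------------------------------------
# Errors


class ConfigError(Exception):
    """Base error for settings-file problems (missing/malformed content)."""


class ConstraintError(ConfigError):
    """A numeric field violates its physical constraint.

    Carries the element path, the offending value and the violated bound so
    callers (and the CLI) can report exactly what is wrong and where.
    """

    def __init__(self, element_path: str, value: object, constraint: str):
        self.element_path = element_path
        self.value = value
        self.constraint = constraint
        super().__init__(
            f"{element_path}: value {value!r} violates constraint ({constraint})"
        )


class PathError(ConfigError):
    """A dotted field path does not resolve to a known field."""


# ---------------------------------------------------------------------------
# Validated record types
#
# Constraints mirror the settings schema: strictly positive rates, lengths
# and times; [0, 1] for fluid_fraction, calcified_fraction and migration_bias.

PositiveFloat = Annotated[float, Field(gt=0)]
UnitInterval = Annotated[float, Field(ge=0, le=1)]


class _Validated(BaseModel):
    model_config = {"validate_assignment": True}


class DomainConfig(_Validated):
    """Simulation domain bounds and voxel lengths, in µm."""

    x_min: float
    y_min: float
    z_min: float
    x_max: float
    y_max: float
    z_max: float
    dx: PositiveFloat
    dy: PositiveFloat
    dz: PositiveFloat

    @model_validator(mode="after")
    def _bounds_ordered(self) -> "DomainConfig":
        for axis in "xyz":
            lo, hi = getattr(self, f"{axis}_min"), getattr(self, f"{axis}_max")
            if hi <= lo:
                raise ValueError(f"{axis}_max must exceed {axis}_min ({hi} <= {lo})")
        return self


class OverallConfig(_Validated):
    """Total simulation time and the three PhysiCell time steps, in min."""

    max_time: PositiveFloat
    dt_diffusion: PositiveFloat
    dt_mechanics: PositiveFloat
    dt_phenotype: PositiveFloat


class SubstanceConfig(_Validated):
    """One diffusing microenvironment substance."""

    name: str
    diffusion_coefficient: PositiveFloat  # µm²/min
    decay_rate: PositiveFloat  # 1/min
    initial_condition: PositiveFloat
    dirichlet_boundary_condition: PositiveFloat


class _PhaseLists(_Validated):
    """Phase durations (min) or phase transition rates (1/min).

    PhysiCell cycle/death models are parameterized by exactly one of the two
    lists; the file provides whichever applies and the other stays empty.
    """

    phase_durations: list[PositiveFloat] = []
    phase_transition_rates: list[PositiveFloat] = []

    @model_validator(mode="after")
    def _one_parameterization(self) -> "_PhaseLists":
        if self.phase_durations and self.phase_transition_rates:
            raise ValueError(
                "at most one of phase_durations / phase_transition_rates may be non-empty"
            )
        return self


class CycleConfig(_PhaseLists):
    pass


class DeathConfig(_PhaseLists):
    pass


class VolumeConfig(_Validated):
    total: PositiveFloat  # µm³
    fluid_fraction: UnitInterval
    nuclear: PositiveFloat  # µm³
    fluid_change_rate: PositiveFloat  # 1/min
    cytoplasmic_biomass_change_rate: PositiveFloat
    nuclear_biomass_change_rate: PositiveFloat
    calcified_fraction: UnitInterval
    calcification_rate: PositiveFloat
    relative_rupture_volume: PositiveFloat


class MechanicsConfig(_Validated):
    cell_cell_adhesion_strength: PositiveFloat  # µm/min
    cell_cell_repulsion_strength: PositiveFloat  # µm/min
    relative_maximum_adhesion_distance: PositiveFloat


class MotilityConfig(_Validated):
    """Random-walk motility: speed (µm/min), persistence time (min) and the
    chemotactic migration bias in [0, 1] (0 = pure random walk, 1 =
    deterministic gradient following)."""

    speed: PositiveFloat
    persistence_time: PositiveFloat
    migration_bias: UnitInterval


class CellConfig(_Validated):
    name: str
    cycle: CycleConfig
    death: DeathConfig
    volume: VolumeConfig
    mechanics: MechanicsConfig
    motility: MotilityConfig


_CELL_BLOCKS = ("cycle", "death", "volume", "mechanics", "motility")


class SimulationConfig:
    """A validated settings tree plus the underlying XML document.

    Equality compares modeled values only (the XML byte layout is carried for
    write-back but does not participate in ``==``).
    """

    def __init__(
        self,
        domain: DomainConfig,
        overall: OverallConfig,
        substances: list[SubstanceConfig],
        cells: list[CellConfig],
        tree: etree._ElementTree,
        bindings: list[tuple],
        source: Path | None = None,
    ):
        self.domain = domain
        self.overall = overall
        self.substances = substances
        self.cells = cells
        self._tree = tree
        self._bindings = bindings
        self.source = source

    def substance(self, name: str) -> SubstanceConfig:
        for s in self.substances:
            if s.name == name:
                return s
        raise PathError(f"no substance named {name!r}")

    def cell(self, name: str) -> CellConfig:
        for c in self.cells:
            if c.name == name:
                return c
        raise PathError(f"no cell definition named {name!r}")

    def _dump(self) -> dict:
        return {
            "domain": self.domain.model_dump(),
            "overall": self.overall.model_dump(),
            "substances": [s.model_dump() for s in self.substances],
            "cells": [c.model_dump() for c in self.cells],
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimulationConfig):
            return NotImplemented
        return self._dump() == other._dump()

    def __repr__(self) -> str:
        names = [c.name for c in self.cells]
        return f"SimulationConfig(substances={len(self.substances)}, cells={names})"

    def iter_fields(self) -> Iterator[tuple[str, object]]:
        """Yield (dotted path, value) for every modeled scalar field."""
        for f in DomainConfig.model_fields:
            yield f"domain/{f}", getattr(self.domain, f)
        for f in OverallConfig.model_fields:
            yield f"overall/{f}", getattr(self.overall, f)
        for s in self.substances:
            for f in SubstanceConfig.model_fields:
                if f != "name":
                    yield f"substance/{s.name}/{f}", getattr(s, f)
        for c in self.cells:
            for block in _CELL_BLOCKS:
                obj = getattr(c, block)
                for f in type(obj).model_fields:
                    yield f"cell/{c.name}/{block}/{f}", getattr(obj, f)


# ---------------------------------------------------------------------------
# Parsing

# field -> relative xpath, where they differ from the field name
_SUBSTANCE_FIELDS = {
    "diffusion_coefficient": "physical_parameter_set/diffusion_coefficient",
    "decay_rate": "physical_parameter_set/decay_rate",
    "initial_condition": "initial_condition",
    "dirichlet_boundary_condition": "Dirichlet_boundary_condition",
}


def _find(parent: etree._Element, rel: str, path: str) -> etree._Element:
    el = parent.find(rel)
    if el is None:
        raise ConfigError(f"missing element {path}/{rel}")
    return el


def _float_of(el: etree._Element, path: str) -> float:
    text = (el.text or "").strip()
    try:
        return float(text)
    except ValueError:
        raise ConfigError(f"{path}: non-numeric value {text!r}") from None


def _construct(cls, data: dict, raw: dict, xml_path: str):
    """Build a pydantic record, translating validation failures into
    ConstraintError with the XML element path and the violated bound."""
    try:
        return cls(**data)
    except ValidationError as exc:
        err = exc.errors()[0]
        loc = "/".join(str(p) for p in err["loc"]) if err["loc"] else ""
        value = err.get("input")
        where = f"{xml_path}/{loc}" if loc else xml_path
        raise ConstraintError(where, value, err["msg"]) from None


def _load_scalars(parent, fields: dict[str, str], xml_path: str):
    vals: dict[str, float] = {}
    elems: dict[str, etree._Element] = {}
    for fname, rel in fields.items():
        el = _find(parent, rel, xml_path)
        vals[fname] = _float_of(el, f"{xml_path}/{rel}")
        elems[fname] = el
    return vals, elems


def _load_phase_lists(parent, xml_path: str):
    dur_elems = parent.findall(".//phase_durations/duration")
    rate_elems = parent.findall(".//phase_transition_rates/rate")
    vals = {
        "phase_durations": [
            _float_of(e, f"{xml_path}/phase_durations/duration") for e in dur_elems
        ],
        "phase_transition_rates": [
            _float_of(e, f"{xml_path}/phase_transition_rates/rate")
            for e in rate_elems
        ],
    }
    elems = {"phase_durations": dur_elems, "phase_transition_rates": rate_elems}
    return vals, elems


def load_config(path: str | Path) -> SimulationConfig:
    """Parse and validate a settings file.

    Raises ``FileNotFoundError`` for a missing file, ``ConfigError`` for
    malformed XML or missing elements, and ``ConstraintError`` (with element
    path, value and bound) when a value violates its schema constraint.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"settings file not found: {path}")
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ConfigError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    bindings: list[tuple] = []

    def bind(model, elems: dict):
        for fname, target in elems.items():
            kind = "list" if isinstance(target, list) else "scalar"
            bindings.append((kind, model, fname, target))

    dom_el = _find(root, "domain", "")
    dom_fields = {f: f for f in DomainConfig.model_fields}
    vals, elems = _load_scalars(dom_el, dom_fields, "domain")
    domain = _construct(DomainConfig, vals, vals, "domain")
    bind(domain, elems)

    ov_el = _find(root, "overall", "")
    ov_fields = {f: f for f in OverallConfig.model_fields}
    vals, elems = _load_scalars(ov_el, ov_fields, "overall")
    overall = _construct(OverallConfig, vals, vals, "overall")
    bind(overall, elems)

    substances: list[SubstanceConfig] = []
    for var in root.findall("microenvironment_setup/variable"):
        name = var.get("name")
        if name is None:
            raise ConfigError("microenvironment_setup/variable missing name attribute")
        xml_path = f"substance/{name}"
        vals, elems = _load_scalars(var, _SUBSTANCE_FIELDS, xml_path)
        sub = _construct(SubstanceConfig, {"name": name, **vals}, vals, xml_path)
        substances.append(sub)
        bind(sub, elems)

    cells: list[CellConfig] = []
    for cd in root.findall("cell_definitions/cell_definition"):
        name = cd.get("name")
        if name is None:
            raise ConfigError("cell_definition missing name attribute")
        phen = _find(cd, "phenotype", f"cell/{name}")
        blocks = {}
        for block, cls, loader in (
            ("cycle", CycleConfig, _load_phase_lists),
            ("death", DeathConfig, _load_phase_lists),
            ("volume", VolumeConfig, None),
            ("mechanics", MechanicsConfig, None),
            ("motility", MotilityConfig, None),
        ):
            bel = _find(phen, block, f"cell/{name}")
            xml_path = f"cell/{name}/{block}"
            if loader is not None:
                vals, elems = loader(bel, xml_path)
            else:
                fields = {f: f for f in cls.model_fields}
                vals, elems = _load_scalars(bel, fields, xml_path)
            model = _construct(cls, vals, vals, xml_path)
            blocks[block] = (model, elems)
        cell = CellConfig(name=name, **{b: m for b, (m, _) in blocks.items()})
        # rebind to the submodels owned by the CellConfig instance
        for block, (_, elems) in blocks.items():
            bind(getattr(cell, block), elems)
        cells.append(cell)

    return SimulationConfig(domain, overall, substances, cells, tree, bindings, path)


# ---------------------------------------------------------------------------
# Editing


def update_field(config: SimulationConfig, dotted: str, value: float) -> SimulationConfig:
    """Set one field addressed by a dotted path, re-validating its record.

    Returns the (mutated) config.  Raises ``PathError`` for an unknown path
    and ``ConstraintError`` when the new value violates the field's bound.
    All other fields are untouched.
    """
    parts = [p for p in dotted.strip("/").split("/") if p]
    if not parts:
        raise PathError("empty field path")
    head = parts[0]
    if head == "domain" and len(parts) == 2:
        obj, fname = config.domain, parts[1]
    elif head == "overall" and len(parts) == 2:
        obj, fname = config.overall, parts[1]
    elif head == "substance" and len(parts) == 3:
        obj, fname = config.substance(parts[1]), parts[2]
    elif head == "cell" and len(parts) == 4:
        if parts[2] not in _CELL_BLOCKS:
            raise PathError(f"unknown phenotype block {parts[2]!r} in {dotted!r}")
        obj, fname = getattr(config.cell(parts[1]), parts[2]), parts[3]
    else:
        raise PathError(f"unrecognized field path {dotted!r}")
    if fname not in type(obj).model_fields:
        raise PathError(f"unknown field {fname!r} in {dotted!r}")
    if isinstance(getattr(obj, fname), list):
        raise PathError(f"list field {dotted!r} is not addressable")
    try:
        setattr(obj, fname, value)
    except ValidationError as exc:
        err = exc.errors()[0]
        raise ConstraintError(dotted, value, err["msg"]) from None
    return config


# ---------------------------------------------------------------------------
# Writing


def _format_number(v: float) -> str:
    if math.isnan(v) or math.isinf(v):
        raise ConfigError(f"cannot serialize non-finite value {v}")
    # shortest decimal string that reparses to the same float
    return repr(float(v))


def _sync_text(el: etree._Element, value: float) -> None:
    old = (el.text or "").strip()
    try:
        if old and float(old) == value:
            return  # keep original formatting byte-for-byte
    except ValueError:
        pass
    el.text = _format_number(value)


def write_config(config: SimulationConfig, path: str | Path) -> Path:
    """Serialize the config back to XML at ``path``.

    Modeled values are written into the original document; everything else
    (unmodeled elements, attributes, comments, formatting) is emitted
    unchanged.  Numbers are serialized with full round-trip precision, so
    ``load(write(load(f)))`` equals ``load(f)`` on all modeled values.
    """
    for kind, model, fname, target in config._bindings:
        value = getattr(model, fname)
        if kind == "scalar":
            _sync_text(target, value)
        else:
            for el, v in zip(target, value):
                _sync_text(el, v)
    path = Path(path)
    try:
        config._tree.write(str(path), xml_declaration=True, encoding="utf-8")
    except OSError as exc:
        raise ConfigError(f"cannot write settings file {path}: {exc}") from exc
    return path
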