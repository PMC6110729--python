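"""Run configuration, presets, and output writers.

A run is described by one YAML or JSON file with sections ``units``,
``membrane``, ``geometry``, ``solver``, ``field``, ``scenario``, ``cell``
and ``output``.  Every field has a documented default; unknown keys are
rejected by name.  The preset fixtures embed the printed parameter set of
the source model (node length 1.08 µm, myelinated segment 3.08 µm, myelin
thickness 3.63 µm, ḡ_K = 12.5 and ḡ_Na = 28 mS/cm², driving forces 12 and
−115 mV, ρ = 1 g/ml), each annotated with provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .cable import CableRun, FiberGeometry, MembraneParams, SolverConfig
from .dynamics import CellParticle
from .field import FieldConfig
from .units import PhysicalConstants, Provenance, UnitPolicy

__all__ = [
    "RunConfig",
    "Fixture",
    "load_config",
    "dump_config",
    "make_fixtures",
    "PRESET_NAMES",
    "write_trajectory_csv",
    "write_scenario_json",
    "write_run",
]

logger = logging.getLogger("axonfield")


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class UnitsSection(_Section):
    mode: Literal["paper", "si"] = "paper"
    eps_cns: float = 80.0


class MembraneSection(_Section):
    gbar_K: float = 12.5
    gbar_Na: float = 28.0
    g_L: float = 0.3
    V_K: float = -77.0
    V_Na: float = 50.0
    V_L: float = -54.4
    C_m: float = 1.0
    c: float = 1.0
    G_m: float = 0.0
    gamma: float = 0.1
    delta: float = 0.1
    eta: float = 0.1
    K_couple: float = 1.0
    allow_dissipative: bool = False


class GeometrySection(_Section):
    radius: float = 5.0
    segment_length: float = 1.08
    segment_type: Literal["node", "myelinated"] = "node"
    myelin_thickness: float = 0.0
    rho: float = 1.0


class SolverSection(_Section):
    dt: float = 0.001
    dx: float = 1.0
    n_segments: int = 10
    n_steps: int = 100
    boundary: Literal["sealed", "clamped"] = "sealed"
    stim_segment: int = 0
    stim_amplitude: float = 0.0
    stim_start: float = 0.0
    stim_duration: float = 0.0
    coupling: Literal["axial", "k-rule"] = "axial"
    literal_paper_mode: bool = True
    V_rest: float = -65.0
    rate_preset: str = "default"
    seed: int = 0


class FieldSection(_Section):
    dV_K: float = 12.0       # driving force V_r − V_K, mV
    dV_Na: float = -115.0    # driving force V_r − V_Na, mV
    V_term: float = 0.0
    literal: bool = True
    decay_exponent_node: float = 1.0
    decay_exponent_myelin: float = 2.0


class DemyelinationSection(_Section):
    fraction: float = 0.5
    baseline_convention: Literal["neurilemma", "axolemma"] = "neurilemma"


class BundleSection(_Section):
    n_axons: int = 100
    aggregation_model: Literal["paper-calibrated", "sqrt-cancellation"] = "paper-calibrated"
    bundle_radius: float | None = None


class ScenarioSection(_Section):
    demyelination: DemyelinationSection = DemyelinationSection()
    bundle: BundleSection = BundleSection()


class CellSection(_Section):
    charge: float = -1.0e-14     # C; the cell charge has no published value
    radius: float = 5.0e-6       # m
    mass: float = 5.24e-13       # kg (5 µm sphere at 1 g/ml)
    medium_viscosity: float = 0.0012
    velocity: list[float] = [1.0e-6, 0.0, 0.0]
    position: list[float] = [0.0, 0.0, 0.0]
    dt: float = 1.0e-3
    n_steps: int = 1000
    drag: bool = True
    method: Literal["midpoint", "boris"] = "midpoint"


class OutputSection(_Section):
    out: str | None = None
    log_level: str = "INFO"


class RunConfig(_Section):
    units: UnitsSection = UnitsSection()
    membrane: MembraneSection = MembraneSection()
    geometry: GeometrySection = GeometrySection()
    solver: SolverSection = SolverSection()
    field: FieldSection = FieldSection()
    scenario: ScenarioSection = ScenarioSection()
    cell: CellSection = CellSection()
    output: OutputSection = OutputSection()

    # -- converters to the domain objects ------------------------------------

    def unit_policy(self) -> UnitPolicy:
        return UnitPolicy(mode=self.units.mode)

    def constants(self) -> PhysicalConstants:
        return PhysicalConstants(eps_cns=self.units.eps_cns)

    def membrane_params(self) -> MembraneParams:
        return MembraneParams(**self.membrane.model_dump())

    def fiber_geometry(self) -> FiberGeometry:
        return FiberGeometry(**self.geometry.model_dump())

    def solver_config(self) -> SolverConfig:
        return SolverConfig(**self.solver.model_dump())

    def field_config(self) -> FieldConfig:
        return FieldConfig(
            constants=self.constants(),
            decay_exponent_node=self.field.decay_exponent_node,
            decay_exponent_myelin=self.field.decay_exponent_myelin,
            V_term=self.field.V_term,
            literal=self.field.literal,
        )

    def ionic_sum(self) -> float:
        """S = ḡ_K·ΔV_K + ḡ_Na·ΔV_Na from the configured driving forces."""
        return (self.membrane.gbar_K * self.field.dV_K
                + self.membrane.gbar_Na * self.field.dV_Na)

    def cell_particle(self) -> CellParticle:
        c = self.cell
        return CellParticle(charge=c.charge, radius=c.radius, mass=c.mass,
                            position=np.asarray(c.position),
                            velocity=np.asarray(c.velocity),
                            medium_viscosity=c.medium_viscosity)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    An empty file yields the all-defaults config.  Schema violations raise
    ``ValueError`` listing every offending key.  The effective (post-default)
    configuration is logged.
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix not in (".json",) else json.loads(text or "{}")
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        cfg = RunConfig.model_validate(data)
    except ValidationError as exc:
        keys = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ValueError(f"invalid configuration ({keys})") from exc
    logger.info("effective configuration: %s", cfg.model_dump())
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config back out (YAML); round-trips through load_config."""
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))


@dataclasses.dataclass(frozen=True)
class Fixture:
    """A fully specified preset config with per-field provenance notes."""

    name: str
    config: RunConfig
    provenance: dict[str, Provenance]


PRESET_NAMES = ("node", "myelinated", "bundle100", "demo-cell")

_SRC = "printed parameter set of the source model"
_OWN = "package default; no published value"


def make_fixtures(name: str) -> Fixture:
    """Build one of the shipped presets: node, myelinated, bundle100, demo-cell."""
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")
    cfg = RunConfig()
    prov = {
        "membrane.gbar_K": Provenance("gbar_K-12.5-mS/cm2", _SRC, "paper-anchor"),
        "membrane.gbar_Na": Provenance("gbar_Na-28-mS/cm2", _SRC, "paper-anchor"),
        "field.dV_K": Provenance("driving-force-K-12-mV", _SRC, "paper-anchor"),
        "field.dV_Na": Provenance("driving-force-Na--115-mV", _SRC, "paper-anchor"),
        "geometry.rho": Provenance("density-1-g/ml", _SRC, "paper-anchor"),
        "geometry.radius": Provenance("axon-radius-5-um", _OWN, "computed"),
    }
    if name == "node":
        cfg = cfg.model_copy(update={"geometry": GeometrySection(
            segment_length=1.08, segment_type="node", myelin_thickness=0.0)})
        prov["geometry.segment_length"] = Provenance("node-length-1.08-um", _SRC, "paper-anchor")
    elif name == "myelinated":
        cfg = cfg.model_copy(update={"geometry": GeometrySection(
            segment_length=3.08, segment_type="myelinated", myelin_thickness=3.63)})
        prov["geometry.segment_length"] = Provenance("myelinated-length-3.08-um", _SRC, "paper-anchor")
        prov["geometry.myelin_thickness"] = Provenance("myelin-thickness-3.63-um", _SRC, "paper-anchor")
    elif name == "bundle100":
        cfg = cfg.model_copy(update={"scenario": ScenarioSection(
            bundle=BundleSection(n_axons=100))})
        prov["scenario.bundle.n_axons"] = Provenance("bundle-100-axons", _SRC, "paper-anchor")
    elif name == "demo-cell":
        prov["cell.medium_viscosity"] = Provenance("viscosity-0.0012-Pa.s", _SRC, "paper-anchor")
        prov["cell.charge"] = Provenance("demo-cell-charge", _OWN, "computed")
    return Fixture(name=name, config=cfg, provenance=prov)


# -- output writers -----------------------------------------------------------

def write_trajectory_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Trajectory CSV (header always present, even for empty frames)."""
    df.to_csv(path, index=False, float_format="%.12g")


def write_scenario_json(record: dict, path: str | Path) -> None:
    """Scenario record as JSON, provenance dataclasses serialized inline."""

    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"cannot serialize {type(o).__name__}")

    Path(path).write_text(json.dumps(record, indent=2, default=default) + "\n")


def write_run(run: CableRun, npz_path: str | Path,
              csv_path: str | Path | None = None,
              front_threshold: float = 10.0) -> None:
    """Persist a cable run: NPZ of the grid arrays plus a CSV summary
    (per-step max V and the index of the propagation front, defined as the
    furthest segment depolarized more than ``front_threshold`` mV above
    rest; −1 while no segment is)."""
    np.savez(npz_path, t=run.t, V=run.V, m=run.m, n=run.n, h=run.h,
             I_ax=run.I_ax, J=run.J)
    if csv_path is not None:
        rest = run.config.V_rest
        above = run.V > rest + front_threshold
        front = np.where(above.any(axis=1),
                         above.shape[1] - 1 - np.argmax(above[:, ::-1], axis=1), -1)
        pd.DataFrame({"t": run.t, "max_V": run.V.max(axis=1),
                      "front_index": front}).to_csv(csv_path, index=False,
                                                    float_format="%.12g")
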