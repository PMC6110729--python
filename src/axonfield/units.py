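"""Physical constants, the unit registry, and the calibration policy.

The field computations in this package run in one of two modes:

``si``
    Every quantity is carried in SI units and all downstream operations are
    dimensionally consistent.  This is the mode used by all property tests.

``paper``
    The headline reference values of the underlying model (field strengths at
    the axolemma/neurilemma, homogeneity ranges) were published from a worked
    arithmetic whose mixed units (mS/cm², mV, cm, g/ml) do not reduce to a
    single self-consistent system.  In this mode those published numbers are
    treated as *calibration anchors*: scenario operations return them directly,
    and every such value carries a provenance tag naming the anchor it came
    from.  Anchors are never silently substituted into SI-mode computations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

__all__ = [
    "PhysicalConstants",
    "Provenance",
    "Anchor",
    "UnitPolicy",
    "UNIT_REGISTRY",
    "convert",
    "dimension_of",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Electromagnetic constants used throughout the field model.

    Parameters
    ----------
    mu0 : float
        Magnetic permeability of free space, T·m/A.
    eps0 : float
        Electric permittivity of free space, F/m.
    eps_cns : float
        Relative permittivity of CNS tissue (dimensionless).  Brain tissue is
        mostly water; 80 is the standard low-frequency relative permittivity
        of water and is the configurable default.
    """

    mu0: float = 4.0e-7 * math.pi
    eps0: float = 8.8541878128e-12
    eps_cns: float = 80.0

    def __post_init__(self) -> None:
        if self.mu0 <= 0 or self.eps0 <= 0 or self.eps_cns <= 0:
            raise ValueError("physical constants must be strictly positive")


@dataclass(frozen=True)
class Provenance:
    """Where a numeric output came from: a calibration anchor or a computation."""

    tag: str
    location: str
    mode: Literal["paper-anchor", "computed"]


@dataclass(frozen=True)
class Anchor:
    """A published calibration value with its provenance."""

    name: str
    value: float
    units: str
    location: str

    @property
    def provenance(self) -> Provenance:
        return Provenance(tag=self.name, location=self.location, mode="paper-anchor")


def _default_anchors() -> dict[str, Anchor]:
    loc = "published reference value of the source model"
    return {
        a.name: a
        for a in (
            Anchor("B_axolemma", 3.0e-12, "T",
                   f"peak field at the node of Ranvier (axolemma); {loc}"),
            Anchor("B_neurilemma", 2.3e-12, "T",
                   f"field at the myelin surface (neurilemma); {loc}"),
            Anchor("B_bundle", 6.0e-12, "T",
                   f"peak field of a 100-axon bundle; {loc}"),
            Anchor("D_max_node", 6.606, "um",
                   f"homogeneity range from axolemma at a node; {loc}"),
            Anchor("D_max_myelinated", 2.066, "um",
                   f"homogeneity range from neurilemma; {loc}"),
            Anchor("r_max_myelinated", 5.696, "um",
                   f"homogeneity range from axolemma across myelin; {loc}"),
            Anchor("D_max_bundle", 12.005, "um",
                   f"homogeneity range of a 100-axon bundle; {loc}"),
        )
    }


@dataclass
class UnitPolicy:
    """Computation mode plus the registry of calibration anchors.

    In ``mode="si"`` the anchors are reference metadata only; scenario
    operations compute everything from user parameters.  In ``mode="paper"``
    scenario operations may return anchors, always with their provenance.
    """

    mode: Literal["paper", "si"] = "paper"
    anchors: dict[str, Anchor] = field(default_factory=_default_anchors)

    def anchor(self, name: str) -> Anchor:
        try:
            return self.anchors[name]
        except KeyError:
            known = ", ".join(sorted(self.anchors))
            raise KeyError(f"unknown anchor {name!r}; known anchors: {known}") from None


# ---------------------------------------------------------------------------
# Unit registry.  Dimensions are exponent tuples over (kg, m, s, A); each label
# maps to (dimension, factor-to-SI).  This is deliberately only the registry
# this package needs, not a general units library.
# ---------------------------------------------------------------------------

_D_LEN = (0, 1, 0, 0)
_D_TIME = (0, 0, 1, 0)
_D_VOLT = (1, 2, -3, -1)
_D_COND_AREA = (-1, -4, 3, 2)   # conductance per area, S/m^2
_D_FIELD = (1, 0, -2, -1)       # tesla
_D_CURRENT = (0, 0, 0, 1)
_D_DENSITY = (1, -3, 0, 0)
_D_VISCOSITY = (1, -1, -1, 0)   # Pa·s

UNIT_REGISTRY: dict[str, tuple[tuple[int, int, int, int], float]] = {
    "m": (_D_LEN, 1.0),
    "cm": (_D_LEN, 1e-2),
    "um": (_D_LEN, 1e-6),
    "µm": (_D_LEN, 1e-6),
    "s": (_D_TIME, 1.0),
    "ms": (_D_TIME, 1e-3),
    "V": (_D_VOLT, 1.0),
    "mV": (_D_VOLT, 1e-3),
    "S/m^2": (_D_COND_AREA, 1.0),
    "mS/cm^2": (_D_COND_AREA, 10.0),
    "T": (_D_FIELD, 1.0),
    "A": (_D_CURRENT, 1.0),
    "kg/m^3": (_D_DENSITY, 1.0),
    "g/ml": (_D_DENSITY, 1e3),
    "Pa.s": (_D_VISCOSITY, 1.0),
}


def dimension_of(unit: str) -> tuple[int, int, int, int]:
    """Dimension exponents (kg, m, s, A) of a registered unit label."""
    try:
        return UNIT_REGISTRY[unit][0]
    except KeyError:
        known = ", ".join(sorted(UNIT_REGISTRY))
        raise ValueError(f"unknown unit label {unit!r}; registry: {known}") from None


def convert(value: float, src: str, dst: str) -> float:
    """Convert ``value`` from unit ``src`` to unit ``dst``.

    Raises
    ------
    ValueError
        If either label is not in the registry, or the dimensions differ.
    """
    dim_src = dimension_of(src)
    dim_dst = dimension_of(dst)
    if dim_src != dim_dst:
        raise ValueError(
            f"incompatible dimensions: {src!r} has {dim_src}, {dst!r} has {dim_dst}"
        )
    return value * UNIT_REGISTRY[src][1] / UNIT_REGISTRY[dst][1]
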