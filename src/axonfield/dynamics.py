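"""Charged-cell motion in the fiber's electromagnetic field.

Cells (lymphocytes, stem cells, ...) are modeled as charged rigid spheres
in a Newtonian fluid of viscosity 0.0012 Pa·s.  The forces are the Coulomb
force qE, the Lorentz magnetic force q·v×B (magnitude q·v·B·sinθ with θ
the incidence angle against the field), and Stokes drag −6πηr·v.

The default integrator advances the velocity by the implicit-midpoint
(Crank–Nicolson) rule, solving a 3×3 linear system per step: the magnetic
rotation then conserves |v| exactly, so the "magnetic force does no work"
property holds to round-off at practical step sizes, and the drag term is
unconditionally stable.  A Boris-style split update is available as an
alternative high-accuracy mode.  Optional Brownian velocity kicks (off by
default, not part of the base model) use the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "CellParticle",
    "electric_force",
    "magnetic_force",
    "stokes_drag_coefficient",
    "step_trajectory",
]

FieldSampler = Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]


@dataclass
class CellParticle:
    """A charged spherical cell.

    ``charge`` in C (typically negative), ``radius`` in m, ``mass`` in kg,
    position/velocity in SI 3-vectors, ``medium_viscosity`` in Pa·s.
    """

    charge: float
    radius: float
    mass: float
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))
    medium_viscosity: float = 0.0012

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.mass <= 0 or self.medium_viscosity <= 0:
            raise ValueError("radius, mass and viscosity must be positive")
        self.position = np.asarray(self.position, dtype=float).copy()
        self.velocity = np.asarray(self.velocity, dtype=float).copy()


def electric_force(q: float, E) -> np.ndarray:
    """Coulomb force F = qE."""
    return q * np.asarray(E, dtype=float)


def magnetic_force(q: float, v, B) -> np.ndarray:
    """Lorentz magnetic force F = q·v×B (|F| = |q||v||B|·sinθ)."""
    return q * np.cross(np.asarray(v, dtype=float), np.asarray(B, dtype=float))


def stokes_drag_coefficient(cell: CellParticle) -> float:
    """Stokes drag coefficient 6πηr (kg/s)."""
    return 6.0 * np.pi * cell.medium_viscosity * cell.radius


def _skew(B: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -B[2], B[1]],
                     [B[2], 0.0, -B[0]],
                     [-B[1], B[0], 0.0]])


def _midpoint_velocity(v, E, B, q, m, c, dt):
    # (m/dt + c) v' − (q/2) v'×B = (m/dt) v + qE + (q/2) v×B
    # with v'×B = −[B]× v'  =>  M v' = rhs, M = (m/dt + c) I + (q/2) [B]×
    M = (m / dt + c) * np.eye(3) + 0.5 * q * _skew(B)
    rhs = (m / dt) * v + q * E + 0.5 * q * np.cross(v, B)
    return np.linalg.solve(M, rhs)


def _boris_velocity(v, E, B, q, m, c, dt):
    # half electric kick, exact-magnitude magnetic rotation, half kick;
    # drag applied as an implicit factor around the kick.
    damp = 1.0 / (1.0 + c * dt / (2.0 * m))
    v_minus = damp * v + 0.5 * dt * q * E / m
    tvec = 0.5 * dt * q * B / m
    v_prime = v_minus + np.cross(v_minus, tvec)
    svec = 2.0 * tvec / (1.0 + tvec @ tvec)
    v_plus = v_minus + np.cross(v_prime, svec)
    return damp * (v_plus + 0.5 * dt * q * E / m)


def step_trajectory(cell: CellParticle, field_sampler: FieldSampler, dt: float,
                    n_steps: int, drag: bool = True, method: str = "midpoint",
                    brownian_sigma: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Integrate the cell's equation of motion m·dv/dt = qE + q v×B − 6πηr v.

    ``field_sampler(position) -> (E, B)`` supplies the local fields.
    ``method`` is ``"midpoint"`` (default) or ``"boris"``.  Brownian kicks
    of standard deviation ``brownian_sigma`` (m/s per step) are an optional
    extension beyond the base model and draw from ``seed``; with the
    default 0 the run is fully deterministic.

    Returns a DataFrame with columns t, x, y, z, vx, vy, vz, F_el, F_mag
    (force magnitudes).  Aborts with the step index if the position leaves
    the finite range.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if method not in ("midpoint", "boris"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    q, m = cell.charge, cell.mass
    c = stokes_drag_coefficient(cell) if drag else 0.0
    x = cell.position.astype(float).copy()
    v = cell.velocity.astype(float).copy()

    rows = np.empty((n_steps + 1, 9))
    E, B = (np.asarray(f, dtype=float) for f in field_sampler(x))
    rows[0] = (0.0, *x, *v, np.linalg.norm(electric_force(q, E)),
               np.linalg.norm(magnetic_force(q, v, B)))
    for k in range(1, n_steps + 1):
        E, B = (np.asarray(f, dtype=float) for f in field_sampler(x))
        if method == "midpoint":
            v = _midpoint_velocity(v, E, B, q, m, c, dt)
        else:
            v = _boris_velocity(v, E, B, q, m, c, dt)
        if brownian_sigma > 0.0:
            v = v + rng.normal(0.0, brownian_sigma, size=3)
        x = x + dt * v
        if not np.all(np.isfinite(x)):
            raise RuntimeError(f"non-finite position at step {k}")
        rows[k] = (k * dt, *x, *v, np.linalg.norm(electric_force(q, E)),
                   np.linalg.norm(magnetic_force(q, v, B)))
    return pd.DataFrame(rows, columns=["t", "x", "y", "z", "vx", "vy", "vz",
                                       "F_el", "F_mag"])
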