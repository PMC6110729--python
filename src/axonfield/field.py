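"""Magnetic and induced electric fields around a fiber.

In the homogeneous regime close to the fiber, the field of the membrane
currents reduces (Ampère's loop law, with the enclosed-charge term dropped)
to a closed form

    B(r) = μ₀ [ S + 2πr(x+r)·V/(ρx) ] / (2πr),

with S = g_K(V−V_K) + g_Na(V−V_Na) the ionic driving sum (the leak term is
negligible against Na/K and is dropped).  Setting B(r) = 0 gives the
homogeneity range r_max as the positive root of a quadratic; beyond it the
profile decays as a power law.  A discretized Biot–Savart sum provides the
full |B| map on a grid transverse to the fiber, and the time-varying field
induces E = 1/(μ₀ ε₀ ε_cns) ∫ ∇×B dt.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from .units import PhysicalConstants

__all__ = [
    "FieldConfig",
    "FieldProfile",
    "FieldMap",
    "ionic_sum",
    "simplified_B",
    "find_range",
    "radial_profile",
    "straight_wire_segments",
    "biot_savart_grid",
    "curl_2d",
    "induced_E",
]


@dataclass(frozen=True)
class FieldConfig:
    """Options for the analytic field expressions.

    ``V_term`` is the membrane potential entering the resistive bracket
    term (mV).  In ``literal`` mode the bracket reproduces the printed
    worked form, where that V is dropped (coefficient 1); dimensional mode
    keeps it.  ``Q_enc_model`` handles the enclosed-charge term of the
    loop law: ``"zero"`` is the homogeneous-regime approximation (the term
    vanishes close to the fiber); a callable hook Q_enc(t) may be supplied
    for the inhomogeneous regime.
    """

    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    Q_enc_model: Literal["zero"] | Callable[[float], float] = "zero"
    decay_exponent_node: float = 1.0
    decay_exponent_myelin: float = 2.0
    V_term: float = 0.0
    literal: bool = True

    def __post_init__(self) -> None:
        if self.decay_exponent_node <= 0 or self.decay_exponent_myelin <= 0:
            raise ValueError("decay exponents must be positive")

    def bracket_V(self) -> float:
        """Coefficient multiplying 2πr(x+r)/(ρx) in the bracket."""
        return 1.0 if self.literal else self.V_term


@dataclass(frozen=True)
class FieldProfile:
    """Radial |B| profile: a plateau of strength ``plateau_B`` out to
    ``D_max`` from the reference surface, then a (D_max/r)^p decay."""

    plateau_B: float
    D_max: float
    reference_surface: Literal["axolemma", "neurilemma"] = "axolemma"
    decay_exponent: float = 1.0
    myelin_thickness: float = 0.0

    def __post_init__(self) -> None:
        if self.plateau_B < 0 or self.D_max < 0:
            raise ValueError("plateau_B and D_max must be non-negative")

    @property
    def r_max(self) -> float:
        """Range measured from the axolemma (adds back the myelin)."""
        return self.D_max + self.myelin_thickness


@dataclass(frozen=True)
class FieldMap:
    """|B| sampled on a transverse (y, z) grid; fiber along x."""

    y: np.ndarray
    z: np.ndarray
    B_mag: np.ndarray
    n_segments: int
    masked: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.B_mag.shape != (len(self.y), len(self.z)):
            raise ValueError("map dimensions must match axes")
        if np.any(self.B_mag < 0):
            raise ValueError("|B| must be non-negative")


def ionic_sum(g_K: float, dV_K: float, g_Na: float, dV_Na: float) -> float:
    """S = g_K·(V−V_K) + g_Na·(V−V_Na), the ionic driving sum."""
    return g_K * dV_K + g_Na * dV_Na


def simplified_B(r, S: float, x: float, rho: float,
                 config: FieldConfig | None = None):
    """Closed-form B(r) of the homogeneous regime (leak term dropped).

    ``r`` and ``x`` must share one length unit, and S, ρ, V the matching
    units, for the output to be in tesla; the expression itself is evaluated
    verbatim in either mode.
    """
    config = config or FieldConfig()
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radial distance must be positive")
    Vc = config.bracket_V()
    bracket = S + 2.0 * np.pi * r * (x + r) * Vc / (rho * x)
    out = config.constants.mu0 * bracket / (2.0 * np.pi * r)
    return float(out) if out.ndim == 0 else out


def find_range(S: float, x: float, rho: float,
               config: FieldConfig | None = None,
               myelin_thickness: float = 0.0,
               cross_check: bool = True) -> tuple[float, float]:
    """Radius at which B(r) crosses zero: the homogeneity range.

    Solves S + (2πV/(ρx))·r(x+r) = 0 for its positive root in closed form
    (quadratic discriminant branch) and, optionally, cross-checks against a
    bracketing root solve.  Returns ``(r_max, D_max)`` where D_max subtracts
    the myelin thickness (equal to r_max at a node).

    Degenerate S = 0 returns (0, 0).  A sign configuration with no positive
    real root raises.
    """
    config = config or FieldConfig()
    if S == 0.0:
        return 0.0, 0.0
    Vc = config.bracket_V()
    if Vc == 0.0:
        raise ValueError("bracket V term is zero: B(r) never crosses zero")
    c2 = 2.0 * np.pi * Vc / (rho * x)
    c1 = 2.0 * np.pi * Vc / rho
    c0 = S
    disc = c1 * c1 - 4.0 * c2 * c0
    if disc < 0:
        raise ValueError(
            f"no real root: discriminant {disc:g} < 0 for S={S:g}, V={Vc:g}"
        )
    roots = ((-c1 + math.sqrt(disc)) / (2 * c2), (-c1 - math.sqrt(disc)) / (2 * c2))
    pos = [rt for rt in roots if rt > 0]
    if not pos:
        raise ValueError(
            f"no positive root for S={S:g}, V={Vc:g} (both roots non-positive); "
            "S and the bracket V term must have opposite signs"
        )
    r_max = min(pos)
    if cross_check:
        f = lambda r: c2 * r * r + c1 * r + c0
        lo, hi = r_max * 0.5, r_max * 2.0
        if f(lo) * f(hi) < 0:
            r_bis = brentq(f, lo, hi, xtol=1e-15, rtol=1e-14)
            if not math.isclose(r_max, r_bis, rel_tol=1e-9):
                raise RuntimeError("closed-form and bracketing roots disagree")
    return r_max, r_max - myelin_thickness


def radial_profile(profile: FieldProfile, r):
    """|B| at distance ``r`` from the profile's reference surface.

    Constant at ``plateau_B`` for r ≤ D_max, then plateau·(D_max/r)^p —
    continuous at the knee.  The degenerate D_max = 0, r = 0 corner returns
    the plateau.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    if profile.D_max == 0.0:
        out = np.where(r == 0.0, profile.plateau_B, 0.0)
    else:
        # for r <= D_max the ratio clamps to 1, giving the plateau
        out = profile.plateau_B * (profile.D_max
                                   / np.maximum(r, profile.D_max)) ** profile.decay_exponent
    return float(out) if out.ndim == 0 else out


# -- Biot–Savart grid map -----------------------------------------------------

def straight_wire_segments(current: float, length: float, n_segments: int = 101,
                           axis: Sequence[float] = (1.0, 0.0, 0.0),
                           center: Sequence[float] = (0.0, 0.0, 0.0)):
    """Discretize a straight wire into (midpoint, direction, dL, I) tuples."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    center = np.asarray(center, dtype=float)
    dL = length / n_segments
    s = (np.arange(n_segments) - (n_segments - 1) / 2.0) * dL
    return [(center + si * axis, axis, dL, current) for si in s]


def biot_savart_grid(segments, y: np.ndarray, z: np.ndarray,
                     x_plane: float = 0.0, mask_radius: float | None = None,
                     kernel: str = "segment-exact") -> FieldMap:
    """Sum the discretized Biot–Savart law over all wire segments.

    With ``kernel="segment-exact"`` (default) each straight segment
    contributes its exact line integral of (μ₀ I/4π)·dL×R̂/|R|², so a long
    straight wire reproduces the infinite-wire field essentially to the
    finite-length truncation error.  ``kernel="midpoint"`` instead evaluates
    the pointwise kernel at each segment midpoint (one term per segment),
    which converges to the exact sum as segments shrink.  Points within
    ``mask_radius`` (default: one grid cell) of a segment are masked to
    zero and flagged.
    """
    if len(segments) == 0:
        raise ValueError("need at least one wire segment")
    if kernel not in ("segment-exact", "midpoint"):
        raise ValueError(f"unknown kernel {kernel!r}")
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if len(y) < 2 or len(z) < 2:
        raise ValueError("grid must be non-degenerate")
    if mask_radius is None:
        mask_radius = max(abs(y[1] - y[0]), abs(z[1] - z[0]))
    mu0_4pi = 1e-7  # μ₀/4π exactly, in SI

    Y, Z = np.meshgrid(y, z, indexing="ij")
    P = np.stack([np.full_like(Y, x_plane), Y, Z], axis=-1)  # (ny, nz, 3)
    B = np.zeros_like(P)
    masked = np.zeros(Y.shape, dtype=bool)
    for mid, dirn, dL, I in segments:
        mid = np.asarray(mid, dtype=float)
        u = np.asarray(dirn, dtype=float)
        u = u / np.linalg.norm(u)
        w = P - (mid - 0.5 * dL * u)          # from segment start to field point
        s = w @ u                             # axial coordinate of the point
        rho_vec = w - s[..., None] * u
        rho = np.linalg.norm(rho_vec, axis=-1)
        s_clamped = np.clip(s, 0.0, dL)
        dist = np.linalg.norm(w - s_clamped[..., None] * u, axis=-1)
        close = dist < mask_radius
        masked |= close
        safe_rho = np.where(rho == 0.0, np.inf, rho)
        if kernel == "segment-exact":
            mag = (mu0_4pi * I / safe_rho) * (
                (dL - s) / np.sqrt((dL - s) ** 2 + rho ** 2)
                + s / np.sqrt(s ** 2 + rho ** 2))
            phi_hat = np.cross(np.broadcast_to(u, P.shape),
                               rho_vec / safe_rho[..., None])
            B += mag[..., None] * phi_hat
        else:
            Rv = P - mid
            Rn = np.linalg.norm(Rv, axis=-1)
            Rn = np.where(close, np.inf, Rn)
            cross = np.cross(np.broadcast_to(u, P.shape), Rv)
            B += mu0_4pi * I * dL * cross / Rn[..., None] ** 3
    if masked.any():
        warnings.warn(f"{int(masked.sum())} grid points within the masking "
                      "radius of the wire were zeroed", RuntimeWarning, stacklevel=2)
        B[masked] = 0.0
    return FieldMap(y=y, z=z, B_mag=np.linalg.norm(B, axis=-1),
                    n_segments=len(segments), masked=masked)


# -- induced electric field ---------------------------------------------------

def _check_uniform(ax: np.ndarray, name: str) -> float:
    d = np.diff(ax)
    if not np.allclose(d, d[0], rtol=1e-9, atol=0.0):
        raise ValueError(f"non-uniform {name} grid")
    return float(d[0])


def curl_2d(B: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Centered-difference curl of a 3-component field sampled on a (y, z)
    grid with no x-variation (∂/∂x ≡ 0).  B has shape (3, ny, nz)."""
    dy = _check_uniform(np.asarray(y, dtype=float), "y")
    dz = _check_uniform(np.asarray(z, dtype=float), "z")
    Bx, By, Bz = B
    dBz_dy = np.gradient(Bz, dy, axis=0, edge_order=2)
    dBy_dz = np.gradient(By, dz, axis=1, edge_order=2)
    dBx_dz = np.gradient(Bx, dz, axis=1, edge_order=2)
    dBx_dy = np.gradient(Bx, dy, axis=0, edge_order=2)
    return np.stack([dBz_dy - dBy_dz, dBx_dz, -dBx_dy])


def induced_E(B_series: np.ndarray, t: np.ndarray, y: np.ndarray, z: np.ndarray,
              constants: PhysicalConstants | None = None) -> np.ndarray:
    """E = 1/(μ₀ ε₀ ε_cns) ∫ ∇×(B(t) − B(t₀)) dt on a uniform transverse grid.

    Only the time-varying part of the field induces a (non-electrostatic)
    electric field, so the initial sample is the magnetostatic baseline and
    is subtracted before the curl; a time-constant B therefore induces
    nothing.  ``B_series`` has shape (nt, 3, ny, nz); the integral is
    trapezoidal in time.  Returns the accumulated E of shape (3, ny, nz).
    """
    constants = constants or PhysicalConstants()
    B_series = np.asarray(B_series, dtype=float)
    t = np.asarray(t, dtype=float)
    if B_series.ndim != 4 or B_series.shape[0] != len(t) or len(t) < 2:
        raise ValueError("need >= 2 time samples of shape (3, ny, nz)")
    dB = B_series - B_series[0]
    curls = np.stack([curl_2d(dB[k], y, z) for k in range(len(t))])
    integral = np.trapezoid(curls, x=t, axis=0)
    return integral / (constants.mu0 * constants.eps0 * constants.eps_cns)
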