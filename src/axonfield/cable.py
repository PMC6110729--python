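"""Compartmental cable model with axial-current coupling.

The membrane potential on a discretized fiber obeys a Crank–Nicolson
averaged cable equation

    C_m (V_i^{j+1} − V_i^j)/Δt
        = ½ [ (d/4R_i)·δ²V^{j+1}/Δx² − G_m V_i^{j+1} − J_i^{j+1}
            + (d/4R_i)·δ²V^j/Δx²     − G_m V_i^j     − J_i^j ],

where the classical applied-current term is replaced by an *axial* current
density J transferred from segment to segment.  J^{j+1} is supplied either
by the explicit axial-current expression (ionic fractions γ, δ plus a
resistive term) or by the coupling rule J_i^{j+1} = K·J_i^j with K ≥ 1.

Quantities are carried in the conventional electrophysiology unit set:
mV, ms, µm, mS/cm², µF/cm²; the resistivity surrogate ρ keeps the g/ml
value of the source parameterization (see the methods note).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .gating import GatingState, RateSet, equilibrium_state, gating_step, rate_constants

__all__ = [
    "FiberGeometry",
    "MembraneParams",
    "SolverConfig",
    "CableState",
    "CableRun",
    "segment_area",
    "segment_resistance",
    "ionic_current",
    "longitudinal_current",
    "axial_current",
    "current_density",
    "couple_segments",
    "thomas_solve",
    "crank_nicolson_step",
    "simulate",
]


@dataclass(frozen=True)
class FiberGeometry:
    """Geometry of one axonal segment.

    ``radius`` and ``segment_length`` in µm; ``myelin_thickness`` in µm
    (zero at a node of Ranvier); ``rho`` is the resistivity surrogate
    carried with the numeric value 1 in g/ml units.  Note the fiber
    *diameter* d = 2·radius and the myelin thickness are distinct fields
    even though both are conventionally written d.
    """

    radius: float
    segment_length: float
    segment_type: Literal["node", "myelinated"] = "node"
    myelin_thickness: float = 0.0
    rho: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.segment_length < 0:
            raise ValueError("segment_length must be non-negative")
        if self.myelin_thickness < 0:
            raise ValueError("myelin_thickness must be non-negative")
        if self.segment_type == "node" and self.myelin_thickness != 0.0:
            raise ValueError("node segments have myelin_thickness = 0")
        if self.rho <= 0:
            raise ValueError("rho must be positive")

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass(frozen=True)
class MembraneParams:
    """Membrane and coupling parameters.

    Conductances in mS/cm², potentials in mV, capacitances in µF/cm².
    γ, δ, η are the fractions of each ionic current feeding the axial
    current (each strictly inside (0, 1)); K_couple is the segment-coupling
    constant, constrained to ≥ 1 unless ``allow_dissipative`` is set.
    """

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

    def __post_init__(self) -> None:
        for name in ("gamma", "delta", "eta"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")
        if self.K_couple <= 0:
            raise ValueError("K_couple must be positive")
        if self.K_couple < 1.0 and not self.allow_dissipative:
            raise ValueError(
                "K_couple < 1 dissipates the propagating signal, which the "
                "coupling constraint (K such that J^j < J^{j+1}) forbids; "
                "set allow_dissipative=True to override"
            )


@dataclass(frozen=True)
class SolverConfig:
    """Discretization, boundary, stimulus and mode switches for a run."""

    dt: float = 0.001            # ms
    dx: float = 1.0              # µm
    n_segments: int = 10
    n_steps: int = 100
    boundary: Literal["sealed", "clamped"] = "sealed"
    stim_segment: int = 0
    stim_amplitude: float = 0.0  # depolarizing current density, µA/cm²
    stim_start: float = 0.0      # ms
    stim_duration: float = 0.0   # ms
    coupling: Literal["axial", "k-rule"] = "axial"
    literal_paper_mode: bool = True
    V_rest: float = -65.0
    rate_preset: str = "default"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dx <= 0:
            raise ValueError("dt and dx must be positive")
        if self.n_segments < 3:
            raise ValueError("need at least 3 segments")
        if not 0 <= self.stim_segment < self.n_segments:
            raise ValueError("stimulus segment index out of range")


@dataclass(frozen=True)
class CableState:
    """Per-segment fields at one time level."""

    V: np.ndarray
    gating: GatingState
    I_ion: np.ndarray
    I_cap: np.ndarray
    I_lng: np.ndarray
    I_ax: np.ndarray
    J: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.V)
        for name in ("I_ion", "I_cap", "I_lng", "I_ax", "J"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match V")


@dataclass(frozen=True)
class CableRun:
    """Full trajectory of a simulation: arrays indexed (time, segment)."""

    t: np.ndarray
    V: np.ndarray
    m: np.ndarray
    n: np.ndarray
    h: np.ndarray
    I_ax: np.ndarray
    J: np.ndarray
    effective_K: np.ndarray
    config: SolverConfig


# -- geometry -----------------------------------------------------------------

def segment_area(geometry: FiberGeometry) -> float:
    """Lateral-plus-endcap area A = 2πrx + 2πr² (µm²)."""
    r, x = geometry.radius, geometry.segment_length
    return 2.0 * np.pi * r * x + 2.0 * np.pi * r * r


def segment_resistance(geometry: FiberGeometry) -> float:
    """Segment resistance R = ρx / (2πr(x+r)), i.e. ρ·x/A with the area above."""
    if geometry.segment_length == 0:
        raise ValueError("zero-length segment has no defined resistance")
    r, x = geometry.radius, geometry.segment_length
    return geometry.rho * x / (2.0 * np.pi * r * (x + r))


# -- currents -----------------------------------------------------------------

def ionic_current(V, gating: GatingState, params: MembraneParams):
    """I_ion = ḡ_K n⁴ (V−V_K) + ḡ_Na m³h (V−V_Na) + g_L (V−V_L)."""
    n4 = np.asarray(gating.n) ** 4
    m3h = np.asarray(gating.m) ** 3 * np.asarray(gating.h)
    return (params.gbar_K * n4 * (np.asarray(V) - params.V_K)
            + params.gbar_Na * m3h * (np.asarray(V) - params.V_Na)
            + params.g_L * (np.asarray(V) - params.V_L))


def longitudinal_current(V, R: float, mode: str = "dimensional",
                         V_prev=None, step_term=0.0):
    """Longitudinal current along the fiber core.

    ``mode="dimensional"`` is Ohm's law, I = V/R.  ``mode="literal_paper"``
    reproduces the printed update form I = R·[V_prev + Δx·I_ion/C] exactly,
    with ``step_term`` standing for Δx·I_ion/C.
    """
    if R <= 0:
        raise ValueError("resistance must be positive")
    if mode == "dimensional":
        return np.asarray(V) / R
    if mode == "literal_paper":
        base = np.asarray(V if V_prev is None else V_prev)
        return R * (base + np.asarray(step_term))
    raise ValueError(f"unknown mode {mode!r}")


def axial_current(V, gating: GatingState, params: MembraneParams, R: float,
                  step: float, rate_preset: str = "default",
                  rates: RateSet | None = None):
    """Axial current transferred to the next segment.

    Evaluates, per segment,

        γ ḡ_K [n + s·(α_n(1−n) − β_n n)]⁴ (V⁺ − V_K)
      + δ ḡ_Na [m + s·(α_m(1−m) − β_m m)]³ [h + s·(α_h(1−h) − β_h h)] (V⁺ − V_Na)
      + R·V⁺,      with  V⁺ = V + s·I_ion/C  and  s = ``step``.

    The leak term is omitted: the Na/K conductances dominate it.  Passing the
    state at time level j−1 gives I_i^j; the state at level j gives I_i^{j+1}.
    Updated gate factors are clamped to [0, 1] with a warning if the step
    overshoots.
    """
    rs = rates if rates is not None else rate_constants(V, preset=rate_preset)
    I_ion = ionic_current(V, gating, params)
    V_plus = np.asarray(V) + step * I_ion / params.C_m

    def upd(p, a, b):
        return np.asarray(p) + step * (np.asarray(a) * (1 - np.asarray(p))
                                       - np.asarray(b) * np.asarray(p))

    n1 = upd(gating.n, rs.alpha_n, rs.beta_n)
    m1 = upd(gating.m, rs.alpha_m, rs.beta_m)
    h1 = upd(gating.h, rs.alpha_h, rs.beta_h)
    if any(np.any(p < 0) or np.any(p > 1) for p in map(np.asarray, (n1, m1, h1))):
        warnings.warn("axial-current gate update left [0, 1]; clamped",
                      RuntimeWarning, stacklevel=2)
        n1, m1, h1 = (np.clip(p, 0.0, 1.0) for p in (n1, m1, h1))
    return (params.gamma * params.gbar_K * n1 ** 4 * (V_plus - params.V_K)
            + params.delta * params.gbar_Na * m1 ** 3 * h1 * (V_plus - params.V_Na)
            + R * V_plus)


def current_density(I, A: float):
    """J = I / A."""
    if A <= 0:
        raise ValueError("area must be positive")
    return np.asarray(I) / A


def couple_segments(J_prev, K: float, allow_dissipative: bool = False):
    """Coupling rule J^{j+1} = K·J^j.

    K must be positive; K < 1 is rejected (it would dissipate the signal,
    violating the constraint J^j < J^{j+1}) unless explicitly overridden.
    """
    if K <= 0:
        raise ValueError("coupling constant K must be positive")
    if K < 1.0 and not allow_dissipative:
        raise ValueError(
            "K < 1 violates the non-dissipation coupling constraint "
            "(J^j < J^{j+1}); pass allow_dissipative=True to override"
        )
    return K * np.asarray(J_prev)


# -- linear algebra -----------------------------------------------------------

def thomas_solve(lower: np.ndarray, diag: np.ndarray, upper: np.ndarray,
                 rhs: np.ndarray) -> np.ndarray:
    """Solve a tridiagonal system by the Thomas algorithm (O(n), pivot-free).

    ``lower`` and ``upper`` have length n−1.  Falls back on a dense solve
    when the elimination would divide by a (near-)zero pivot without the
    system actually being singular; a genuinely singular system raises with
    the offending diagonal index.
    """
    n = len(diag)
    c = np.empty(n - 1)
    d = np.empty(n)
    piv = diag[0]
    if abs(piv) < 1e-300:
        raise np.linalg.LinAlgError("singular tridiagonal system at diagonal 0")
    c[0] = upper[0] / piv
    d[0] = rhs[0] / piv
    for i in range(1, n):
        piv = diag[i] - lower[i - 1] * c[i - 1]
        if abs(piv) < 1e-13 * max(abs(diag[i]), 1.0):
            return _dense_fallback(lower, diag, upper, rhs, i)
        if i < n - 1:
            c[i] = upper[i] / piv
        d[i] = (rhs[i] - lower[i - 1] * d[i - 1]) / piv
    x = np.empty(n)
    x[-1] = d[-1]
    for i in range(n - 2, -1, -1):
        x[i] = d[i] - c[i] * x[i + 1]
    return x


def _dense_fallback(lower, diag, upper, rhs, where: int) -> np.ndarray:
    A = np.diag(diag) + np.diag(lower, -1) + np.diag(upper, 1)
    if np.linalg.matrix_rank(A) < len(diag):
        raise np.linalg.LinAlgError(
            f"singular tridiagonal system (pivot vanished at diagonal {where})"
        )
    return np.linalg.solve(A, rhs)


# -- time stepping ------------------------------------------------------------

def _next_density(state: CableState, params: MembraneParams,
                  geometry: FiberGeometry, config: SolverConfig) -> np.ndarray:
    A = segment_area(geometry)
    if config.coupling == "k-rule":
        return couple_segments(state.J, params.K_couple, params.allow_dissipative)
    R = segment_resistance(geometry)
    I_next = axial_current(state.V, state.gating, params, R, step=config.dx,
                           rate_preset=config.rate_preset)
    return current_density(I_next, A)


def crank_nicolson_step(state: CableState, params: MembraneParams,
                        geometry: FiberGeometry, config: SolverConfig,
                        stim_density: float = 0.0) -> CableState:
    """Advance the cable one Δt by the Crank–Nicolson tridiagonal solve.

    ``stim_density`` is a depolarizing applied current density added at the
    configured stimulus segment for this step.  The gating system is advanced
    alongside by its Euler update at the pre-step voltages.
    """
    dt, dx = config.dt, config.dx
    nseg = len(state.V)
    R = segment_resistance(geometry)
    a = geometry.diameter / (4.0 * R) / dx ** 2

    J_j = state.J.copy()
    J_j1 = _next_density(state, params, geometry, config)
    if stim_density:
        # applied depolarizing current enters the balance opposite to J
        J_j = J_j.copy()
        J_j[config.stim_segment] -= stim_density
        J_j1 = J_j1.copy()
        J_j1[config.stim_segment] -= stim_density

    def laplacian(V):
        L = np.zeros_like(V)
        L[1:-1] = V[2:] - 2 * V[1:-1] + V[:-2]
        if config.boundary == "sealed":      # zero-flux ghost nodes
            L[0] = V[1] - V[0]
            L[-1] = V[-2] - V[-1]
        else:                                # clamped: boundary rows held fixed
            L[0] = L[-1] = 0.0
        return L

    Cdt = params.C_m / dt
    rhs = ((Cdt - params.G_m / 2.0) * state.V + (a / 2.0) * laplacian(state.V)
           - 0.5 * (J_j + J_j1))

    diag = np.full(nseg, Cdt + params.G_m / 2.0 + a)
    lower = np.full(nseg - 1, -a / 2.0)
    upper = np.full(nseg - 1, -a / 2.0)
    if config.boundary == "sealed":
        diag[0] = diag[-1] = Cdt + params.G_m / 2.0 + a / 2.0
    else:
        diag[0] = diag[-1] = 1.0
        upper[0] = lower[-1] = 0.0
        rhs[0], rhs[-1] = state.V[0], state.V[-1]

    V_new = thomas_solve(lower, diag, upper, rhs)

    rates = rate_constants(state.V, preset=config.rate_preset)
    gating_new = gating_step(state.gating, rates, dt)

    I_ion = ionic_current(V_new, gating_new, params)
    I_cap = params.C_m * (V_new - state.V) / dt
    if config.literal_paper_mode:
        I_lng = longitudinal_current(V_new, R, mode="literal_paper",
                                     V_prev=state.V, step_term=dx * I_ion / params.C_m)
    else:
        I_lng = longitudinal_current(V_new, R, mode="dimensional")
    I_ax = J_j1 * segment_area(geometry)
    return CableState(V=V_new, gating=gating_new, I_ion=I_ion, I_cap=I_cap,
                      I_lng=I_lng, I_ax=I_ax, J=J_j1)


def initial_state(config: SolverConfig) -> CableState:
    """Resting state: V ≡ V_rest, gating at its fixed point, all currents zero."""
    n = config.n_segments
    V = np.full(n, config.V_rest)
    eq = equilibrium_state(config.V_rest, preset=config.rate_preset)
    gating = GatingState(m=np.full(n, eq.m), n=np.full(n, eq.n), h=np.full(n, eq.h))
    z = np.zeros(n)
    return CableState(V=V, gating=gating, I_ion=z.copy(), I_cap=z.copy(),
                      I_lng=z.copy(), I_ax=z.copy(), J=z.copy())


def simulate(params: MembraneParams, geometry: FiberGeometry,
             config: SolverConfig, state: CableState | None = None) -> CableRun:
    """Run ``n_steps`` of the coupled cable + gating system.

    Deterministic given the config (the seed is recorded for config parity
    with stochastic extensions; the solver itself draws no random numbers).
    Aborts with the step index if the voltage field leaves the finite range.
    """
    state = initial_state(config) if state is None else state
    n, T = config.n_segments, config.n_steps
    out = {k: np.empty((T + 1, n)) for k in ("V", "m", "n", "h", "I_ax", "J")}
    effK = np.full((T, n), np.nan)

    def record(idx, s):
        out["V"][idx] = s.V
        out["m"][idx] = np.asarray(s.gating.m)
        out["n"][idx] = np.asarray(s.gating.n)
        out["h"][idx] = np.asarray(s.gating.h)
        out["I_ax"][idx] = s.I_ax
        out["J"][idx] = s.J

    record(0, state)
    for j in range(T):
        t = j * config.dt
        stim = (config.stim_amplitude
                if config.stim_start <= t < config.stim_start + config.stim_duration
                else 0.0)
        J_before = state.J
        state = crank_nicolson_step(state, params, geometry, config, stim_density=stim)
        if not np.all(np.isfinite(state.V)):
            raise RuntimeError(f"non-finite voltage detected at step {j}")
        with np.errstate(divide="ignore", invalid="ignore"):
            effK[j] = np.where(J_before != 0, state.J / J_before, np.nan)
        record(j + 1, state)

    t = np.arange(T + 1) * config.dt
    return CableRun(t=t, V=out["V"], m=out["m"], n=out["n"], h=out["h"],
                    I_ax=out["I_ax"], J=out["J"], effective_K=effK, config=config)
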