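"""Voltage-gated channel kinetics.

Two layers are provided.  The generic layer is a two-state Markov channel
(closed ⇌ open with Arrhenius-type voltage-dependent rates), from which the
resting potential of the circuit follows in closed form.  The concrete layer
is the classic m/n/h gating system: six rate functions α_p(V), β_p(V) for
p ∈ {m, n, h}, steady states p_∞ = α/(α+β), time constants τ_p = 1/(α+β),
and a first-order (Euler) update of the gate probabilities.

Two rate presets exist.  ``"default"`` uses the printed coefficients of the
source model (α_n prefactor 0.1, β_m decay 0.00556/mV); ``"canonical_hh"``
uses the textbook Hodgkin–Huxley values (0.01 and 1/18) for side-by-side
sanity comparisons.  Voltages are absolute membrane potentials in mV (rest
near −65 mV); rates are in 1/ms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MarkovChannel",
    "GatingState",
    "RateSet",
    "rate_constants",
    "steady_state",
    "gating_step",
]


@dataclass(frozen=True)
class MarkovChannel:
    """Two-state channel with rates k⁺ = k₀⁺·e^{−αV}, k⁻ = k₀⁻·e^{−βV}."""

    k_plus0: float
    k_minus0: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.k_plus0 <= 0 or self.k_minus0 <= 0:
            raise ValueError("base rate constants must be positive")

    def rates(self, V: float) -> tuple[float, float]:
        return self.k_plus0 * math.exp(-self.alpha * V), self.k_minus0 * math.exp(-self.beta * V)

    def equilibrium_voltage(self) -> float:
        """Voltage at which k⁺(V) = k⁻(V): V₀ = ln(k₀⁻/k₀⁺)/(β−α)."""
        if self.beta == self.alpha:
            raise ValueError("beta == alpha: equilibrium voltage undefined")
        return math.log(self.k_minus0 / self.k_plus0) / (self.beta - self.alpha)

    def open_fraction_dynamics(self, V: float, convention: str = "sum") -> tuple[float, float]:
        """(f_∞, τ) of df₀/dt = k⁺(1−f₀) − k⁻f₀ at fixed V.

        ``convention="sum"`` (default) is the standard relaxation algebra,
        f_∞ = k⁺/(k⁺+k⁻), τ = 1/(k⁺+k⁻) — the only form consistent with
        df₀/dt = (f_∞−f₀)/τ.  ``convention="literal"`` exposes the
        minus-sign variants f_∞ = k⁺/(k⁺−k⁻), τ = 1/(k⁺−k⁻) exactly as a
        documented alternative; note τ < 0 whenever k⁻ > k⁺.
        """
        kp, km = self.rates(V)
        if convention == "sum":
            return kp / (kp + km), 1.0 / (kp + km)
        if convention == "literal":
            if kp == km:
                raise ValueError("k+ == k-: literal-convention tau undefined")
            return kp / (kp - km), 1.0 / (kp - km)
        raise ValueError(f"unknown convention {convention!r}")


@dataclass(frozen=True)
class GatingState:
    """Gate-open probabilities; each entry (scalar or array) lies in [0, 1]."""

    m: np.ndarray | float
    n: np.ndarray | float
    h: np.ndarray | float

    def __post_init__(self) -> None:
        for name in ("m", "n", "h"):
            p = np.asarray(getattr(self, name))
            if np.any(p < 0) or np.any(p > 1):
                raise ValueError(f"gate probability {name} outside [0, 1]")


@dataclass(frozen=True)
class RateSet:
    """α_p, β_p for p in {m, n, h} at a given voltage, in 1/ms."""

    alpha_m: np.ndarray | float
    beta_m: np.ndarray | float
    alpha_n: np.ndarray | float
    beta_n: np.ndarray | float
    alpha_h: np.ndarray | float
    beta_h: np.ndarray | float


def _linoverexp(coef: float, u):
    """coef·u / (1 − e^{−0.1·u}) with the removable singularity at u = 0 filled
    by its analytic limit coef/0.1."""
    u = np.asarray(u, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = coef * u / (-np.expm1(-0.1 * u))
    out = np.where(np.abs(u) < 1e-9, coef / 0.1, out)
    return out if out.ndim else float(out)


#: (alpha_n_coef, beta_m_decay) per preset; all other coefficients coincide.
_PRESETS = {
    "default": (0.1, 0.00556),
    "canonical_hh": (0.01, 1.0 / 18.0),
}


def rate_constants(V, preset: str = "default") -> RateSet:
    """Evaluate the six rate functions at membrane potential ``V`` (mV).

    Accepts scalars or arrays.  Removable singularities of α_m (V = −40) and
    α_n (V = −55) return their analytic limits.
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    an_coef, bm_decay = _PRESETS[preset]
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    rs = RateSet(
        alpha_m=_linoverexp(0.1, V + 40.0),
        beta_m=_scal(4.0 * np.exp(-bm_decay * (V + 65.0))),
        alpha_n=_linoverexp(an_coef, V + 55.0),
        beta_n=_scal(0.125 * np.exp(-0.0125 * (V + 65.0))),
        alpha_h=_scal(0.07 * np.exp(-0.05 * (V + 65.0))),
        beta_h=_scal(1.0 / (1.0 + np.exp(-0.1 * (V + 35.0)))),
    )
    return rs


def _scal(x):
    x = np.asarray(x)
    return float(x) if x.ndim == 0 else x


def steady_state(V, preset: str = "default"):
    """Steady states and time constants of the gating ODEs at fixed V.

    Returns ``(m_inf, n_inf, h_inf, tau_m, tau_n, tau_h)`` with
    p_∞ = α_p/(α_p+β_p) and τ_p = 1/(α_p+β_p) (ms).
    """
    r = rate_constants(V, preset=preset)
    out = []
    for a, b in ((r.alpha_m, r.beta_m), (r.alpha_n, r.beta_n), (r.alpha_h, r.beta_h)):
        s = np.asarray(a) + np.asarray(b)
        if np.any(s == 0):
            raise ValueError("alpha + beta = 0: degenerate kinetics")
        out.append((np.asarray(a) / s, 1.0 / s))
    (m_inf, tau_m), (n_inf, tau_n), (h_inf, tau_h) = out
    return tuple(_scal(x) for x in (m_inf, n_inf, h_inf, tau_m, tau_n, tau_h))


def _euler_gate(p, alpha, beta, dt):
    return np.asarray(p) + dt * (np.asarray(alpha) * (1.0 - np.asarray(p))
                                 - np.asarray(beta) * np.asarray(p))


def gating_step(state: GatingState, rates: RateSet, dt: float) -> GatingState:
    """Advance all gates one Euler step: p ← p + Δt(α(1−p) − βp).

    Results are clamped to [0, 1]; clamping emits a warning because it means
    dt is too large for the local time constants.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    m = _euler_gate(state.m, rates.alpha_m, rates.beta_m, dt)
    n = _euler_gate(state.n, rates.alpha_n, rates.beta_n, dt)
    h = _euler_gate(state.h, rates.alpha_h, rates.beta_h, dt)
    stacked = [np.asarray(p) for p in (m, n, h)]
    if any(np.any(p < 0) or np.any(p > 1) for p in stacked):
        warnings.warn("gate probability left [0, 1] and was clamped; reduce dt",
                      RuntimeWarning, stacklevel=2)
        m, n, h = (np.clip(p, 0.0, 1.0) for p in stacked)
    return GatingState(m=_scal(m), n=_scal(n), h=_scal(h))


def equilibrium_state(V: float, preset: str = "default") -> GatingState:
    """Gating state initialized at the fixed point of the gating ODEs."""
    m_inf, n_inf, h_inf, *_ = steady_state(V, preset=preset)
    return GatingState(m=m_inf, n=n_inf, h=h_inf)
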