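"""Channel-gate kinetics: steady states and exponential relaxation.

Evaluates the m/n/h rate functions at a clamped membrane potential, then
steps the gating ODEs forward and compares against the closed-form
exponential approach to steady state.
"""

import math

from axonfield.gating import GatingState, gating_step, rate_constants, steady_state

V = -50.0  # clamped membrane potential, mV
m_inf, n_inf, h_inf, tau_m, tau_n, tau_h = steady_state(V)
print(f"At V = {V:.0f} mV:")
print(f"  steady states  m_inf={m_inf:.4f}  n_inf={n_inf:.4f}  h_inf={h_inf:.4f}")
print(f"  time constants tau_m={tau_m:.3f}  tau_n={tau_n:.3f}  tau_h={tau_h:.3f} ms")

rates = rate_constants(V)
state = GatingState(m=0.05, n=0.9, h=0.9)
dt = min(tau_m, tau_n, tau_h) / 200.0
t = 0.0
for _ in range(2000):
    state = gating_step(state, rates, dt)
    t += dt
analytic_m = m_inf + (0.05 - m_inf) * math.exp(-t / tau_m)
print(f"\nAfter {t:.2f} ms of stepping (dt = {dt:.4f} ms):")
print(f"  m = {float(state.m):.6f}   closed form = {analytic_m:.6f}")
print("The Euler-stepped gate matches the analytic exponential relaxation;")
print("each gate decays toward its steady state with its own voltage-dependent tau.")
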