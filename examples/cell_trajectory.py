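"""A charged cell moving through the fiber's field: gyration and drag.

Integrates m dv/dt = qE + q v x B - 6*pi*eta*r v for a negatively charged
sphere.  First a pure magnetic orbit (speed conserved, circular gyration),
then Stokes drag toward the terminal velocity qE/(6*pi*eta*r).
"""

import numpy as np

from axonfield.dynamics import CellParticle, step_trajectory, stokes_drag_coefficient

# scaled units so the gyration is visible in a short run
cell = CellParticle(charge=-1.0, radius=1.0, mass=1.0,
                    velocity=np.array([1.0, 0.0, 0.0]),
                    medium_viscosity=1.0 / (6.0 * np.pi))
B = np.array([0.0, 0.0, 2.0])
period = 2 * np.pi * cell.mass / (abs(cell.charge) * B[2])
df = step_trajectory(cell, lambda p: (np.zeros(3), B), dt=period / 500,
                     n_steps=1000, drag=False)
speed = np.sqrt(df.vx**2 + df.vy**2 + df.vz**2)
radius = 0.5 * (df.x.max() - df.x.min())
print(f"Magnetic orbit: radius {radius:.4f} (theory {cell.mass / B[2]:.4f}),"
      f" speed drift {abs(speed.iloc[-1] / speed.iloc[0] - 1):.2e}")
print("The magnetic force does no work: the cell circles at constant speed.")

cell2 = CellParticle(charge=-1.0, radius=1.0, mass=1.0,
                     medium_viscosity=1.0 / (6.0 * np.pi))
E = np.array([3.0, 0.0, 0.0])
c = stokes_drag_coefficient(cell2)
df2 = step_trajectory(cell2, lambda p: (E, np.zeros(3)), dt=0.05,
                      n_steps=800, drag=True)
print(f"\nWith drag: v_x settles at {df2.vx.iloc[-1]:.4f} "
      f"(terminal velocity qE/6*pi*eta*r = {cell2.charge * E[0] / c:.4f})")
print("A negative cell drifts against E; drag caps the speed at the Stokes")
print("terminal velocity, the regime relevant for cells in CNS tissue.")
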