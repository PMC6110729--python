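"""Magnetic-field ranges and radial profiles around a fiber.

In calibration ("paper") mode the node and myelinated profiles carry the
published plateau strengths and homogeneity ranges; in SI mode the range
comes from the closed-form root of B(r) = 0.  Both are shown.
"""

from axonfield.field import FieldConfig, find_range, radial_profile
from axonfield.scenarios import segment_profile
from axonfield.units import UnitPolicy

policy = UnitPolicy(mode="paper")
for seg in ("node", "myelinated"):
    prof, prov = segment_profile(seg, policy)
    print(f"{seg:>10}: plateau {prof.plateau_B:.2e} T at the "
          f"{prof.reference_surface}, homogeneous out to {prof.D_max:.3f} um")
    print(f"{'':>12}provenance: {prov.tag} ({prov.mode})")
    for r in (0.0, prof.D_max, 2 * prof.D_max):
        print(f"{'':>12}|B|({r:6.3f} um) = {radial_profile(prof, r):.2e} T")

# SI mode: the homogeneity range is the positive root of the bracket
# S + 2 pi r (x + r) V / (rho x) = 0, here with an illustrative SI-consistent
# parameter set (S in A, x in m, rho as the resistivity surrogate, V in V).
fc = FieldConfig(V_term=0.065, literal=False)
r_max, D_max = find_range(S=-4.0e-5, x=1.08e-6, rho=1.0, config=fc)
print(f"\nSI mode example: B(r) crosses zero at r_max = {r_max * 1e6:.3f} um")
print("Inside that radius the field is treated as homogeneous; beyond it the")
print("profile decays as a power law and the field becomes inhomogeneous.")
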