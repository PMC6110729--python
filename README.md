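# axonfield

Modeling toolkit for the electromagnetic fields generated around nerve
fibers by propagating action potentials, and for the forces those fields
exert on charged cells (lymphocytes, stem cells) in nervous tissue.

The package is aimed at computational neurophysiologists and biophysicists
who want to explore the hypothesis that cell–fiber interactions are partly
electromagnetic: it couples a compartmental Hodgkin–Huxley cable model to a
field model around the fiber and a charged-particle integrator for cells.

## The model in brief

**Cable with axial coupling.** The membrane potential on a discretized
fiber follows a Crank–Nicolson cable equation in which the classical
applied-current term is replaced by an axial current density transferred
between segments,

    C_m (V_i^{j+1} − V_i^j)/Δt = ½[(d/4R)·δ²V/Δx² − G_m V − J]^{j+1,j},
    J_i^{j+1} = K·J_i^j   (K ≥ 1),

with J supplied either by the coupling constant K or by an explicit
expression built from the HH conductances (g_K = ḡ_K n⁴, g_Na = ḡ_Na m³h)
and a resistive term, on the segment geometry A = 2πrx + 2πr²,
R = ρx/(2πr(x+r)).

**Field around the fiber.** Near the fiber the loop law gives
B(r) = μ₀[S + 2πr(x+r)V/(ρx)]/(2πr) with S = g_K(V−V_K) + g_Na(V−V_Na);
its positive root defines the homogeneity range D_max within which the
field is treated as constant. A Biot–Savart segment sum produces the full
transverse |B| map, and E = 1/(μ₀ε₀ε_cns)·∫∇×B dt gives the induced
electric field of the time-varying part.

**Cells.** Charged spheres in a Newtonian fluid: m·dv/dt = qE + q·v×B −
6πηr·v, integrated by an exactly speed-preserving implicit-midpoint update.

Because the published headline values (field plateaus of 3.0 and
2.3×10⁻¹² T, ranges of 6.606 and 2.066 µm, …) stem from a worked arithmetic
that is not unit-consistent, the package runs in two modes: `si` computes
everything dimensionally consistently, while `paper` carries those values
as provenance-tagged calibration anchors. See `docs/methods.md`.

## Worked example

```python
from axonfield.scenarios import DemyelinationScenario, demyelinate

delta, surface, prov = demyelinate(DemyelinationScenario(fraction=0.5))
print(delta, surface, prov.tag)
```

prints

```
3.500000000000001e-13 2.6500000000000002e-12 demyelination-linear-increment
```

meaning: losing half the myelin raises the magnetic field at the fiber
surface by 0.35×10⁻¹² T, from the intact neurilemma value 2.3×10⁻¹² T to
2.65×10⁻¹² T; the provenance tag records that the endpoints are calibration
anchors. The `examples/` directory holds one short script per capability
(gating relaxation, stimulated cable run, field ranges and maps,
demyelination, bundles, cell trajectories); each prints the numbers it
computes and what they mean, e.g.

```sh
$ python examples/nerve_bundle.py
   N   paper-calibrated    sqrt-cancellation
    1   3.000e-12 T        3.000e-12 T
   10   4.243e-12 T        3.721e-12 T
  100   6.000e-12 T        6.000e-12 T
...
```

A thin CLI wraps the same functions:

```sh
axonfield scenario demyelinate --fraction 0.5
axonfield scenario bundle --n 100
axonfield field range --preset node
axonfield simulate --config run.yaml --out traj.npz
```

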