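# Methods

## The model

`axonfield` implements a compartmental Hodgkin–Huxley cable model in which
the classical applied-current term is replaced by an **axial current**
transferred from each axonal segment to the next, and the electromagnetic
field that this current system generates around the fiber.

### Gating kinetics (`axonfield.gating`)

Channels are two-state Markov processes (closed ⇌ open) with Arrhenius-type
voltage-dependent rates k⁺ = k₀⁺e^(−αV), k⁻ = k₀⁻e^(−βV); the circuit's
resting potential follows as V₀ = ln(k₀⁻/k₀⁺)/(β−α). The concrete gating
system is the classic m/n/h trio with g_K = ḡ_K n⁴ and g_Na = ḡ_Na m³h.
The rate closed forms are taken verbatim from the source parameterization,
including two values that differ from the canonical 1952 constants: the α_n
prefactor is 0.1 (canonical 0.01) and the β_m exponential decay is
0.00556/mV (canonical 1/18). The `canonical_hh` preset restores the
textbook values for side-by-side comparison. Removable singularities of α_m
(V = −40 mV) and α_n (V = −55 mV) are filled with their analytic limits.

The source material writes the Markov time constant as τ = 1/(k⁺ − k⁻) and
f_∞ = k⁺/(k⁺ − k⁻). These minus-sign forms yield negative τ whenever
k⁻ > k⁺; the standard relaxation algebra (sums) is the only form consistent
with df₀/dt = (f_∞ − f₀)/τ, so the sum forms are the default and the
minus-sign variants are available only behind `convention="literal"`.

Gate updates are first-order Euler: p ← p + Δt(α(1−p) − βp), clamped to
[0, 1] with a warning if the step overshoots. For fixed V the stepped
solution tracks the closed form p_∞ + (p₀−p_∞)e^(−t/τ) — this is verified to
0.1% in the test suite at dt = τ/1000.

### Cable solver (`axonfield.cable`)

The membrane potential obeys the Crank–Nicolson averaged discretization

    C_m (V_i^{j+1} − V_i^j)/Δt = ½[ (d/4R)·δ²V^{j+1}/Δx² − G_m V^{j+1} − J^{j+1}
                                  + (d/4R)·δ²V^j/Δx²     − G_m V^j     − J^j ]

solved per step by a hand-written Thomas algorithm (O(n), pivot-free) with a
dense fallback when a pivot degenerates. Segment geometry uses
A = 2πrx + 2πr² and R = ρx/(2πr(x+r)) (so R·A = ρx identically). The
current-density term J is supplied either by

- the explicit **axial-current expression** (default): ionic fractions
  γḡ_K[n-update]⁴(V⁺−V_K) + δḡ_Na[m-update]³[h-update](V⁺−V_Na) plus a
  resistive term R·V⁺, with V⁺ = V + step·I_ion/C, divided by the segment
  area; the leak conductance is dropped from this expression because the
  Na/K terms dominate it; or
- the **coupling rule** J^{j+1} = K·J^j (fast mode). K < 1 would dissipate
  the propagating signal and is rejected unless explicitly overridden. A
  per-step diagnostic reports the effective K = J^{j+1}/J^j so the two
  routes can be compared.

Note the axial-current expression advances its gate factors with the
*spatial* step Δx, reproducing the printed form exactly; the solver's own
time advancement of the gating ODEs always uses Δt (an ODE in time cannot
be advanced by a length). The longitudinal current has two modes:
`dimensional` (Ohm's law, I = V/R) and `literal_paper`
(I = R·[V_prev + Δx·I_ion/C], the printed update form; note the two differ
dimensionally — the literal form is kept for fidelity, the dimensional one
is used in SI-consistency tests).

Boundaries default to sealed ends (zero-flux ghost nodes), which preserves
the discrete conservation of the diffusion operator (mean V conserved to
1e-10 with J ≡ 0, G_m = 0); clamped ends are optional. The stimulus is a
rectangular depolarizing current-density pulse at a configurable segment.
Initial gating is the fixed point at V_rest (default −65 mV, the reference
voltage of the rate constants).

### Field model (`axonfield.field`)

Close to the fiber the loop form of the Ampère–Maxwell law, with the
enclosed-charge term dropped (it vanishes in the homogeneous regime; a
user-supplied hook Q_enc(t) covers the inhomogeneous regime), gives

    B(r) = μ₀[S + 2πr(x+r)·V/(ρx)]/(2πr),   S = g_K(V−V_K) + g_Na(V−V_Na).

Setting B(r) = 0 yields the homogeneity range r_max as the positive root of
a quadratic, computed in closed form and cross-checked by a bracketing root
solve. For myelinated segments D_max = r_max − myelin thickness. Beyond
D_max the radial profile decays as plateau·(D_max/r)^p with p = 1 at nodes
(line-current behavior) and p = 2 across myelin, both configurable.

The full transverse |B| map sums the Biot–Savart law over wire segments.
The default kernel integrates each straight segment *exactly* (the
closed-form finite-segment field); a `midpoint` kernel evaluating
dL×R̂/R² once per segment is available and converges to the exact sum as
segments shrink. The exact kernel is the default because the pointwise
kernel carries an aliasing error of order 1% when the segment length is
comparable to the field-point distance. Grid points within one cell of the
wire are masked and flagged.

The induced electric field is E = 1/(μ₀ε₀ε_cns)·∫∇×(B(t) − B(t₀))dt with a
centered-difference curl and trapezoidal time integral. The initial sample
is subtracted as the magnetostatic baseline: only the time-varying part of
B induces a non-electrostatic E, so a static field induces nothing.

### Calibration modes and anchors (`axonfield.units`)

The published headline numbers of the source model — 3.0×10⁻¹² T at the
node axolemma, 2.3×10⁻¹² T at the neurilemma, ranges 6.606 / 2.066 / 5.696
/ 12.005 µm, bundle peak 6.0×10⁻¹² T — come from a worked arithmetic mixing
mS/cm², mV, cm and g/ml that does not reduce to a single consistent unit
system (solving the printed bracket literally gives a range of ~22 cm, not
6.6 µm). The package therefore runs in one of two modes:

- **`si`** — every computation is dimensionally consistent; used by all
  property tests. Here S is the total segment driving current (A), ρ the
  resistivity surrogate, and B comes out in tesla.
- **`paper`** — the published values are *calibration anchors*: scenario
  operations return them directly, each tagged with provenance
  (anchor name, description, `paper-anchor` mode), never silently mixed
  into SI computations.

A small unit registry (metric prefixes over the quantities this package
touches) backs explicit conversions; round trips are exact to 1e-12.

ρ = 1 g/ml is carried with its published numeric value as a
resistivity-surrogate parameter inside the resistance formula; it is not a
physical resistivity and is documented as such.

### Scenarios (`axonfield.scenarios`)

- **Demyelination**: losing a fraction f of the myelin raises the surface
  field linearly, ΔB = f·(B_bare − B_intact); with the anchors this gives
  0.35×10⁻¹² T at f = 0.5 and 0.7×10⁻¹² T at f = 1. The absolute
  post-demyelination field depends on a baseline convention (neurilemma
  default, axolemma optional — published discussions use both); the
  increment itself is convention-independent and is the tested quantity.
- **Bundles**: opposing currents in a bundle partially cancel, so the
  aggregate field grows sublinearly. Only two endpoints are published
  (no change at N = 1, doubling at N = 100); two labeled models
  interpolate them: `paper-calibrated` s(N) = N^(ln2/ln100) and
  `sqrt-cancellation` s(N) = 1 + (√N−1)/9. Both are models anchored at the
  endpoints, not derived laws. The bundle range in SI mode treats the
  bundle as one wire of radius R and reuses the root solve with the
  aggregated driving sum, measuring the range from the bundle surface.

### Cell dynamics (`axonfield.dynamics`)

Cells are charged rigid spheres in a Newtonian fluid (default viscosity
0.0012 Pa·s, the published tissue value). Forces: Coulomb qE, Lorentz
q·v×B, Stokes drag −6πηr·v. The cell charge has no published value and is
a required configuration parameter (the demo value −1e-14 C is arbitrary).

The velocity update is the implicit-midpoint (Crank–Nicolson) rule solved
as a 3×3 linear system per step. This choice is deliberate: the midpoint
rotation is a Cayley transform — exactly orthogonal — so a pure magnetic
force conserves speed to round-off at any step size, making the "magnetic
force does no work" property testable at practical dt; the implicit drag
term is unconditionally stable and reproduces the terminal velocity
v_t = qE/(6πηr) exactly at steady state. A Boris-style split update is the
optional high-accuracy alternative. Optional Brownian velocity kicks
(seeded, off by default) are an extension beyond the base model, as are
any of the pressure-driven/Lévy-walk transport behaviors of real cells,
which this integrator does not attempt.

## What the fixtures emulate — and what they do not

The preset fixtures carry the published parameter set: node length
1.08 µm, myelinated segment 3.08 µm, myelin thickness 3.63 µm, ḡ_K = 12.5
and ḡ_Na = 28 mS/cm², driving forces 12 and −115 mV, ρ = 1 g/ml, 100-axon
bundles. Values the source never prints are package defaults documented as
such: g_L = 0.3 mS/cm², V_K = −77, V_Na = 50, V_L = −54.4 mV, C_m = 1
µF/cm², G_m = 0, γ = δ = η = 0.1, K = 1.0, axon radius 5 µm, ε_cns = 80.

Passing tests therefore show the discretizations converge and the
calibrated arithmetic is internally consistent; they do not validate the
absolute field magnitudes against tissue measurements, nor do the fixtures
capture myelin conductance structure, extracellular return currents, or
fiber tortuosity.

## Numerical choices

- CN tridiagonal solve: Thomas algorithm, dense fallback at degenerate
  pivots, singularity reported with the offending diagonal index.
- Gate clamping to [0, 1] always warns — it signals too large a step.
- Removable singularities filled within |u| < 1e-9 of the singular point.
- Root solve: quadratic closed form (discriminant branch, smaller positive
  root), brentq cross-check at 1e-9 relative; S = 0 degenerates to range 0.
- Default problem sizes (10–20 segments, 1–3 ms, 201² grids, 1e4 particle
  steps) keep every example and test in seconds on one core.

## Known limitations

- `paper` mode returns calibration constants; it cannot extrapolate them.
- The K-rule coupling is spatially uniform; no per-internode heterogeneity
  or patchy demyelination.
- Single fiber per solve; no branching, synapses, or multi-fiber coupling.
- The induced-E computation assumes a uniform transverse grid and no
  x-variation of B.
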