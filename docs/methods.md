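# Methods

This note records the model equations as implemented, the defaults and
why they were chosen, the numerical machinery, and the known
limitations.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Network hemodynamics

Flow in each segment follows Poiseuille's law with the in vivo apparent
viscosity law (diameter-dependent 0.45-hematocrit viscosity, a
hematocrit-dependence exponent C(D), and the effective-diameter
endothelial-surface-layer correction `(D/(D−1.1))²`; plasma baseline
1 cP).  The law is undefined at D ≤ 2.7 μm and the wall dynamics floor
diameters at 2.8 μm.  Mass conservation at nodes gives a sparse linear
system for node pressures (Dirichlet boundaries in mmHg, converted at
1333.22 dyn cm⁻² per mmHg); discharge hematocrit propagates through the
flow-ordered network, with the empirical logit partition law at
diverging bifurcations.  The asymmetry coefficient of that law carries
the (1−H_D) factor of its published form,
`A = −13.29 [(D₁²−D₂²)/(D₁²+D₂²)] (1−H_D)/D_f`.  Daughter hematocrits
are capped at 1 with the excess returned to the sibling.  The coupled
fixed point (pressures → hematocrit → viscosity) is under-relaxed
(damping 0.5, raised adaptively while converging monotonically) to a
relative flow tolerance of 10⁻⁶, then polished undamped to machine
precision so the reported state satisfies both the pressure system and
exact red-cell balance; marginal bifurcations that limit-cycle below
10⁻⁴ relative amplitude are accepted as converged.  RBC flux uses a
cell volume of 70 fL; vessels are *flowing* above 12.5 cells/s.  The
inflow discharge hematocrit defaults to 0.45 (systemic hamster value);
it is configurable.

## Vascular smooth muscle wall

Parameters derive from D0, the passive diameter at 100 mmHg:
C_pass = 6.666·D0, C′_pass = −0.027·D0 + 12.52, C_act = 1.30·D0^1.48,
C′_act = −0.00059·D0 + 0.773, C″_act = −0.00080·D0 + 0.415,
C_myo = 1.369/D0 cm/dyn, C_shear = 0.0258 cm²/dyn,
C_meta = 5000 (μM·cm)⁻¹, with D0 in μm.  The stimulus sign convention
is excitatory myogenic, inhibitory shear and metabolic.  Wall tension
uses the mean of the segment's end-node pressures.

## Oxygen transport

Tissue: D·α·∇²p = M0·p/(p+P0) with P0 = 1 mmHg;
D·α = 9.4×10⁻¹⁰ cm³O₂ cm⁻¹ s⁻¹ mmHg⁻¹, effective blood solubility
3.1×10⁻⁵ cm³O₂ cm⁻³ mmHg⁻¹, RBC binding capacity 0.5 cm³O₂ per cm³
RBC, Hill n = 2.55, P50 = 26 mmHg.  Arterial inflow PO2 100 mmHg;
venular inflows (if any) 20 mmHg.

The Green's-function discretization: perfused vessels are subsegments
(≤ 25 μm by default; 50 μm in sweeps) acting as oxygen sources, tissue
is a regular cubic sink mesh (20 μm default; 60 μm in sweeps) covering
the vascular sheet with 50 μm lateral and 15 μm axial padding (the
networks model a thin planar muscle, so metabolizing tissue does not
extend far beyond the sheet).  Self-interactions use the
equivalent-cylinder surface potential `2 asinh(l/2a)/(4πDα l)` for
sources and the equivalent-sphere form for sinks; pair distances are
clamped below half a subsegment length, which keeps the source matrix
positive definite where vessels touch.

Free-space kernels cannot satisfy a global balance by themselves, so the
superposition carries an unknown additive far-field level c together
with the requirement that total source strength equal total sink
strength (an insulated-domain closure).  This also makes the
zero-demand limit exact: with M0 = 0 the tissue sits at the perfused
vessels' PO2.  The level is driven by a damped scalar update using the
smaller of a secant and an analytic sensitivity estimate; when the
balance provably does not respond to the level (the free-space-leak mode
of small, oversupplied configurations) the level freezes and the
stationary state is returned flagged `converged=False`.

The source-strength system is solved with the blood PO2 at the wall as
the matching condition, augmented by the linearized within-segment
convective transport (a lower-triangular block with sensitivity
1/(Q·C′(P)) per subsegment) that makes the alternation an inexact
Newton iteration; vessels act as sources only (uptake from an
oxygen-rich neighborhood is neglected, consistent with neglecting
venous exchange), and a sweep-truncation guarantees no segment extracts
more oxygen than arrives at its inlet.  Subsegments whose matched
strength would be negative are switched off (complementarity) and
re-enter when the local field falls below their blood PO2.  The sink
nonlinearity is solved by damped Newton–Krylov with FFT-evaluated
sink–sink convolutions.  Convergence requires a stationary tissue field
(0.5 mmHg), stationary blood PO2 in at least 99% of subsegments
(vessels at the edge of depletion sit on kinks of the extraction
nonlinearity and may jitter within a bounded band; the returned blood
profile is a short trailing average), and a closed convective balance
(1.5%).  Blood PO2 above the Hill plateau carries almost no content
information and is compared capped at 120 mmHg; inversion of the
content relation is capped at 150 mmHg.

Feed vessels A and LA exchange with a fixed-consumption sleeve of width
18.8 μm.  Because their tuned hydraulic lengths are lumped resistances
(possibly decimeters), both the sleeve consumption and the conducted
signal decay over these vessels use a fixed anatomical extent of
1.5 mm.

Wall PO2 for signaling: subsegments releasing oxygen read the blood
(equal to the matched field); zero-flux subsegments (stagnant vessels,
or ones switched off by complementarity) read the local tissue field,
since zero flux implies no radial gradient at the wall.

## Conducted metabolic signal

The local signal density is proportional to the oxygen deficit at the
wall, k_sig·(M0 − M(P_wall)) = k_sig·M0·P0/(P_wall+P0), so it scales
with demand.  It is conducted upstream with exponential decay (length
constant L0 = 1 cm), summed where daughters meet a parent, split in
proportion to parent diameters where one downstream vessel feeds two
parents, and virtual distal segments (0.1 cm, venular-PO2 deficit)
supply a boundary signal at outflows.  The absolute scale k_sig is a
unit convention the model must fix; k_sig = 0.02 μM per unit demand was
chosen so that (a) the calibrated per-vessel tone constants C″_tone
fall within the range reported for the antecedent vasoregulation models
(about −1 to 132) and (b) the calibrated reference is a dynamically
stable operating point.  Because the deficit is proportional to M0, the
demand response is carried largely by this direct factor rather than by
a high within-state feedback gain.

## Reference state and calibration

Boundary pressures are 100/12.91 mmHg; the A, LV, and V segments are
length-scaled to drops of 10, 1.49, and 1 mmHg, and the LA length is
root-found so the arterial side of the microvessel network sits at
66 ± 0.05 mmHg.  Capillaries are nudged by at most ±1.2 μm (the imaging
uncertainty of diameter measurements) toward their intended
flowing/nonflowing labels.  Tone inversion: with the reference
hemodynamics, oxygen field (M0 = 1) and conducted signals,
A_ref = (T_c − T_pass)/T_act^max at the control diameter,
S_tone,ref = logit(A_ref), and C″_tone absorbs the myogenic, shear and
metabolic reference inputs, making the reference an exact fixed point.
Vessels whose dilated diameter does not exceed the control diameter get
S_tone = −1000 (effectively passive).  Where the generated control
diameter admits no activation in (0,1), or only a locally *unstable*
equilibrium of the (D, A) wall dynamics, the control diameter is moved
to the nearest feasible, stable value and the reference re-solved; the
calibration iterates oxygen solves until the tone constants absorb the
same signal field the dynamics will see at its first step.

## Synthetic networks

The generator emulates the statistics of the hamster-cremaster
preparation the model conditions assume: a binary arteriolar tree of 32
segments with 6 terminal leaves (chain links carry capillary side
branches so that every arteriole is the parent of a diverging
bifurcation), 93 capillary segments organized as chains of 2–4 from 33
origins, sibling-chain cross-links (anastomoses within a microvascular
unit), and two venule collecting chains of 6 segments.  Terminal chains
end on venule junctions; side chains are wired as tributaries into
low-pressure interior nodes chosen from a solved passive-dilated
pressure field, with a bounded repair loop guaranteeing that the
branching-pattern classification reproduces the generated labels.
Collecting capillaries widen by a Murray-like n^(1/3) rule (capped at
7.9 μm near cross-link nodes, 11 μm otherwise).  Arteriole dilated
diameters taper from 20 μm with log-normal jitter and are floored at
8 μm; control diameters are dilated × tone fraction (0.55–1.0); about
20% of capillaries and 10% of distal arterioles are assigned small
control diameters (arterioles: 2.9–3.8 μm) so they flow only in the
dilated state.  Vessels sit in a 1000×800×50 μm slab with the vascular
sheet confined to the middle 40% of its thickness; centerlines are bent
polylines whose arc length equals the drawn segment length.  The large
feeding arteriole's control tone is 0.6·D0: the 0.70–0.80 band is a
locally unstable operating range of the wall model at feed-vessel
pressures.  Generation is deterministic per seed.

What the generator does not emulate: the real network's exact geometry
and measured fluxes, venule geometry beyond the constructed chains, and
any remodeling.  Passing tests on these networks therefore demonstrate
the mechanisms (threshold recruitment, hematocrit redistribution,
metabolic dilation), not agreement with any particular preparation's
numbers.

## Dynamics and the demand sweep

dD/dt = (1/τ_d)(D_c/T_c)(T − T_total) and dA/dt = (1/τ_a)(A_total − A),
explicit Euler, dt = 0.25 s (dt = 0.5 s is unstable), run to 200 s with
averaging over 100–200 s in the full protocol.  Oxygen and signals
update every 4 steps by default; the flow solve is skipped while
diameters are static.  Endpoints are steady if all diameters change by
less than 10⁻⁴ relative over the last quarter of the run, otherwise
oscillatory (vasomotion); oscillatory endpoints are averaged like
steady ones.  Runs start from the calibrated reference state.

The ensemble experiments (ten seeds, three variants) use a scaled-down
protocol chosen for tractability on one CPU: t_end = 30 s with
averaging over the second half (about 1.5 activation time constants:
the ensemble measures the short-horizon regulated response; at high
demand the long-horizon endpoint develops the large-amplitude
vasomotion noted under limitations), oxygen updates every 12 steps with a
10-iteration budget per update (the tissue field then relaxes alongside
the slowly moving diameters; the first update after a demand change
converges fully), per-step flow tolerance 5×10⁻⁵, and the coarse oxygen
mesh (50 μm subsegments, 60 μm sinks).  The no-regulation variant's
endpoint is demand-independent, so it is run once and its oxygen field
re-evaluated statically at higher demands.  Variant comparisons are
within-network: one generated, feed-tuned, capillary-adjusted geometry
per seed, with per-variant tone calibration.

## Known limitations

- At the highest demand (M0 = 8) the regulated system operates close to
  its oxygen-carrying capacity; the metabolic loop gain is then large
  (the deficit slope steepens as tissue PO2 approaches P0) and the
  endpoint is a large-amplitude vasomotion-like oscillation whose
  window average can sit below the reference flowing count.  One or two
  regulating vessels per network sit near the myogenic stability
  boundary and wobble by 1–2% of diameter at the reference.
- The free-space Green's kernel leaks oxygen in small, strongly
  oversupplied configurations; such solutions are returned flagged
  unconverged with the leak visible in `balance_error()`.
- Vessels are oxygen sources only; venous re-uptake and intravascular
  resistance to radial flux are neglected.
- The tissue mesh is a rectangular slab; no-flux outer boundaries are
  represented only through the far-field closure, not exactly.
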