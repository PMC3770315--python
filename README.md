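# microflowreg

Metabolic blood flow regulation and capillary recruitment in
heterogeneous microvessel networks.

In striated muscle, the number of capillaries carrying moving red blood
cells rises with metabolic demand.  `microflowreg` implements an
integrated simulator that shows how this *capillary recruitment* can
emerge without precapillary sphincters, purely from (a) active control
of arteriolar diameters and (b) the unequal partition of hematocrit at
diverging microvascular bifurcations.  The package is aimed at
microcirculation researchers who want a tested, self-contained
network-level model of flow regulation and oxygen transport.

## The model

A microvessel network (arterioles, capillaries, venules, plus feed and
drain vessels `A, LA, LV1, LV2, V1, V2`) carries two-phase blood flow:
Poiseuille's law per segment with the in vivo apparent viscosity
μ(D, H_D) (Fåhræus–Lindqvist effect with an endothelial surface layer),
and the empirical logit law for red-cell partition at diverging
bifurcations, so discharge hematocrit H_D is nonuniform.  A vessel is
*flowing* when its RBC flux exceeds F_threshold = 12.5 cells/s.

Each arteriole's wall follows vascular smooth muscle length–tension
mechanics.  Total wall tension is

    T_total = C_pass exp[C'_pass (D/D0 − 1)]
            + A · C_act exp[−((D/D0 − C'_act)/C''_act)²]

with activation A ∈ [0, 1] relaxing toward a sigmoid of the tone
stimulus

    S_tone = C_myo T − C_shear τ_wall − C_meta S_meta + C''_tone ,

where T = P·D/2, τ_wall is wall shear stress, and S_meta is a
wall-derived metabolic signal proportional to the local oxygen deficit
M0 − M(P_wall), conducted upstream with exponential decay, summed at
branch points and split in proportion to parent diameters.  Diameters
and activations are integrated with explicit Euler (τ_d = 1 s,
τ_a = 20 s, dt = 0.25 s) over quasi-steady hemodynamics.

Tissue oxygen obeys D α ∇²p = M0 p/(p + P0) and is solved by a
Green's-function method: perfused vessels are discrete oxygen sources
matched to the blood PO2 at the wall, the tissue is a regular mesh of
Michaelis–Menten sinks, and the free-space superposition is closed by a
far-field level with a total source = total sink balance.  Convective
transport uses Hill-equation hemoglobin binding (n = 2.55,
P50 = 26 mmHg).

The unpublished experimental network the model conditions refer to is
emulated by a seeded generator: 32 arterioles (6 terminal), 93
capillaries (~15 per terminal arteriole), 12 venules, with a
configurable fraction of vessels intended to flow only when the
arterioles dilate.

## Worked example

```python
import numpy as np
from microflowreg import GeneratorConfig, generate_network
from microflowreg.calibration import calibrate
from microflowreg.dynamics import SimulationSettings, run_simulation
from microflowreg.oxygen import OxygenParameters, OxygenSolver

net = generate_network(GeneratorConfig(seed=1))
par = OxygenParameters()
solver = OxygenSolver(net, par, subsegment_um=50.0, sink_spacing_um=60.0,
                      padding_um=40.0, max_outer=600)
ref = calibrate(net, oxygen_solver=solver)     # 66 mmHg arterial side
for M0 in (1.0, 4.0):
    sim = SimulationSettings(t_end=50.0, averaging_window=(25.0, 50.0),
                             oxygen_update_stride=12,
                             oxygen_iterations_budget=10, M0=M0)
    ts = run_simulation(net, ref, sim, oxygen_params=par,
                        oxygen_solver=solver)
    print(f"M0={M0}: inflow {ts.mean_inflow:.1f} nl/min, "
          f"flowing {ts.mean_n_flowing:.1f}, "
          f"hypoxic fraction {ts.mean_hypoxic_fraction:.3f}")
```

prints (seed 1)

```
M0=1.0: inflow 11.8 nl/min, flowing 98.7, hypoxic fraction 0.000
M0=4.0: inflow 21.0 nl/min, flowing 102.5, hypoxic fraction 0.000
```

At the reference demand (M0 = 1 cm³O₂/100 cm³/min) about 99 of the 125
arterioles and capillaries are flowing and the tissue is fully
oxygenated.  Quadrupling demand nearly doubles inflow through metabolic
vasodilation and *recruits* several additional vessels — individual
capillaries cross the RBC-flux threshold as upstream arterioles dilate
and hematocrit redistributes — while hypoxia remains absent.

A command line mirrors the library:

```
microflowreg generate --seed 1 --out net.tsv
microflowreg steady --net net.tsv --phase-separation on --out state.tsv
microflowreg calibrate --net net.tsv --out net.cal.tsv
microflowreg sweep --seeds 1,2 --demands 1,4,8 --out-dir sweep_out
```

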