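"""Time integration of arteriolar diameter and activation.

Each regulating vessel carries two state variables: the diameter D,
driven by the imbalance between the intravascular wall tension T = P*D/2
and the tension the wall can sustain (passive plus activation-scaled
active), and the VSM activation A, relaxing toward the sigmoidal target
set by the combined myogenic/shear/metabolic stimulus:

    dD/dt = (1/tau_d) * (D_c/T_c) * (T - T_total(D, A))
    dA/dt = (1/tau_a) * (A_total(S_tone) - A)

integrated by an explicit Euler method with quasi-steady hemodynamics at
every step and oxygen/conducted-signal updates every few steps.  After
the transient the system either settles to a steady state or shows
stable oscillations (vasomotion); endpoint values are defined by
averaging over the second half of the run in either case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import ReferenceState
from .hemodynamics import FlowSolverSettings, classify_flowing, solve_flows
from .network import NetworkGraph
from .oxygen import OxygenParameters, OxygenSolver, tissue_statistics
from .signals import SignalSettings, compute_signals
from .wall import (activation_target, stimulus_tone, total_tension,
                   wall_tension_from_pressure)


class IntegrationError(RuntimeError):
    pass


@dataclass
class SimulationSettings:
    tau_d: float = 1.0                 # s, diameter time constant
    tau_a: float = 20.0                # s, activation time constant
    dt: float = 0.25                   # s
    t_end: float = 200.0               # s
    averaging_window: tuple[float, float] = (100.0, 200.0)
    oxygen_update_stride: int = 4      # steps between oxygen/signal updates
    oxygen_iterations_budget: int | None = None  # per-update outer iterations
    metabolic_regulation: bool = True
    phase_separation: bool = True
    M0: float = 1.0                    # cm^3 O2/100cm^3/min
    steady_rel_tol: float = 1e-4       # endpoint classification
    oxygen_tolerance: float = 1.5      # mmHg, during the transient
    flow_tolerance: float = 1e-5       # relative, per-step flow fixed point


@dataclass
class TimeSeries:
    time: np.ndarray
    diameters: np.ndarray              # (steps, n_regulating), um
    activations: np.ndarray            # (steps, n_regulating)
    inflow: np.ndarray                 # nl/min per step
    n_flowing: np.ndarray              # arterioles+capillaries per step
    median_po2: np.ndarray             # per oxygen update (NaN between)
    hypoxic_fraction: np.ndarray
    endpoint: str                      # "steady" | "oscillatory"
    mean_diameters: np.ndarray         # averaged over the window
    mean_activations: np.ndarray
    mean_inflow: float
    mean_n_flowing: float
    mean_n_flowing_capillaries: float
    mean_n_flowing_arterioles: float
    mean_median_po2: float
    mean_hypoxic_fraction: float
    reg_ids: list[str] = field(default_factory=list)


def step_euler(D, A, T, T_tot, A_tot, ref: ReferenceState,
               settings: SimulationSettings):
    """One explicit Euler step of the wall dynamics (arrays per vessel)."""
    Dn = D + settings.dt / settings.tau_d * (ref.D_c / ref.T_c) * (T - T_tot)
    An = A + settings.dt / settings.tau_a * (A_tot - A)
    # floor just above the validity limit of the in vivo viscosity law
    Dn = np.maximum(Dn, 2.8)
    An = np.clip(An, 0.0, 1.0)
    if not (np.all(np.isfinite(Dn)) and np.all(np.isfinite(An))):
        bad = np.where(~np.isfinite(Dn) | ~np.isfinite(An))[0]
        raise IntegrationError(
            f"non-finite wall state in segment(s) {bad.tolist()}")
    return Dn, An


def run_simulation(net: NetworkGraph, ref: ReferenceState,
                   settings: SimulationSettings,
                   oxygen_params: OxygenParameters | None = None,
                   signal_settings: SignalSettings | None = None,
                   oxygen_solver: OxygenSolver | None = None) -> TimeSeries:
    """Integrate the coupled wall/flow/oxygen system to its endpoint."""
    oxygen_params = oxygen_params or OxygenParameters()
    signal_settings = signal_settings or SignalSettings()
    flow_settings = FlowSolverSettings(
        phase_separation_enabled=settings.phase_separation,
        tolerance=settings.flow_tolerance, max_iterations=800)

    reg_idx = np.array([i for i, s in enumerate(net.segments)
                        if s.regulating])
    sidx = net.segment_index()
    assert [net.segments[i].id for i in reg_idx] == ref.seg_ids, \
        "reference state does not match the network's regulating segments"

    n_steps = int(round(settings.t_end / settings.dt))
    nreg = len(reg_idx)
    D_all = np.array([s.diameter_current for s in net.segments])
    D = ref.D_c.copy()
    A = ref.A_ref.copy()
    D_all[reg_idx] = D

    solver = oxygen_solver
    if solver is None:
        solver = OxygenSolver(net, oxygen_params, subsegment_um=50.0,
                              sink_spacing_um=60.0, padding_um=40.0,
                              tolerance_mmhg=settings.oxygen_tolerance,
                              max_outer=600)
    # per-step solves run at the (looser) transient tolerance
    saved_tol = solver.tolerance
    solver.tolerance = settings.oxygen_tolerance

    hemo = solve_flows(net, D_all, flow_settings)
    D_solved = D_all[reg_idx].copy()
    S_meta = np.zeros(len(net.segments))
    med_po2 = np.nan
    hyp = np.nan

    t_arr = np.zeros(n_steps)
    D_hist = np.zeros((n_steps, nreg))
    A_hist = np.zeros((n_steps, nreg))
    Q_hist = np.zeros(n_steps)
    nflow_hist = np.zeros(n_steps)
    ncap_hist = np.zeros(n_steps)
    nart_hist = np.zeros(n_steps)
    med_hist = np.full(n_steps, np.nan)
    hyp_hist = np.full(n_steps, np.nan)

    for step in range(n_steps):
        t = step * settings.dt
        if step % settings.oxygen_update_stride == 0:
            for i in range(len(net.segments)):
                net.segments[i].diameter_current = D_all[i]
            # the first update after a demand change converges fully;
            # later updates may run on a fixed budget, letting the field
            # relax alongside the slowly moving diameters
            budget = None if step == 0 else \
                settings.oxygen_iterations_budget
            try:
                oxy = solver.solve(hemo, M0=settings.M0,
                                   iterations_budget=budget)
            except Exception:
                if budget is not None:
                    raise
                # let the field relax over subsequent updates instead
                oxy = solver.solve(hemo, M0=settings.M0,
                                   iterations_budget=30)
            if settings.metabolic_regulation:
                sig = compute_signals(net, hemo, oxy, signal_settings,
                                      M0=settings.M0)
                S_meta = sig.S_meta
            stats = tissue_statistics(oxy)
            med_po2 = stats["median_po2"]
            hyp = stats["hypoxic_fraction"]

        P_seg = hemo.pressure[reg_idx]
        tau_seg = hemo.wall_shear[reg_idx]
        Sm = S_meta[reg_idx] if settings.metabolic_regulation else \
            np.zeros(nreg)
        T = wall_tension_from_pressure(P_seg, D)
        T_tot = np.array([total_tension(D[k], A[k], ref.wall[k])
                          for k in range(nreg)])
        S_tone = np.array([stimulus_tone(T[k], tau_seg[k], Sm[k],
                                         ref.wall[k]) for k in range(nreg)])
        A_tot = activation_target(S_tone)

        t_arr[step] = t
        D_hist[step] = D
        A_hist[step] = A
        Q_hist[step] = hemo.total_inflow(net)
        fl = classify_flowing(net, hemo, flow_settings.flux_threshold)
        ncap_hist[step] = fl["n_flowing_capillaries"]
        nart_hist[step] = fl["n_flowing_arterioles"]
        nflow_hist[step] = ncap_hist[step] + nart_hist[step]
        med_hist[step] = med_po2
        hyp_hist[step] = hyp

        D, A = step_euler(D, A, T, T_tot, A_tot, ref, settings)
        D_all[reg_idx] = D
        # skip the flow re-solve while diameters are effectively static
        if np.max(np.abs(D_all[reg_idx] - D_solved)
                  / np.maximum(D_solved, 1e-9)) > 1e-7:
            hemo = solve_flows(net, D_all, flow_settings, warm_start=hemo)
            D_solved = D_all[reg_idx].copy()

    for i in range(len(net.segments)):
        net.segments[i].diameter_current = D_all[i]
    solver.tolerance = saved_tol

    # endpoint classification over the last quarter of the run
    tail = slice(int(0.75 * n_steps), n_steps)
    span = D_hist[tail].max(axis=0) - D_hist[tail].min(axis=0)
    rel = span / np.maximum(D_hist[tail].mean(axis=0), 1e-12)
    endpoint = "steady" if rel.max() < settings.steady_rel_tol \
        else "oscillatory"

    w0, w1 = settings.averaging_window
    win = (t_arr >= w0) & (t_arr <= w1)
    if not win.any():
        win = np.ones(n_steps, dtype=bool)
    owin = win & ~np.isnan(med_hist)
    return TimeSeries(
        time=t_arr, diameters=D_hist, activations=A_hist, inflow=Q_hist,
        n_flowing=nflow_hist, median_po2=med_hist, hypoxic_fraction=hyp_hist,
        endpoint=endpoint,
        mean_diameters=D_hist[win].mean(axis=0),
        mean_activations=A_hist[win].mean(axis=0),
        mean_inflow=float(Q_hist[win].mean()),
        mean_n_flowing=float(nflow_hist[win].mean()),
        mean_n_flowing_capillaries=float(ncap_hist[win].mean()),
        mean_n_flowing_arterioles=float(nart_hist[win].mean()),
        mean_median_po2=float(med_hist[owin].mean()) if owin.any()
        else float("nan"),
        mean_hypoxic_fraction=float(hyp_hist[owin].mean()) if owin.any()
        else float("nan"),
        reg_ids=list(ref.seg_ids))
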