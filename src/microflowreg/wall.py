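"""Vascular smooth muscle (VSM) wall mechanics.

Steady wall tension is the sum of a passive exponential length-tension
component and an active component: the maximal active tension (a Gaussian
in normalized diameter, peaking near the optimal muscle length) scaled by
the activation A in [0, 1].  The target activation is a sigmoid of the
total vasoactive stimulus S_tone, which combines an excitatory myogenic
(wall tension) term with inhibitory shear and conducted-metabolic terms:

    S_tone = C_myo * T - C_shear * tau_wall - C_meta * S_meta + C''_tone

All diameter-dependent parameters derive from D0, the passive diameter at
100 mmHg, in um; tensions are in dyn/cm, wall shear in dyn/cm^2, and the
conducted signal S_meta in uM*cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .hemodynamics import MMHG_TO_DYN_CM2, UM_TO_CM


@dataclass
class WallParameters:
    """Length-tension and stimulus-sensitivity constants for one vessel."""
    D0: float                       # um, passive diameter at 100 mmHg
    C_meta: float = 5000.0          # 1/(uM*cm)
    C_shear: float = 0.0258         # cm^2/dyn
    C_tone_pp: float = 0.0          # C''_tone, calibrated per vessel

    # derived, filled in __post_init__
    C_pass: float = field(init=False)
    C_pass_p: float = field(init=False)
    C_act: float = field(init=False)
    C_act_p: float = field(init=False)
    C_act_pp: float = field(init=False)
    C_myo: float = field(init=False)

    def __post_init__(self):
        if self.D0 <= 0:
            raise ValueError("D0 must be positive")
        D0 = self.D0
        self.C_pass = 6.666 * D0
        self.C_pass_p = -0.027 * D0 + 12.52
        self.C_act = 1.30 * D0 ** 1.48
        self.C_act_p = -0.00059 * D0 + 0.773
        self.C_act_pp = -0.00080 * D0 + 0.415
        self.C_myo = 1.369 / D0


@dataclass
class WallState:
    D: float      # um
    A: float      # activation, 0..1
    T: float      # dyn/cm


def passive_tension(D, p: WallParameters):
    """T_pass = C_pass * exp[C'_pass * (D/D0 - 1)], dyn/cm."""
    D = np.asarray(D, dtype=float)
    out = p.C_pass * np.exp(p.C_pass_p * (D / p.D0 - 1.0))
    return out if out.ndim else float(out)


def active_tension_max(D, p: WallParameters):
    """T_act^max = C_act * exp[-((D/D0 - C'_act)/C''_act)^2], dyn/cm."""
    D = np.asarray(D, dtype=float)
    out = p.C_act * np.exp(-(((D / p.D0) - p.C_act_p) / p.C_act_pp) ** 2)
    return out if out.ndim else float(out)


def total_tension(D, A, p: WallParameters):
    """Passive plus activation-scaled active tension, dyn/cm."""
    A = np.asarray(A, dtype=float)
    if np.any((A < 0) | (A > 1)):
        raise ValueError("activation A outside [0, 1]")
    out = passive_tension(D, p) + A * active_tension_max(D, p)
    return out if np.asarray(out).ndim else float(out)


def activation_target(S_tone):
    """Sigmoidal saturating target activation A_total = 1/(1+exp(-S_tone))."""
    S = np.clip(np.asarray(S_tone, dtype=float), -500.0, 500.0)
    out = 1.0 / (1.0 + np.exp(-S))
    return out if out.ndim else float(out)


def stimulus_tone(T, tau_wall, S_meta, p: WallParameters):
    """Combined myogenic (+), shear (-), metabolic (-) stimulus."""
    out = (p.C_myo * np.asarray(T, float)
           - p.C_shear * np.asarray(tau_wall, float)
           - p.C_meta * np.asarray(S_meta, float)
           + p.C_tone_pp)
    return out if np.asarray(out).ndim else float(out)


def wall_tension_from_pressure(P_mmHg, D_um):
    """Laplace wall tension T = P*D/2 in dyn/cm (P in mmHg, D in um)."""
    return P_mmHg * MMHG_TO_DYN_CM2 * (D_um * UM_TO_CM) / 2.0


def equilibrium_diameter(p: WallParameters, P_mmHg: float,
                         tau_wall: float = 0.0, S_meta: float = 0.0,
                         bracket: tuple[float, float] = (0.25, 1.4)
                         ) -> float:
    """Static equilibrium diameter at fixed pressure/shear/metabolic input.

    Solves T(P, D) = T_total(D, A_total(S_tone(...))) by bisection on
    D in (bracket[0]*D0, bracket[1]*D0).  Raises if no sign change.
    """
    def resid(D):
        T = wall_tension_from_pressure(P_mmHg, D)
        A = activation_target(stimulus_tone(T, tau_wall, S_meta, p))
        return T - total_tension(D, A, p)

    lo, hi = bracket[0] * p.D0, bracket[1] * p.D0
    flo, fhi = resid(lo), resid(hi)
    if flo * fhi > 0:
        # expand downward: very constricted equilibria live at small D
        for lo2 in (0.1 * p.D0, 0.05 * p.D0):
            if resid(lo2) * fhi <= 0:
                lo = lo2
                break
        else:
            raise ValueError("no equilibrium diameter in bracket")
    return float(brentq(resid, lo, hi, xtol=1e-10))
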