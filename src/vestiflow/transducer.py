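"""The duct as a second-order transducer: frequency response and the
subcupular-space sensitivity optimum.

In standard form the duct obeys y'' + 2 zeta w_n y' + w_n^2 y = w_n^2 x with
transfer function H(s) = w_n^2 / (s^2 + 2 zeta w_n s + w_n^2).  The same
mass-spring system yields three classical frequency-response views depending
on which physical quantity is taken as the input: accelerometer (|H|),
velocity meter (u |H|) and seismometer (u^2 |H|), with u = w/w_n.  For the
heavily overdamped duct (zeta ~ 30) the velocity view shows a wide plateau
between the corner frequencies f1 = 1/T1 and f2 = 1/T2.

The subcupular space is the narrow channel between sensory epithelium and
cupula through which the duct forces the endolymph; narrowing it speeds the
flow until friction chokes it, so an optimal area ratio A_s/A_d exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coupled_init import subcupular_initial_velocity
from .exceptions import ModelDomainError

__all__ = ["TransferSpec", "transfer_gain", "corner_frequencies",
           "subcupular_design_curve", "subcupular_optimum"]

#: Frequency-response views of the one mass-spring system.
VIEWS = ("accel", "velocity", "displacement")


@dataclass(frozen=True)
class TransferSpec:
    """Damping ratio and natural frequency of the standard second-order form."""

    zeta: float
    omega_n: float

    def __post_init__(self):
        if not (self.zeta > 0 and self.omega_n > 0):
            raise ValueError("zeta and omega_n must be positive")

    @classmethod
    def from_time_constants(cls, T1: float, T2: float) -> "TransferSpec":
        """omega_n = 1/sqrt(T1 T2) and zeta = sqrt(T1/T2)/2."""
        if not (T1 > 0 and T2 > 0):
            raise ValueError("time constants must be positive")
        return cls(zeta=0.5 * math.sqrt(T1 / T2),
                   omega_n=1.0 / math.sqrt(T1 * T2))


def transfer_gain(spec: TransferSpec, omega, view: str = "velocity"):
    """Gain of the second-order system at angular frequency omega [rad/s].

    ``view`` selects the input quantity: ``accel`` returns |H(ju)|,
    ``velocity`` u |H|, ``displacement`` (seismometer) u^2 |H|, where
    u = omega/omega_n.  All three derive from the single TransferSpec — they
    are views of the very same sensor, not different sensors.
    """
    if view not in VIEWS:
        raise ValueError(f"view must be one of {VIEWS}")
    u = np.asarray(omega, dtype=float) / spec.omega_n
    if np.any(u < 0):
        raise ValueError("omega must be non-negative")
    h = 1.0 / np.sqrt((1.0 - u**2) ** 2 + (2.0 * spec.zeta * u) ** 2)
    power = {"accel": 0, "velocity": 1, "displacement": 2}[view]
    gain = u**power * h
    return float(gain) if np.isscalar(omega) else gain


def corner_frequencies(T1: float, T2: float) -> tuple:
    """Corner frequencies (f1, f2) [Hz] as inverse time constants, plus T1/T2.

    The convention f = 1/T (not 1/(2 pi T)) is used, matching the quoted
    0.05 Hz lower corner of a human-like duct with T1 = 20 s.
    """
    if not (T1 >= T2 > 0):
        raise ValueError("require T1 >= T2 > 0")
    return 1.0 / T1, 1.0 / T2, T1 / T2


def subcupular_design_curve(length_ratio: float, area_grid) -> pd.DataFrame:
    """Normalized subcupular design quantities over a grid of area ratios.

    ``length_ratio`` is l_s/l_d (subcupular space to duct), ``area_grid`` the
    A_s/A_d values.  Columns:

    - ``v0_norm``: initial subcupular velocity / stimulus speed,
      (1 + l_d/l_s) / (1 + (l_d/l_s)(A_s/A_d));
    - ``T2_norm``: fast constant of the composite circuit normalized by the
      uniform-duct value A_d rho/(8 pi eta).  On volumetric flow the
      composite inertia and friction are M_q = rho sum(l_i/A_i) and
      F_q = 8 pi eta sum(l_i/A_i^2), so
      T2_norm = (1 + L/alpha) / (1 + L/alpha^2) with L = l_s/l_d and
      alpha = A_s/A_d (equal to 1 for a uniform duct);
    - ``xmax_norm`` = v0_norm * T2_norm, the normalized maximal excursion.
    """
    if length_ratio <= 0:
        raise ModelDomainError("length ratio l_s/l_d must be positive")
    alpha = np.asarray(area_grid, dtype=float)
    if alpha.size == 0:
        raise ValueError("area-ratio grid is empty")
    if np.any(alpha <= 0):
        raise ModelDomainError("area ratios must be positive")
    Lr = length_ratio
    v0 = np.array([
        subcupular_initial_velocity(1.0, Lr, 1.0, a, normalized=True)
        for a in alpha
    ])
    t2 = (1.0 + Lr / alpha) / (1.0 + Lr / alpha**2)
    return pd.DataFrame({
        "area_ratio": alpha,
        "v0_norm": v0,
        "T2_norm": t2,
        "xmax_norm": v0 * t2,
    })


def subcupular_optimum(length_ratio: float, area_grid) -> tuple:
    """Design curve plus the area ratio maximising the normalized excursion.

    Returns ``(curve, optimum)`` where ``optimum`` is the A_s/A_d value of
    the grid with the largest ``xmax_norm``.
    """
    curve = subcupular_design_curve(length_ratio, area_grid)
    i = int(curve["xmax_norm"].idxmax())
    return curve, float(curve["area_ratio"].loc[i])
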