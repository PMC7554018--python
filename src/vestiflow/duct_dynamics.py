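"""Equations of motion of endolymph flow: single ducts and coupled networks.

A single duct circuit obeys the overdamped force equation

    M x'' + F x' + S x = 0,    M = rho A l,   F = 8 pi eta l,

with S the lumped cupular stiffness.  Its two time constants are the slow
restoring constant T1 = F/S (the "mechanical memory") and the fast viscous
constant T2 = M/F = r^2/(8 nu) (the "measuring phase"); the damping ratio is
zeta = sqrt(T1/T2)/2, of order 30 for human-like dimensions — heavily
overdamped, so both characteristic roots are real.

For a coupled network the per-section equations are joined by confluence-node
pressures and volume continuity.  Rather than transcribing the historical
18x18 symbolic matrix, the dynamics are reduced to loop (cycle-space)
coordinates of the volumetric displacement, giving a small generalized
second-order system whose eigen-decomposition yields the 2 * n_loops time
constants (six for the canonical three-loop labyrinth) and the per-duct
amplitude tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .coupled_init import InitialFlowState
from .exceptions import RegimeError, TopologyError
from .geometry import DuctSection, EndolymphProps, LabyrinthNetwork

__all__ = ["MotionCoefficients", "TimeConstants", "ModeDecomposition",
           "motion_coefficients", "time_constants", "step_response",
           "max_excursion", "coupled_modes", "elasticity_for_T1",
           "loop_system_matrices"]


@dataclass(frozen=True)
class MotionCoefficients:
    """Lumped coefficients of one duct circuit.

    M : endolymph mass [kg]; F : Poiseuille friction coefficient [kg/s];
    S : cupular elasticity [N/m], zero for sections without a cupula.
    """

    M: float
    F: float
    S: float = 0.0

    def __post_init__(self):
        if not (self.M > 0 and self.F > 0 and self.S >= 0):
            raise ValueError("require M > 0, F > 0, S >= 0")


@dataclass(frozen=True)
class TimeConstants:
    """Slow (T1 = F/S) and fast (T2 = M/F) time constants [s].

    T1 and the damping ratio zeta = sqrt(T1/T2)/2 are ``None`` for springless
    sections (S = 0), which relax but never restore.
    """

    T2: float
    T1: float | None = None
    zeta: float | None = None

    @property
    def separation(self) -> float | None:
        return None if self.T1 is None else self.T1 / self.T2


def motion_coefficients(section: DuctSection, props: EndolymphProps,
                        S: float = 0.0) -> MotionCoefficients:
    """M = rho A l and F = 8 pi eta l for one duct section; S passed through."""
    M = props.rho * section.area * section.length
    F = 8.0 * math.pi * props.eta * section.length
    return MotionCoefficients(M, F, float(S))


def time_constants(coeffs: MotionCoefficients, r: float | None = None,
                   nu: float | None = None) -> TimeConstants:
    """Time constants from the motion coefficients.

    When the duct radius and kinematic viscosity are supplied, the identity
    T2 = M/F = r^2/(8 nu) is cross-checked; a disagreement means the
    coefficients do not describe a uniform Poiseuille duct.
    """
    T2 = coeffs.M / coeffs.F
    if r is not None and nu is not None:
        T2_geom = r * r / (8.0 * nu)
        if not math.isclose(T2, T2_geom, rel_tol=1e-9):
            raise ValueError(
                f"T2 = M/F = {T2:.6g} s disagrees with r^2/8nu = {T2_geom:.6g} s"
            )
    if coeffs.S == 0.0:
        return TimeConstants(T2=T2)
    T1 = coeffs.F / coeffs.S
    zeta = 0.5 * math.sqrt(T1 / T2)
    return TimeConstants(T2=T2, T1=T1, zeta=zeta)


def _characteristic_roots(coeffs: MotionCoefficients) -> tuple:
    disc = coeffs.F**2 - 4.0 * coeffs.M * coeffs.S
    if disc <= 0:
        raise RegimeError(
            "underdamped or critically damped parameters; the duct model "
            "assumes a heavily overdamped regime (T1 > 4 T2)"
        )
    root = math.sqrt(disc)
    s1 = (-coeffs.F + root) / (2.0 * coeffs.M)  # slow root (less negative)
    s2 = (-coeffs.F - root) / (2.0 * coeffs.M)  # fast root
    return s1, s2


def step_response(coeffs: MotionCoefficients, x0: float, v0: float,
                  t_grid) -> np.ndarray:
    """Free response x(t) = c1 e^{s1 t} + c2 e^{s2 t} from (x0, v0).

    Only the overdamped case is supported; springless sections (S = 0) decay
    with the single constant T2 towards a finite displacement.
    """
    t = np.asarray(t_grid, dtype=float)
    if coeffs.S == 0.0:
        T2 = coeffs.M / coeffs.F
        return x0 + v0 * T2 * (1.0 - np.exp(-t / T2))
    s1, s2 = _characteristic_roots(coeffs)
    c1 = (v0 - s2 * x0) / (s1 - s2)
    c2 = (s1 * x0 - v0) / (s1 - s2)
    return c1 * np.exp(s1 * t) + c2 * np.exp(s2 * t)


def max_excursion(coeffs: MotionCoefficients, v0: float,
                  approximate: bool = False) -> float:
    """Peak displacement for release from rest position with velocity v0.

    The approximate form is the classical x_max ~ v0 T2; the exact peak of
    the two-exponential solution is smaller by a factor that vanishes as
    T2/T1 -> 0.
    """
    T2 = coeffs.M / coeffs.F
    if approximate or coeffs.S == 0.0:
        return v0 * T2
    s1, s2 = _characteristic_roots(coeffs)
    t_peak = math.log(s2 / s1) / (s1 - s2)
    amp = v0 / (s1 - s2)
    return amp * (math.exp(s1 * t_peak) - math.exp(s2 * t_peak))


def elasticity_for_T1(section: DuctSection, props: EndolymphProps,
                      T1: float) -> float:
    """Cupular stiffness S = F/T1 that gives a prescribed slow constant."""
    if T1 <= 0:
        raise ValueError("T1 must be positive")
    return 8.0 * math.pi * props.eta * section.length / T1


# ---------------------------------------------------------------------------
# Coupled network dynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModeDecomposition:
    """Exponential-mode decomposition of the coupled free response.

    ``time_constants`` holds the 2 * n_loops positive constants T_i [s]
    (sorted descending); ``amplitudes`` is a sections x modes table of
    coefficients [m] such that  x_s(t) = sum_i amplitudes[s, i] e^{-t/T_i}.
    """

    time_constants: np.ndarray
    amplitudes: pd.DataFrame

    def evaluate(self, t_grid) -> pd.DataFrame:
        """Reconstructed per-section displacement time courses [m]."""
        t = np.asarray(t_grid, dtype=float)
        decay = np.exp(-t[:, None] / self.time_constants[None, :])
        data = decay @ self.amplitudes.to_numpy().T
        return pd.DataFrame(data, index=t, columns=self.amplitudes.index)


def loop_system_matrices(net: LabyrinthNetwork, S: float):
    """Cycle-space inertia, friction and stiffness matrices (L, R, C, B).

    Per section the volumetric-displacement coefficients are
    L_s = rho l_s / A_s, R_s = 8 pi eta l_s / A_s^2 and C_s = S / A_s^2 for
    elastic sections.  B is an orthonormal cycle basis (null space of the
    reduced incidence matrix); loop coordinates z satisfy
    (B'LB) z'' + (B'RB) z' + (B'CB) z = 0 with V = B z.
    """
    areas = np.array([s.area for s in net.sections])
    lens = np.array([s.length for s in net.sections])
    L = net.props.rho * lens / areas
    R = 8.0 * math.pi * net.props.eta * lens / areas**2
    C = np.array([S / s.area**2 if s.elastic else 0.0 for s in net.sections])
    D = net.incidence_matrix(drop_node=sorted(net.nodes)[0])
    B = scipy.linalg.null_space(D)
    if B.shape[1] != net.n_loops():
        raise TopologyError("cycle-space dimension does not match the topology")
    Lt = (B.T * L) @ B
    Rt = (B.T * R) @ B
    Ct = (B.T * C) @ B
    return Lt, Rt, Ct, B


def coupled_modes(net: LabyrinthNetwork, S: float,
                  init: InitialFlowState) -> ModeDecomposition:
    """Eigen-decomposition of the coupled free decay after a rotation stop.

    Assumes one common cupular stiffness S on all elastic sections.  The
    initial state is the post-stop flow distribution (displacements zero,
    velocities from the momentum balance).

    Raises
    ------
    RegimeError
        If any eigenvalue is complex or non-decaying (outside the heavily
        overdamped regime) or if some loop carries no cupular spring.
    """
    if S <= 0:
        raise ValueError("coupled modes require a positive elasticity S")
    Lt, Rt, Ct, B = loop_system_matrices(net, S)
    k = B.shape[1]
    if np.linalg.matrix_rank(Ct, tol=1e-30) < k:
        raise RegimeError("some flow loop contains no elastic section; its "
                          "slow time constant would be infinite")
    Astate = np.block([
        [np.zeros((k, k)), np.eye(k)],
        [-np.linalg.solve(Lt, Ct), -np.linalg.solve(Lt, Rt)],
    ])
    w, V = scipy.linalg.eig(Astate)
    if np.max(np.abs(w.imag)) > 1e-9 * np.max(np.abs(w.real)):
        raise RegimeError("complex eigenvalues: system is not overdamped")
    w = w.real
    if np.any(w >= 0):
        raise RegimeError("non-decaying eigenvalue found")
    V = V.real

    # initial loop coordinates: z(0) = 0, z'(0) from the velocity field
    areas = np.array([s.area for s in net.sections])
    v0 = init.velocity_vector(net.section_names) * areas
    zdot0, res, *_ = np.linalg.lstsq(B, v0, rcond=None)
    if np.linalg.norm(v0 - B @ zdot0) > 1e-9 * max(np.linalg.norm(v0), 1e-300):
        raise TopologyError("initial velocities violate volume continuity")
    state0 = np.concatenate([np.zeros(k), zdot0])
    coeff = np.linalg.solve(V, state0)

    T = -1.0 / w
    order = np.argsort(-T)
    T = T[order]
    # per-section displacement amplitudes: x_s = (B z)_s / A_s
    amp = (B @ (V[:k, :] * coeff[None, :]))[:, order] / areas[:, None]
    table = pd.DataFrame(amp, index=net.section_names,
                         columns=[f"T{i+1}" for i in range(2 * k)])
    return ModeDecomposition(time_constants=T, amplitudes=table)
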