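"""Closed-form theory of the two-duct labyrinth.

Two congruent ducts a and p (equal lengths l_d and radii r_d) share a common
part c; the shape ratios are lambda = l_c/l_d and gamma = r_c/r_d.  For this
system the coupled momentum balance collapses to closed forms: fast time
constants T21 = T22 f0(gamma, lambda) and T22 = r^2/(8 nu), initial
velocities, maximal excursions, and the posterior/anterior coupling ratio

    k_alpha = [I_aex l + I_pex (g^2 + l) - I_cex] / [I_aex (g^2 + l) + I_pex l + I_cex]

(g = gamma, l = lambda).  The sign of the I_cex terms follows the unique
assignment consistent with the excursion formulas: +I_cex in duct a's
velocity and -I_cex in duct p's (the velocity-form and impulse-form maximal
excursions then agree identically, which is asserted at run time).

Special rotations give k_alpha = 1 (serial), -1 (parallel) and
lambda/(gamma^2 + lambda) (excitation of duct a only); the inter-duct angle
at which duct p stays still is alpha = pi - arccos(-f3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import ModelDomainError, VestiflowError
from .geometry import DuctSection, EndolymphProps, LabyrinthNetwork
from .impulses import RotationStop, external_impulse

__all__ = ["TwoDuctRatios", "TwoDuctImpulses", "f0", "init_velocities_2duct",
           "k_alpha", "k_alpha_max", "max_excursions_2duct",
           "null_flow_angle", "optimal_orientation", "lambda_scan",
           "dip_family", "smooth_family"]


@dataclass(frozen=True)
class TwoDuctRatios:
    """Shape ratios lambda = l_c/l_d and gamma = r_c/r_d of a two-duct system."""

    lam: float
    gam: float = 1.0

    def __post_init__(self):
        if not (self.lam > 0 and self.gam > 0):
            raise ValueError("lambda and gamma must be positive")

    @classmethod
    def from_network(cls, net: LabyrinthNetwork) -> "TwoDuctRatios":
        """Extract (lambda, gamma) from a validated two-duct network.

        The two elastic sections are the ducts (they must be congruent); the
        single non-elastic section is the common part.
        """
        ducts = [s for s in net.sections if s.elastic]
        common = [s for s in net.sections if not s.elastic]
        if len(ducts) != 2 or len(common) != 1:
            raise ModelDomainError(
                "two-duct theory needs exactly two elastic ducts and one "
                "common part")
        d1, d2 = ducts
        if not (math.isclose(d1.length, d2.length, rel_tol=1e-9)
                and math.isclose(d1.radius, d2.radius, rel_tol=1e-9)):
            raise ModelDomainError("the two ducts must have equal lengths and radii")
        c = common[0]
        return cls(lam=c.length / d1.length, gam=c.radius / d1.radius)


@dataclass(frozen=True)
class TwoDuctImpulses:
    """Signed external impulses [kg m/s] and the (common) duct mass M [kg]."""

    I_aex: float
    I_pex: float
    I_cex: float = 0.0
    M: float = 1.0

    def __post_init__(self):
        if self.M <= 0:
            raise ValueError("duct mass M must be positive")


def f0(gam: float, lam: float) -> float:
    """Fast-constant ratio f0 = gamma^2 (gamma^2 + 2 lambda) / (gamma^4 + 2 lambda).

    T21 = T22 * f0; the function is close to 1 over the anatomical range of
    (gamma, lambda), which is why the fast constants of real labyrinths are
    nearly equal.
    """
    if gam <= 0 or lam <= 0:
        raise ModelDomainError("gamma and lambda must be positive")
    g2 = gam * gam
    return g2 * (g2 + 2.0 * lam) / (g2 * g2 + 2.0 * lam)


def init_velocities_2duct(imp: TwoDuctImpulses,
                          ratios: TwoDuctRatios) -> tuple:
    """Initial velocities (x_a'(0), x_p'(0)) [m/s] of the two ducts."""
    g2 = ratios.gam**2
    lam = ratios.lam
    den = imp.M * (g2 + 2.0 * lam)
    xa = (imp.I_aex * (g2 + lam) + imp.I_pex * lam + imp.I_cex) / den
    xp = (imp.I_aex * lam + imp.I_pex * (g2 + lam) - imp.I_cex) / den
    return xa, xp


def k_alpha(imp: TwoDuctImpulses, ratios: TwoDuctRatios) -> float:
    """Coupling ratio x_p'(0) / x_a'(0) of initial velocities."""
    g2 = ratios.gam**2
    lam = ratios.lam
    num = imp.I_aex * lam + imp.I_pex * (g2 + lam) - imp.I_cex
    den = imp.I_aex * (g2 + lam) + imp.I_pex * lam + imp.I_cex
    if den == 0.0:
        raise ModelDomainError("k_alpha undefined: duct a has zero initial velocity")
    return num / den


def max_excursions_2duct(imp: TwoDuctImpulses, ratios: TwoDuctRatios,
                         T22: float) -> tuple:
    """Maximal excursions (x_a_max, x_p_max, k_alpha_max).

    Both closed forms are evaluated — the velocity form (via the two fast
    constants) and the impulse form — and must agree to near machine
    precision; their agreement is the decisive internal-consistency check of
    the sign conventions.
    """
    if T22 <= 0:
        raise ModelDomainError("T22 must be positive")
    lam, gam = ratios.lam, ratios.gam
    g2, g4 = gam**2, gam**4
    xa0, xp0 = init_velocities_2duct(imp, ratios)
    T21 = T22 * f0(gam, lam)
    xa_v = xa0 * (T22 + T21) / 2.0 + xp0 * (T22 - T21) / 2.0
    xp_v = xp0 * (T22 + T21) / 2.0 + xa0 * (T22 - T21) / 2.0
    den = imp.M * (g4 + 2.0 * lam)
    xa_i = T22 * (imp.I_aex * (g4 + lam) + imp.I_pex * lam + imp.I_cex * g2) / den
    xp_i = T22 * (imp.I_aex * lam + imp.I_pex * (g4 + lam) - imp.I_cex * g2) / den
    scale = max(abs(xa_i), abs(xp_i), 1e-300)
    if abs(xa_v - xa_i) > 1e-12 * scale or abs(xp_v - xp_i) > 1e-12 * scale:
        raise VestiflowError(
            "velocity-form and impulse-form maximal excursions disagree; "
            "internal sign conventions are inconsistent")
    if xa_i == 0.0:
        return xa_i, xp_i, math.nan
    return xa_i, xp_i, xp_i / xa_i


def k_alpha_max(imp: TwoDuctImpulses, ratios: TwoDuctRatios) -> float:
    """Ratio of maximal excursions x_p_max / x_a_max."""
    lam, g2, g4 = ratios.lam, ratios.gam**2, ratios.gam**4
    num = imp.I_aex * lam + imp.I_pex * (g4 + lam) - imp.I_cex * g2
    den = imp.I_aex * (g4 + lam) + imp.I_pex * lam + imp.I_cex * g2
    if den == 0.0:
        raise ModelDomainError("k_alpha_max undefined: zero maximal excursion in a")
    return num / den


def null_flow_angle(ratios: TwoDuctRatios) -> float:
    """Inter-duct angle [rad] at which rotation in duct a's plane leaves p still.

    alpha = pi - arccos(-f3) with f3 = lambda/(gamma^2 + lambda).
    """
    f3 = ratios.lam / (ratios.gam**2 + ratios.lam)
    if not (0.0 < f3 < 1.0):
        raise ModelDomainError("f3 outside (0, 1): no null-flow angle exists")
    return math.pi - math.acos(-f3)


def optimal_orientation(alpha: float) -> float:
    """Duct-to-midline angle mu = (pi - alpha)/2 for pitch-moving animals."""
    if not (0.0 < alpha < math.pi):
        raise ModelDomainError("inter-duct angle must lie in (0, pi)")
    return (math.pi - alpha) / 2.0


# ---------------------------------------------------------------------------
# Shape families and the lambda scan
# ---------------------------------------------------------------------------

def dip_family(lam: float, duct_length: float = 1.0,
               radius: float = 0.01) -> LabyrinthNetwork:
    """Two-triangle family with a dip between the ducts.

    Two mirror-image isosceles triangular circuits share a straight common
    leg of length lambda * duct_length; the duct arc length is held fixed,
    so lambda parameterises how deep the dip between the circuits is.
    Valid for lambda in (0, 1).
    """
    if not (0.0 < lam < 1.0):
        raise ModelDomainError("dip family requires lambda in (0, 1)")
    ld = duct_length
    hgt = lam * ld
    w = 0.5 * math.sqrt(ld * ld - hgt * hgt)
    A = (0.0, 0.0, 0.0)
    C = (0.0, hgt, 0.0)
    sections = [
        DuctSection("a", "A", "C", (A, (w, hgt / 2.0, 0.0), C),
                    radius=radius, elastic=True),
        DuctSection("p", "C", "A", (C, (-w, hgt / 2.0, 0.0), A),
                    radius=radius, elastic=True),
        DuctSection("c", "C", "A", (C, A), radius=radius),
    ]
    return LabyrinthNetwork(sections, nodes=("A", "C"))


def smooth_family(lam: float, circuit_radius: float = 1.0,
                  radius: float = 0.01, n_arc: int = 256) -> LabyrinthNetwork:
    """Single convex loop (a circle) split by a chord — no dip.

    The chord is the common part; the two circle arcs are the ducts.  lambda
    is the chord-to-major-arc length ratio, attained by moving the chord.
    """
    if not (0.0 < lam < 1.0):
        raise ModelDomainError("smooth family requires lambda in (0, 1)")
    # chord half-angle phi: lambda = sin(phi) / (pi - phi), monotone on (0, pi)
    phi = brentq(lambda x: math.sin(x) / (math.pi - x) - lam, 1e-9,
                 math.pi - 1e-9)
    R = circuit_radius
    A = (R * math.cos(phi), -R * math.sin(phi), 0.0)
    C = (R * math.cos(phi), R * math.sin(phi), 0.0)
    th_major = np.linspace(phi, 2.0 * math.pi - phi, n_arc)
    major = [(R * math.cos(t), R * math.sin(t), 0.0) for t in th_major]
    th_minor = np.linspace(-phi, phi, max(8, n_arc // 8))
    minor = [(R * math.cos(t), R * math.sin(t), 0.0) for t in th_minor]
    sections = [
        DuctSection("a", "C", "A", tuple(major), radius=radius, elastic=True),
        DuctSection("p", "A", "C", tuple(minor), radius=radius, elastic=True),
        DuctSection("c", "C", "A", (C, A), radius=radius),
    ]
    return LabyrinthNetwork(sections, nodes=("A", "C"))


def lambda_scan(shape_family, lam_grid, omega: float = 1.0) -> pd.DataFrame:
    """Normalized external impulse of duct a as a function of lambda.

    ``shape_family`` maps lambda to a two-duct network (e.g. ``dip_family``
    or ``smooth_family``).  For each shape the rotation stop is taken about
    the midpoint of the common part with the rotation axis normal to the
    labyrinth plane, and I_aex is normalized by rho |omega| V_total (total
    duct volume) so different families are comparable.

    Returns a DataFrame with columns ``lam`` and ``I_a_norm``; the attribute
    ``attrs['optimum']`` holds the interior-argmax lambda or ``None`` when
    the curve is monotone (or the grid is degenerate).
    """
    rows = []
    for lam in np.atleast_1d(np.asarray(lam_grid, dtype=float)):
        try:
            net = shape_family(float(lam))
        except (ModelDomainError, VestiflowError) as exc:
            import warnings

            warnings.warn(f"lambda={lam:g}: invalid geometry skipped ({exc})")
            continue
        common = net["c"]
        mid = 0.5 * (np.asarray(common.vertices[0])
                     + np.asarray(common.vertices[-1]))
        plane = np.cross(
            np.asarray(net["a"].vertices[1]) - np.asarray(net["a"].vertices[0]),
            np.asarray(net["a"].vertices[-1]) - np.asarray(net["a"].vertices[0]))
        axis = plane / np.linalg.norm(plane)
        stim = RotationStop(omega=tuple(omega * axis), origin=tuple(mid))
        imp = external_impulse(net["a"], net.props, stim)
        v_tot = sum(s.area * s.length for s in net.sections)
        rows.append((float(lam), imp.I_ex / (net.props.rho * abs(omega) * v_tot)))
    df = pd.DataFrame(rows, columns=["lam", "I_a_norm"])
    df.attrs["optimum"] = _interior_argmax(df)
    return df


def _interior_argmax(df: pd.DataFrame):
    if len(df) < 3:
        return None
    y = df["I_a_norm"].to_numpy()
    i = int(np.argmax(np.abs(y)))
    if i == 0 or i == len(y) - 1:
        return None
    return float(df["lam"].iloc[i])
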