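"""Size limitations and allometry of semicircular-duct systems.

A circular single-duct circuit is characterised by its circuit radius R and
duct cross-section radius r.  Three functional quantities bound the feasible
design region:

- response speed:  T2 = r^2/(8 nu)            (independent of R),
- sensitivity:     x_max = |omega| R T2,
- laminarity:      Re = |omega| R r / nu      (angular Reynolds number).

Empirical allometric laws relate circuit radius to body mass, with distinct
mammal and fish exponents; R is in millimetres and m in kilograms (the only
unit assignment consistent with the published larval-fish prediction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import EndolymphProps

__all__ = ["AllometryLaw", "MAMMAL_LAW", "FISH_LAW", "DesignPoint",
           "design_metrics", "allometry_R", "design_grid", "isoline_R"]


@dataclass(frozen=True)
class AllometryLaw:
    """Power law R = coeff * m^exp with R in mm and m in kg."""

    coeff: float
    exp: float
    taxon: str = ""

    def __post_init__(self):
        if self.coeff <= 0:
            raise ValueError("allometric prefactor must be positive")
        if not (0.0 < self.exp < 1.0):
            raise ValueError("allometric exponent must lie in (0, 1)")


MAMMAL_LAW = AllometryLaw(1.7644, 0.1157, taxon="mammals")
FISH_LAW = AllometryLaw(4.5487, 0.2885, taxon="fishes")


@dataclass(frozen=True)
class DesignPoint:
    """A candidate duct design: circuit radius R, duct radius r, speed omega."""

    R: float
    r: float
    omega: float = 1.0

    def __post_init__(self):
        if not (self.R > self.r > 0):
            raise ValueError("require circuit radius R > duct radius r > 0")


def design_metrics(pt: DesignPoint, props: EndolymphProps) -> tuple:
    """(T2 [s], x_max [m], Re) for one design point."""
    nu = props.nu
    T2 = pt.r**2 / (8.0 * nu)
    x_max = abs(pt.omega) * pt.R * T2
    Re = abs(pt.omega) * pt.R * pt.r / nu
    return T2, x_max, Re


def allometry_R(m: float, law: AllometryLaw) -> float:
    """Circuit radius [mm] predicted for body mass m [kg]."""
    if m <= 0:
        raise ValueError("body mass must be positive")
    return law.coeff * m**law.exp


def design_grid(r_range, R_range, omega: float, props: EndolymphProps,
                n: int = 50) -> pd.DataFrame:
    """Log-spaced grid of design metrics over (r, R) ranges.

    ``r_range`` and ``R_range`` are (min, max) in metres.  Returns a long
    DataFrame with columns r, R, T2, x_max, Re.
    """
    r_lo, r_hi = map(float, r_range)
    R_lo, R_hi = map(float, R_range)
    if not (0 < r_lo < r_hi and 0 < R_lo < R_hi):
        raise ValueError("ranges must be positive and increasing")
    rs = np.logspace(math.log10(r_lo), math.log10(r_hi), n)
    Rs = np.logspace(math.log10(R_lo), math.log10(R_hi), n)
    rg, Rg = np.meshgrid(rs, Rs)
    nu = props.nu
    T2 = rg**2 / (8.0 * nu)
    x_max = abs(omega) * Rg * T2
    Re = abs(omega) * Rg * rg / nu
    return pd.DataFrame({
        "r": rg.ravel(), "R": Rg.ravel(),
        "T2": T2.ravel(), "x_max": x_max.ravel(), "Re": Re.ravel(),
    })


def isoline_R(kind: str, level: float, r_values, omega: float,
              props: EndolymphProps) -> pd.DataFrame:
    """Closed-form isoline R(r) of one design metric.

    ``T2`` isolines are vertical lines in the (r, R) plane (returned as the
    constant r solving T2 = level); ``x_max`` isolines follow R ∝ 1/r^2 and
    ``Re`` isolines R ∝ 1/r.
    """
    nu = props.nu
    r = np.asarray(r_values, dtype=float)
    if kind == "T2":
        r_iso = math.sqrt(8.0 * nu * level)
        return pd.DataFrame({"r": np.full_like(r, r_iso), "R": r})
    if kind == "x_max":
        return pd.DataFrame({"r": r, "R": 8.0 * nu * level / (abs(omega) * r**2)})
    if kind == "Re":
        return pd.DataFrame({"r": r, "R": nu * level / (abs(omega) * r)})
    raise ValueError("kind must be one of 'T2', 'x_max', 'Re'")
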