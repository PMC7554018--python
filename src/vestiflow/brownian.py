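"""Thermal (Brownian) noise of an ampullar hair bundle.

The bundle is modelled as a stiff rod of length L, elastically anchored at
its base (spring constant kappa) and immersed in endolymph (transverse drag
coefficient gamma).  The mean-square tip excursion lambda = <x^2> obeys the
first-order power balance

    tau lambda' + lambda = 4 D tau,   D = kB T / gamma,   tau = gamma/(2 kappa),

whose solution relaxes from 0 to the stationary value 4 D tau = 2 kB T/kappa
with time constant tau (Tc = 2 tau).  The amplitude spectrum X*(f) [m] has a
low-frequency plateau X*(0) = sqrt(kB T / kappa) / (pi sqrt 2) and, in the
free-diffusion regime, the Einstein tail X*(f) = sqrt(D/(2 f)) / (2 pi).
The exact spectrum used here is the unique time-to-frequency reading of the
relaxation law that reproduces both printed asymptotes:

    X*_exact(f) = (1/2 pi) sqrt(lambda(t_f)),   t_f = 1/(8 f).

The classical two-term closed form

    X*(f) = X*(0) [A / sqrt(pi^2 f^2 a^2 Tc^2 + 1) + B / sqrt(pi^2 f^2 b^2 Tc^2 + 1)]

with A + B = 1 approximates it; the constants are obtained by a constrained
least-squares fit to the exact spectrum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.constants import k as BOLTZMANN
from scipy.optimize import least_squares

from .exceptions import ModelDomainError

__all__ = ["BundleModel", "SpectrumFit", "rod_friction", "amplitude_spectrum",
           "exact_amplitude_spectrum", "kappa_from_plateau", "einstein_rms",
           "fit_spectrum_constants"]


@dataclass(frozen=True)
class BundleModel:
    """Hair-bundle noise parameters.

    gamma_f : transverse drag coefficient of the bundle rod [kg/s]
    kappa : basal spring constant [N/m]
    temperature : absolute temperature [K] (default body temperature 310 K)
    """

    gamma_f: float
    kappa: float
    temperature: float = 310.0

    def __post_init__(self):
        if not (self.gamma_f > 0 and self.kappa > 0 and self.temperature > 0):
            raise ValueError("gamma_f, kappa and temperature must be positive")

    @property
    def kBT(self) -> float:
        """Thermal energy kB * T [J]."""
        return BOLTZMANN * self.temperature

    @property
    def D(self) -> float:
        """Diffusion constant kB T / gamma [m^2/s] (fluctuation-dissipation)."""
        return self.kBT / self.gamma_f

    @property
    def tau(self) -> float:
        """Relaxation time gamma/(2 kappa) [s]."""
        return self.gamma_f / (2.0 * self.kappa)

    @property
    def Tc(self) -> float:
        """Correlation time constant 2 tau [s]."""
        return 2.0 * self.tau

    @property
    def stationary_msd(self) -> float:
        """Stationary mean-square excursion 4 D tau = 2 kB T / kappa [m^2]."""
        return 4.0 * self.D * self.tau

    def msd(self, t) -> np.ndarray:
        """Mean-square excursion lambda(t) = 4 D tau (1 - e^{-t/tau}) [m^2]."""
        t = np.asarray(t, dtype=float)
        return self.stationary_msd * -np.expm1(-t / self.tau)


@dataclass(frozen=True)
class SpectrumFit:
    """Constants of the two-term closed-form spectrum (A + B = 1)."""

    A_c: float
    B_c: float
    a_c: float
    b_c: float
    residual: float = math.nan

    def __post_init__(self):
        if abs(self.A_c + self.B_c - 1.0) > 1e-9:
            raise ValueError("spectrum constants must satisfy A + B = 1")
        if min(self.A_c, self.B_c, self.a_c, self.b_c) <= 0:
            raise ValueError("spectrum constants must be positive")


def rod_friction(length: float, radius_r: float, eta: float) -> float:
    """Transverse slender-body drag of a prolate rod [kg/s].

    gamma = 4 pi eta L / (ln(L/r) + 0.84).  Valid for slender rods only
    (aspect ratio L/r > 2).
    """
    if length <= 0 or radius_r <= 0 or eta <= 0:
        raise ModelDomainError("length, radius and viscosity must be positive")
    if length <= 2.0 * radius_r:
        raise ModelDomainError(
            "slender-body drag requires aspect ratio L/r > 2")
    return 4.0 * math.pi * eta * length / (math.log(length / radius_r) + 0.84)


def amplitude_spectrum(model: BundleModel, fit: SpectrumFit, f) -> np.ndarray:
    """Two-term closed-form Brownian amplitude spectrum X*(f) [m]."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    plateau = math.sqrt(model.kBT / model.kappa) / (math.pi * math.sqrt(2.0))
    Tc = model.Tc
    term_a = fit.A_c / np.sqrt((math.pi * fit.a_c * Tc) ** 2 * f**2 + 1.0)
    term_b = fit.B_c / np.sqrt((math.pi * fit.b_c * Tc) ** 2 * f**2 + 1.0)
    return plateau * (term_a + term_b)


def exact_amplitude_spectrum(model: BundleModel, f) -> np.ndarray:
    """Exact amplitude spectrum (1/2 pi) sqrt(lambda(1/(8 f))) [m].

    Reading each frequency as an observation window t_f = 1/(8 f) of the
    mean-square relaxation law reproduces the plateau at f -> 0 and the
    free-diffusion Einstein tail sqrt(D/(2 f))/(2 pi) at f -> infinity.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ModelDomainError("exact spectrum needs strictly positive f")
    return np.sqrt(model.msd(1.0 / (8.0 * f))) / (2.0 * math.pi)


def kappa_from_plateau(plateau: float, kBT: float) -> float:
    """Bundle stiffness from a measured low-frequency plateau [N/m].

    Exact inverse of the plateau relation: kappa = kB T / (2 pi^2 X*(0)^2).
    """
    if plateau <= 0 or kBT <= 0:
        raise ModelDomainError("plateau and kBT must be positive")
    return kBT / (2.0 * math.pi**2 * plateau**2)


def einstein_rms(D: float, t: float | None = None,
                 f: float | None = None) -> float:
    """Free-diffusion rms displacement [m].

    Time form: sqrt(4 D t).  Frequency form: sqrt(D/(2 f))/(2 pi); diverges
    as f -> 0, which is flagged rather than returned.
    """
    if D <= 0:
        raise ModelDomainError("diffusion constant must be positive")
    if (t is None) == (f is None):
        raise ValueError("give exactly one of t or f")
    if t is not None:
        if t < 0:
            raise ModelDomainError("time must be non-negative")
        return math.sqrt(4.0 * D * t)
    if f <= 0:
        raise ModelDomainError(
            "frequency-domain rms diverges at f = 0; evaluate at f > 0")
    return math.sqrt(D / (2.0 * f)) / (2.0 * math.pi)


def fit_spectrum_constants(model: BundleModel, n_points: int = 200,
                           f_lo_Tc: float = 1e-3,
                           f_hi_Tc: float = 10.0) -> SpectrumFit:
    """Fit the two-term closed form to the exact spectrum (A + B = 1).

    The fit minimises the worst-case relative deviation on a log-spaced grid
    f * Tc in [f_lo_Tc, f_hi_Tc] (a least-squares pass provides the starting
    point, a derivative-free minimax pass polishes it); the plateau is exact
    for any constants because of the A + B = 1 constraint, so only the
    roll-off shape is fitted.  Returns the constants together with the
    maximum relative residual over the fitted band.
    """
    from scipy.optimize import minimize

    Tc = model.Tc
    f = np.logspace(math.log10(f_lo_Tc / Tc), math.log10(f_hi_Tc / Tc),
                    n_points)
    target = exact_amplitude_spectrum(model, f)

    def resid(params):
        A, a, b = params
        fit = SpectrumFit(A_c=A, B_c=1.0 - A, a_c=a, b_c=b)
        return amplitude_spectrum(model, fit, f) / target - 1.0

    res = least_squares(resid, x0=[0.7, 1.0, 0.1],
                        bounds=([1e-6, 1e-6, 1e-6], [1 - 1e-6, 1e3, 1e3]))
    if not res.success:  # pragma: no cover - optimizer failure diagnostics
        raise ModelDomainError(
            f"spectrum fit failed: {res.message}; residuals {res.fun}")

    def worst(params):
        A, a, b = params
        if not (0.0 < A < 1.0 and a > 0.0 and b > 0.0):
            return np.inf
        return float(np.max(np.abs(resid(params))))

    polish = minimize(worst, res.x, method="Nelder-Mead",
                      options={"maxiter": 4000, "xatol": 1e-10,
                               "fatol": 1e-12})
    x = polish.x if polish.fun <= worst(res.x) else res.x
    A, a, b = x
    return SpectrumFit(A_c=float(A), B_c=float(1.0 - A), a_c=float(a),
                       b_c=float(b), residual=worst(x))
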