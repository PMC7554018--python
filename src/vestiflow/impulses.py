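"""External impulses generated by a pseudo-impulse rotation stop.

The stimulus protocol is a long constant rotation halted instantaneously at
t = 0.  Integrating the tangential acceleration over the (vanishingly short)
stop interval leaves the endolymph moving at omega x r relative to the duct
wall, and endows each duct section with an *external impulse*: the momentum
due solely to that section's own motion,

    I_sex = (rho A_s l_s) (omega x h_s) . t_hat  * sign_s,

where h_s is the perpendicular from the rotation centre M to the section's
supporting line and t_hat the unit vector of the positive flow direction.
For polyline sections the impulse is summed over the straight sub-segments.

The centripetal and Coriolis terms of the full acceleration decomposition
vanish for this protocol (all coordinate frames coincide at the stop), so
only the tangential term is integrated; the stop duration never appears
because the implementation works directly with momenta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DuctSection, EndolymphProps, LabyrinthNetwork

__all__ = ["RotationStop", "SectionImpulse", "initial_velocity_stop",
           "external_impulse", "network_impulses"]


def _vec3(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("vector components must be finite")
    return a


@dataclass(frozen=True)
class RotationStop:
    """A rotation stimulus applied as a pseudo-impulse stop.

    Parameters
    ----------
    omega : angular-velocity vector before the stop [rad/s]
    origin : rotation centre M [m]
    """

    omega: tuple = (0.0, 0.0, 0.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "omega", tuple(_vec3(self.omega)))
        object.__setattr__(self, "origin", tuple(_vec3(self.origin)))

    @property
    def omega_vec(self) -> np.ndarray:
        return np.asarray(self.omega)

    @property
    def origin_vec(self) -> np.ndarray:
        return np.asarray(self.origin)


@dataclass(frozen=True)
class SectionImpulse:
    """External impulse of one section, reduced to a signed scalar.

    ``I_ex`` [kg m/s] is the momentum along the section's positive flow
    direction; ``v0_free`` [m/s] is the equivalent free tangential speed,
    I_ex / (rho A l sign) — what the section's endolymph would do if the
    section were an isolated closed circuit.
    """

    section: str
    I_ex: float
    v0_free: float


def initial_velocity_stop(stimulus: RotationStop, r) -> np.ndarray:
    """Endolymph velocity omega x r relative to the abruptly stopped wall.

    ``r`` is the position of the fluid point relative to the rotation
    centre M.  Total function: a zero rotation yields the zero vector.
    """
    return np.cross(stimulus.omega_vec, _vec3(r))


def external_impulse(section: DuctSection, props: EndolymphProps,
                     stimulus: RotationStop) -> SectionImpulse:
    """External impulse of one (possibly polyline) duct section.

    Sums rho A l_seg (omega x h_seg) . t_hat_seg over the straight
    sub-segments; for a single straight section this is exactly the
    momentum-arm formula above.
    """
    omega = stimulus.omega_vec
    origin = stimulus.origin_vec
    segs = section.segment_vectors
    lens = section.segment_lengths
    total = 0.0
    pts = section.points
    for i in range(len(segs)):
        h = _vec3(pts[i] - origin)
        # (omega x h).t is invariant to sliding h along the segment, so the
        # segment start point serves as the arm; the perpendicular foot gives
        # the identical projection.
        t_hat = segs[i] / lens[i]
        total += lens[i] * float(np.cross(omega, h) @ t_hat)
    I_ex = props.rho * section.area * total * section.flow_sign
    v0_free = I_ex / (props.rho * section.area * section.length * section.flow_sign)
    return SectionImpulse(section.name, I_ex, v0_free)


def network_impulses(net: LabyrinthNetwork, stimulus: RotationStop) -> dict:
    """External impulses for every section of a network, keyed by name."""
    return {s.name: external_impulse(s, net.props, stimulus) for s in net.sections}
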