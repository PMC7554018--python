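"""Initial endolymph velocities of a coupled duct network after a stop.

Immediately after the pseudo-impulse stop, viscosity and cupular elasticity
have had no time to act, so the flow distribution follows from momentum
balance alone.  For each section (from node X to node Y, positive direction)

    m_s v_s - A_s (P_X - P_Y) = I_sex,

where P is the time-integrated pressure impulse at a confluence node, plus
volume continuity  sum(+/- A_s v_s) = 0  at every node but one.  Pressure
impulses are gauged to zero at a reference node (only differences matter).

For the canonical five-section, three-node labyrinth this system is
algebraically equivalent to the printed 5x5 formulation of the coupled
theory; here the continuity rows are assembled from the topology, which
generalises to any connected network with at least one loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ModelDomainError, TopologyError
from .geometry import LabyrinthNetwork
from .impulses import RotationStop, network_impulses

__all__ = ["InitialFlowState", "solve_initial_velocities",
           "subcupular_initial_velocity"]


@dataclass(frozen=True)
class InitialFlowState:
    """Per-section initial velocities and per-node pressure impulses.

    ``velocities`` maps section name to x_s'(0) [m/s] (along the positive
    flow direction); ``pressure_impulses`` maps node label to P [Pa s],
    gauged to zero at ``reference_node``.
    """

    velocities: dict
    pressure_impulses: dict
    reference_node: str

    def velocity_vector(self, order) -> np.ndarray:
        return np.array([self.velocities[name] for name in order])


def solve_initial_velocities(net: LabyrinthNetwork,
                             stimulus: RotationStop | None = None,
                             impulses: dict | None = None,
                             reference_node: str | None = None
                             ) -> InitialFlowState:
    """Solve the momentum + continuity system for the initial velocities.

    Either a rotation stimulus or an explicit impulse table (section name ->
    external impulse [kg m/s], missing names = 0) must be given.  The
    pressure-impulse gauge is anchored at ``reference_node`` (default: the
    lexicographically first node); the velocities are gauge-independent.

    Raises
    ------
    TopologyError
        If the network has no loop (the system is then singular: a tree
        cannot carry any divergence-free flow).
    """
    if impulses is None:
        if stimulus is None:
            raise ValueError("provide a stimulus or an explicit impulse table")
        impulses = {k: v.I_ex for k, v in network_impulses(net, stimulus).items()}
    if net.n_loops() < 1:
        raise TopologyError("network has no loop; no coupled flow is possible")

    sections = net.sections
    ns = len(sections)
    if reference_node is None:
        ref = sorted(net.nodes)[0]
    elif reference_node in net.nodes:
        ref = reference_node
    else:
        raise TopologyError(f"unknown reference node {reference_node!r}")
    free_nodes = [n for n in net.nodes if n != ref]
    nn = len(free_nodes)
    node_col = {n: ns + i for i, n in enumerate(free_nodes)}

    M = np.zeros((ns + nn, ns + nn))
    rhs = np.zeros(ns + nn)
    rho = net.props.rho
    for j, s in enumerate(sections):
        m_s = rho * s.area * s.length
        M[j, j] = m_s
        if s.node_from != ref:
            M[j, node_col[s.node_from]] = -s.area
        if s.node_to != ref:
            M[j, node_col[s.node_to]] = s.area
        rhs[j] = float(impulses.get(s.name, 0.0))
    D = net.incidence_matrix(drop_node=ref)
    for i in range(nn):
        for j, s in enumerate(sections):
            M[ns + i, j] = D[i, j] * s.area

    try:
        sol = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise TopologyError(f"singular initial-velocity system: {exc}") from exc

    velocities = {s.name: float(sol[j]) for j, s in enumerate(sections)}
    pressures = {ref: 0.0}
    pressures.update({n: float(sol[node_col[n]]) for n in free_nodes})
    return InitialFlowState(velocities, pressures, ref)


def subcupular_initial_velocity(l_d: float, l_s: float, A_d: float, A_s: float,
                                speed: float = 1.0,
                                normalized: bool = False) -> float:
    """Initial velocity in the subcupular space of a duct + subcupular circuit.

    For a circuit of a duct (length l_d, area A_d) in series with the narrow
    subcupular space (l_s, A_s), momentum balance gives

        x_s'(0) = |omega x r| * (1 + l_d/l_s) / (1 + (l_d/l_s)(A_s/A_d)).

    With ``normalized=True`` the stimulus speed is divided out (the utricular
    part is omitted, which is the standard simplification).
    """
    if min(l_d, l_s, A_d, A_s) <= 0:
        raise ModelDomainError("lengths and areas must all be positive")
    ratio = l_d / l_s
    factor = (1.0 + ratio) / (1.0 + ratio * (A_s / A_d))
    return factor if normalized else speed * factor
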