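"""Duct geometry: planes, sections, networks and canonical labyrinth fixtures.

The semicircular-duct (SCD) system is modelled as a network of straight or
polyline duct sections joined at confluence nodes and filled with endolymph.
Each duct circuit lies (at least approximately) in a flat plane; the plane
through three corner points is obtained from 2x2 determinants of coordinate
differences.  Curved ducts are represented as polyline chains of straight
sub-sections, which is all the downstream momentum integrals require.

Units are strict SI throughout (metres, kilograms, seconds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateGeometryError, TopologyError

__all__ = [
    "PlaneCoeffs",
    "EndolymphProps",
    "DuctSection",
    "LabyrinthNetwork",
    "WATER_LIKE_ENDOLYMPH",
    "plane_from_points",
    "perpendicular_foot",
    "build_fixture",
    "FIXTURE_NAMES",
]

#: Relative tolerance used by geometric consistency checks.
GEOM_RTOL = 1e-9


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise DegenerateGeometryError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise DegenerateGeometryError("point coordinates must be finite")
    return a


@dataclass(frozen=True)
class PlaneCoeffs:
    """Coefficients of the plane A*x + B*y + C*z + D = 0.

    (A, B, C) is an (unnormalised) normal vector with units m^2, D an offset
    with units m^3 — the natural units of the determinant construction.
    """

    A: float
    B: float
    C: float
    D: float

    @property
    def normal(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C])

    def evaluate(self, point) -> float:
        """Signed plane equation residual A*x + B*y + C*z + D at ``point``."""
        p = _as_point(point)
        return float(self.normal @ p + self.D)


def plane_from_points(a, b, c) -> PlaneCoeffs:
    """Plane through three non-collinear points.

    The coefficients are built from 2x2 determinants of coordinate
    differences; (A, B, C) equals the cross product (b - a) x (c - a).

    Raises
    ------
    DegenerateGeometryError
        If the points are collinear or coincident.
    """
    pa, pb, pc = _as_point(a), _as_point(b), _as_point(c)
    u = pb - pa
    v = pc - pa
    A = u[1] * v[2] - u[2] * v[1]
    B = u[2] * v[0] - u[0] * v[2]
    C = u[0] * v[1] - u[1] * v[0]
    scale = max(np.linalg.norm(u) * np.linalg.norm(v), 1e-300)
    if math.hypot(A, B, C) <= 1e-12 * scale:
        raise DegenerateGeometryError(
            "the three points are collinear or coincident; no unique plane"
        )
    D = -(pa[0] * A + pa[1] * B + pa[2] * C)
    return PlaneCoeffs(A, B, C, D)


def perpendicular_foot(origin, p0, p1) -> np.ndarray:
    """Vector from ``origin`` perpendicular onto the line through p0, p1.

    This is the moment arm h of a straight duct segment with respect to the
    rotation centre: the returned vector points from the origin to the closest
    point of the segment's supporting line and is orthogonal to p1 - p0.
    """
    o, a, b = _as_point(origin), _as_point(p0), _as_point(p1)
    d = b - a
    n2 = float(d @ d)
    if n2 == 0.0:
        raise DegenerateGeometryError("zero-length segment has no supporting line")
    t = float((o - a) @ d) / n2
    foot = a + t * d
    return foot - o


@dataclass(frozen=True)
class EndolymphProps:
    """Physical properties of the endolymph (a water-like fluid).

    Parameters
    ----------
    rho : density [kg/m^3]
    eta : dynamic viscosity [Pa s]
    """

    rho: float = 1000.0
    eta: float = 1.0e-3

    def __post_init__(self):
        if not (self.rho > 0 and self.eta > 0):
            raise ValueError("endolymph density and viscosity must be positive")

    @property
    def nu(self) -> float:
        """Kinematic viscosity eta/rho [m^2/s]."""
        return self.eta / self.rho


#: Default endolymph: water at body-ish temperature (nu = 1e-6 m^2/s).
WATER_LIKE_ENDOLYMPH = EndolymphProps()


@dataclass(frozen=True)
class DuctSection:
    """One duct section: a straight segment or a polyline chain of segments.

    The vertex order defines the positive flow direction (the arrow convention
    of the folded-out network diagram); ``flow_sign`` flips it without editing
    the vertex list.  ``elastic`` marks sections that contain a cupular spring
    (the three ampullary ducts a, p, h; never the crus commune or utriculus).
    """

    name: str
    node_from: str
    node_to: str
    vertices: tuple = ()  # tuple of 3-tuples, >= 2 points
    radius: float = 0.0
    flow_sign: int = 1
    elastic: bool = False

    def __post_init__(self):
        pts = tuple(tuple(float(x) for x in _as_point(p)) for p in self.vertices)
        object.__setattr__(self, "vertices", pts)
        if len(pts) < 2:
            raise DegenerateGeometryError(
                f"section {self.name!r} needs at least two vertices"
            )
        if self.radius <= 0:
            raise ValueError(f"section {self.name!r} must have a positive radius")
        if self.flow_sign not in (-1, 1):
            raise ValueError(f"section {self.name!r}: flow_sign must be +1 or -1")
        if self.length <= 0:
            raise DegenerateGeometryError(f"section {self.name!r} has zero length")

    @property
    def points(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)

    @property
    def segment_vectors(self) -> np.ndarray:
        p = self.points
        return p[1:] - p[:-1]

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.segment_vectors, axis=1)

    @property
    def length(self) -> float:
        """Arc length l_s of the polyline [m]."""
        return float(self.segment_lengths.sum())

    @property
    def area(self) -> float:
        """Cross-sectional area A_s = pi r_s^2 [m^2]."""
        return math.pi * self.radius**2

    def h_vectors(self, origin) -> np.ndarray:
        """Per-segment moment arms h: perpendicular feet from ``origin``."""
        p = self.points
        return np.array(
            [perpendicular_foot(origin, p[i], p[i + 1]) for i in range(len(p) - 1)]
        )


@dataclass
class LabyrinthNetwork:
    """A set of duct sections joined at confluence nodes.

    Validates on construction: all section endpoints must be declared nodes,
    every node must join at least two sections, and the section graph must be
    connected.
    """

    sections: list
    nodes: tuple = ()
    props: EndolymphProps = field(default_factory=EndolymphProps)

    def __post_init__(self):
        self.sections = list(self.sections)
        declared = tuple(self.nodes) if self.nodes else tuple(
            sorted({s.node_from for s in self.sections}
                   | {s.node_to for s in self.sections})
        )
        self.nodes = declared
        names = [s.name for s in self.sections]
        if len(set(names)) != len(names):
            raise TopologyError("duplicate section names in network")
        touch = {n: 0 for n in declared}
        for s in self.sections:
            for n in (s.node_from, s.node_to):
                if n not in touch:
                    raise TopologyError(
                        f"section {s.name!r} references undeclared node {n!r}"
                    )
                touch[n] += 1
        lonely = [n for n, k in touch.items() if k < 2]
        if lonely:
            raise TopologyError(f"nodes {lonely} are touched by fewer than 2 sections")
        if not self._connected():
            raise TopologyError("duct network is not connected")

    def _connected(self) -> bool:
        if not self.sections:
            return False
        adj = {n: set() for n in self.nodes}
        for s in self.sections:
            adj[s.node_from].add(s.node_to)
            adj[s.node_to].add(s.node_from)
        seen = {self.nodes[0]}
        stack = [self.nodes[0]]
        while stack:
            for m in adj[stack.pop()]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        return len(seen) == len(self.nodes)

    def __getitem__(self, name: str) -> DuctSection:
        for s in self.sections:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def section_names(self) -> list:
        return [s.name for s in self.sections]

    def incidence_matrix(self, drop_node: str | None = None) -> np.ndarray:
        """Signed node-section incidence (+1 where a section enters the node).

        One node row may be dropped (continuity equations are dependent).
        """
        rows = [n for n in self.nodes if n != drop_node]
        D = np.zeros((len(rows), len(self.sections)))
        for j, s in enumerate(self.sections):
            for i, n in enumerate(rows):
                if s.node_to == n:
                    D[i, j] += 1.0
                if s.node_from == n:
                    D[i, j] -= 1.0
        return D

    def n_loops(self) -> int:
        return len(self.sections) - len(self.nodes) + 1


# ---------------------------------------------------------------------------
# Canonical fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("flat_three_duct", "two_duct_fig4", "human_like")

_DEFAULT_SCALES = {
    "flat_three_duct": 0.004,
    "two_duct_fig4": 0.01,
    "human_like": 0.01,
}


def _triangle_duct(name, n_from, n_to, p_from, p_to, duct_length, side, radius,
                   elastic=True):
    """Isosceles triangular duct from p_from to p_to with given arc length.

    ``side`` is a unit-ish vector giving the direction in which the apex
    bulges out of the chord.
    """
    p0, p1 = _as_point(p_from), _as_point(p_to)
    chord = np.linalg.norm(p1 - p0)
    half = duct_length / 2.0
    if half <= chord / 2.0:
        raise DegenerateGeometryError(
            f"duct {name!r}: length {duct_length} too short for chord {chord}"
        )
    h = math.sqrt(half**2 - (chord / 2.0) ** 2)
    side = _as_point(side)
    side = side / np.linalg.norm(side)
    apex = (p0 + p1) / 2.0 + h * side
    return DuctSection(name, n_from, n_to, (tuple(p0), tuple(apex), tuple(p1)),
                       radius=radius, elastic=elastic)


def _flat_three_duct(s: float) -> LabyrinthNetwork:
    # Folded-out flat layout: three confluence nodes on the x-axis, the crus
    # commune (c) and utriculus (u) as short wide straight sections between
    # them, and the three ampullary ducts as triangular circuits (two vertical
    # ducts of length 6 s, the horizontal duct about half that, equal radii).
    E = (-0.75 * s, 0.0, 0.0)
    C = (0.0, 0.0, 0.0)
    A = (0.75 * s, 0.0, 0.0)
    r_d, r_c, r_u = 0.05 * s, 0.11 * s, 0.20 * s
    up, down = (0.0, 1.0, 0.0), (0.0, -1.0, 0.0)
    sections = [
        _triangle_duct("a", "A", "E", A, E, 6.0 * s, up, r_d),
        _triangle_duct("p", "C", "A", C, A, 6.0 * s, down, r_d),
        _triangle_duct("h", "E", "C", E, C, 3.0 * s, down, r_d),
        DuctSection("c", "C", "A", (C, A), radius=r_c),
        DuctSection("u", "E", "C", (E, C), radius=r_u),
    ]
    return LabyrinthNetwork(sections, nodes=("A", "C", "E"))


def _two_duct_fig4(s: float) -> LabyrinthNetwork:
    # Two congruent right-isosceles triangular circuits sharing one leg: the
    # common part c runs C -> A (length s); each duct traverses the other leg
    # plus the hypotenuse, length s(1 + sqrt(2)), so lambda = 1/(1 + sqrt 2).
    A = (0.0, 0.0, 0.0)
    C = (0.0, s, 0.0)
    B = (s, 0.0, 0.0)
    D = (-s, 0.0, 0.0)
    r = 0.02 * s
    sections = [
        DuctSection("a", "A", "C", (A, B, C), radius=r, elastic=True),
        DuctSection("p", "C", "A", (C, D, A), radius=r, elastic=True),
        DuctSection("c", "C", "A", (C, A), radius=r),
    ]
    return LabyrinthNetwork(sections, nodes=("A", "C"))


def _human_like(s: float) -> LabyrinthNetwork:
    # Single duct circuit with human-like dimensions at the default scale
    # s = 0.01 m: duct radius 0.2 mm (T2 = r^2/8nu = 5 ms with nu = 1e-6),
    # duct length 2 s = 20 mm, wide utricular return path.
    U1 = (0.0, 0.0, 0.0)
    U2 = (s, 0.0, 0.0)
    sections = [
        _triangle_duct("d", "U1", "U2", U1, U2, 2.0 * s, (0.0, 1.0, 0.0),
                       0.02 * s),
        DuctSection("u", "U2", "U1", (U2, U1), radius=0.06 * s),
    ]
    return LabyrinthNetwork(sections, nodes=("U1", "U2"))


def build_fixture(name: str, scale: float | None = None) -> LabyrinthNetwork:
    """Build one of the canonical labyrinth geometries.

    Parameters
    ----------
    name : one of ``flat_three_duct``, ``two_duct_fig4``, ``human_like``
    scale : overall length scale [m]; each fixture has a sensible default
        (crus-commune/utricle chord for the three-duct layout, shared-leg
        length for the two-duct layout).
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    s = _DEFAULT_SCALES[name] if scale is None else float(scale)
    if s <= 0:
        raise ValueError("fixture scale must be positive")
    builder = {
        "flat_three_duct": _flat_three_duct,
        "two_duct_fig4": _two_duct_fig4,
        "human_like": _human_like,
    }[name]
    return builder(s)
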