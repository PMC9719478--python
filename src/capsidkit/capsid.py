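"""Quasi-equivalence bookkeeping for the pseudo-T=21 capsid and 3D point models.

A pT = 21 dextro (h = 4, k = 1) shell built from pseudo-hexameric major
capsid protein (MCP) trimers has 200 trimers in four symmetry-distinct
positions plus 12 pentons.  Each asymmetric unit holds 10 MCP monomers
(20 jelly-roll beta-sandwiches) and one penton domain: 21 quasi-equivalent
building blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import icosa
from .lattice import CapsomerSite, LatticeIndex, build_capsid_lattice

__all__ = [
    "TrimerSite",
    "AsymmetricUnitComposition",
    "CapsidPointModel",
    "assign_trimer_types",
    "asymmetric_unit_composition",
    "build_point_model",
]


@dataclass
class TrimerSite:
    site: CapsomerSite
    trimer_type: int  # 1..4
    copies_per_capsid: int


@dataclass(frozen=True)
class AsymmetricUnitComposition:
    mcp_monomers: int
    beta_sandwiches: int
    penton_domains: int

    @property
    def building_blocks(self) -> int:
        return self.beta_sandwiches + self.penton_domains

    def __post_init__(self):
        if self.beta_sandwiches != 2 * self.mcp_monomers:
            raise ValueError("each MCP monomer contributes exactly two beta-sandwiches")


@dataclass
class CapsidPointModel:
    points: list  # (position in Angstrom, label)
    capsid_radius: float
    membrane_radius: float | None = None
    membrane_thickness: float | None = None


def _min_axis_angle(position: np.ndarray, directions: np.ndarray) -> float:
    # angle to the nearest axis, axes being antipodal pairs
    c = np.clip(np.abs(directions @ position), -1.0, 1.0)
    return float(np.arccos(c.max()))


def assign_trimer_types(lattice_sites: list, axes: list) -> list:
    """Assign trimer types 1-4 to the hexamer sites of the (4, 1) capsid.

    Type 3 trimers sit on the icosahedral three-fold axes (20 copies,
    one MCP monomer per asymmetric unit).  Of the three remaining
    60-copy orbits, type 1 is the orbit closest to the five-fold axes
    (peripentonal), type 2 the closest to the two-fold axes of the rest,
    and type 4 the remainder, farthest from any symmetry axis.  Ties are
    broken by angular distance at 1e-9, then by orbit id (the (4, 1)
    lattice has no true ties; the rule keeps the contract total).
    """
    hexes = [s for s in lattice_sites if s.kind == "hexamer"]
    pents = [s for s in lattice_sites if s.kind == "pentamer"]
    if len(hexes) != 200 or len(pents) != 12:
        raise ValueError(
            "trimer typing is specific to the pT=21 (4,1) capsid "
            f"(got {len(pents)} pentamers / {len(hexes)} hexamers)"
        )
    five = icosa.axes_by_fold(axes, 5)
    two = icosa.axes_by_fold(axes, 2)

    orbits: dict = {}
    for s in hexes:
        orbits.setdefault(s.orbit_id, []).append(s)

    def orbit_dist(oid: int, directions: np.ndarray) -> float:
        return min(_min_axis_angle(s.position, directions) for s in orbits[oid])

    type_of: dict = {}
    on3 = [oid for oid, sites in orbits.items() if sites[0].on_threefold]
    if len(on3) != 1 or len(orbits[on3[0]]) != 20:
        raise ValueError("(4,1) lattice must have one 20-copy orbit on the three-folds")
    type_of[on3[0]] = 3
    remaining = [oid for oid in orbits if oid not in type_of]
    t1 = min(remaining, key=lambda o: (round(orbit_dist(o, five), 9), o))
    type_of[t1] = 1
    remaining = [oid for oid in remaining if oid != t1]
    t2 = min(remaining, key=lambda o: (round(orbit_dist(o, two), 9), o))
    type_of[t2] = 2
    (t4,) = [oid for oid in remaining if oid != t2]
    type_of[t4] = 4

    return [
        TrimerSite(site=s, trimer_type=type_of[s.orbit_id], copies_per_capsid=len(orbits[s.orbit_id]))
        for s in hexes
    ]


def asymmetric_unit_composition(index: LatticeIndex) -> AsymmetricUnitComposition:
    """Asymmetric-unit census for a pseudo-T capsid with trimeric MCPs.

    The 10(T-1) trimers contribute 30(T-1) monomers over 60 asymmetric
    units: (T-1)/2 monomers each, i.e. T-1 beta-sandwiches, plus one
    penton domain, for T building blocks per asymmetric unit.  Even T is
    rejected: the monomer count would be fractional, the arithmetic twin
    of the geometric two-fold exclusion.
    """
    T = index.T
    if T % 2 == 0:
        raise ValueError(
            f"T = {T} is even: (T-1)/2 monomers per asymmetric unit is not an "
            "integer (a trimer would need to straddle a two-fold axis)"
        )
    monomers = (T - 1) // 2
    return AsymmetricUnitComposition(
        mcp_monomers=monomers, beta_sandwiches=2 * monomers, penton_domains=1
    )


def _fibonacci_sphere(n: int) -> np.ndarray:
    # deterministic quasi-uniform directions
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def build_point_model(
    index: LatticeIndex,
    capsid_radius: float,
    membrane: tuple | None = None,
    points_per_capsomer: int = 1,
    membrane_points: int = 500,
) -> CapsidPointModel:
    """Pseudo-atom model of a capsid: one cluster per capsomer, optional membrane.

    Capsomer centres are scaled to ``capsid_radius`` (Angstrom).  With
    ``points_per_capsomer`` > 1 the extra points are placed on a small
    deterministic ring around each centre.  ``membrane`` is an optional
    (radius, thickness) pair sampled as a deterministic spherical shell
    spanning radius +/- thickness/2.
    """
    if capsid_radius <= 0:
        raise ValueError("capsid_radius must be positive")
    membrane_radius = membrane_thickness = None
    if membrane is not None:
        membrane_radius, membrane_thickness = float(membrane[0]), float(membrane[1])
        if membrane_radius >= capsid_radius:
            raise ValueError("membrane must lie inside the capsid shell")
        if membrane_thickness <= 0:
            raise ValueError("membrane thickness must be positive")
    sites = build_capsid_lattice(index)
    points = []
    for s in sites:
        label = "PEN" if s.kind == "pentamer" else "HEX"
        centre = s.position * capsid_radius
        points.append((centre, label))
        if points_per_capsomer > 1:
            # small ring in the tangent plane around the centre
            normal = s.position
            seed_vec = np.array([1.0, 0.0, 0.0])
            if abs(normal[0]) > 0.9:
                seed_vec = np.array([0.0, 1.0, 0.0])
            u = np.cross(normal, seed_vec)
            u /= np.linalg.norm(u)
            v = np.cross(normal, u)
            ring_r = 0.02 * capsid_radius
            for m in range(points_per_capsomer - 1):
                a = 2.0 * np.pi * m / (points_per_capsomer - 1)
                points.append((centre + ring_r * (np.cos(a) * u + np.sin(a) * v), label))
    if membrane is not None:
        dirs = _fibonacci_sphere(membrane_points)
        # alternate radii across the shell thickness, deterministic
        radii = membrane_radius + membrane_thickness * (
            (np.arange(membrane_points) % 11) / 10.0 - 0.5
        )
        for d, r in zip(dirs, radii):
            points.append((d * r, "MEM"))
    return CapsidPointModel(
        points=points,
        capsid_radius=capsid_radius,
        membrane_radius=membrane_radius,
        membrane_thickness=membrane_thickness,
    )
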