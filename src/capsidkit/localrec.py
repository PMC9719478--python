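"""Sub-particle geometry for localized reconstruction.

Localized reconstruction treats symmetry-related subregions of a large
particle (here: capsomers of an icosahedral capsid) as independent single
particles.  Each sub-particle's orientation and in-plane position derive
from (i) the parent particle's orientation, (ii) a capsid-frame vector to
the capsomer centre, and (iii) the icosahedral symmetry group.  Sites on
symmetry axes yield fewer distinct sub-particles (60 generic, 20 on
three-folds, 12 on five-folds per capsid) because group images coincide.

Conventions (documented once, used everywhere):

* Euler angles (rot, tilt, psi) are intrinsic ZYZ, degrees; the particle
  matrix ``R = Rz(rot) @ Ry(tilt) @ Rz(psi)`` maps capsid-frame
  coordinates to the laboratory frame, whose z axis is the imaging axis.
* The local-axis alignment ``A`` is the minimal rotation taking the site
  direction onto +z, so an aligned sub-particle's local symmetry axis
  lies on z; the in-plane angle is whatever the minimal rotation gives
  (a documented, deterministic choice).
* Sub-particle orientation = ``R_parent @ G @ A.T`` (alignment composed
  with the symmetry operator and the parent orientation).
* A worked example: the identity particle with a site on +x at radius r
  gives a sub-particle at lab position (r, 0, 0), offsets (r/pixel, 0),
  z_shift 0, and orientation A.T = Ry(-90 deg), i.e. Euler
  (rot, tilt, psi) with tilt = 90.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from . import icosa
from .capsid import CapsidPointModel

__all__ = [
    "ParticleRecord",
    "SubParticleVector",
    "SubParticleRecord",
    "RelaxationSet",
    "CompositeComponent",
    "define_subparticle_vector",
    "expand_subparticles",
    "adjust_defocus",
    "relax_candidates",
    "stitch_composite",
    "euler_to_matrix",
    "matrix_to_euler",
]


@dataclass
class ParticleRecord:
    id: str
    euler_rot: float
    euler_tilt: float
    euler_psi: float
    origin_x: float = 0.0  # pixels
    origin_y: float = 0.0
    defocus_u: float = 0.0  # Angstrom
    defocus_v: float = 0.0
    image_ref: str = ""
    pixel_size: float = 1.0  # Angstrom / pixel

    def __post_init__(self):
        if not (0.0 <= self.euler_tilt <= 180.0):
            raise ValueError("tilt must be in [0, 180] degrees")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def matrix(self) -> np.ndarray:
        return euler_to_matrix(self.euler_rot, self.euler_tilt, self.euler_psi)


@dataclass(frozen=True)
class SubParticleVector:
    direction: np.ndarray  # unit, capsid frame
    radius: float  # Angstrom

    def point(self) -> np.ndarray:
        return self.direction * self.radius


@dataclass
class SubParticleRecord:
    parent_id: str
    sym_index: int
    euler_rot: float
    euler_tilt: float
    euler_psi: float
    offset_x: float  # pixels, parent origin included
    offset_y: float
    defocus_u: float
    defocus_v: float
    z_shift: float  # Angstrom


@dataclass
class RelaxationSet:
    candidates: list  # of (rot, tilt, psi) degrees
    n: int


@dataclass
class CompositeComponent:
    """A localized reconstruction to be stitched back into the capsid.

    ``points`` live in the component's local frame (site centred at the
    origin, local symmetry axis on +z).  ``mask_diameter`` is in pixels,
    as masks are defined on the reconstruction grid.
    """

    points: list  # of (xyz Angstrom, label)
    site_direction: np.ndarray
    radius: float
    mask_diameter: float  # pixels
    pixel_size: float | None = None


def euler_to_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    return Rotation.from_euler("ZYZ", [rot, tilt, psi], degrees=True).as_matrix()


def matrix_to_euler(m: np.ndarray) -> tuple:
    import warnings

    with warnings.catch_warnings():
        # ZYZ is degenerate at tilt 0/180; scipy's convention (third angle
        # zero) is fine for us but warns
        warnings.simplefilter("ignore", UserWarning)
        rot, tilt, psi = Rotation.from_matrix(m).as_euler("ZYZ", degrees=True)
    return float(rot), float(tilt), float(psi)


def define_subparticle_vector(site, radius: float) -> SubParticleVector:
    """Capsid-frame vector to a sub-particle centre at ``radius`` Angstrom.

    ``site`` may be a CapsomerSite, a SymmetryAxis or a bare 3-vector.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    direction = getattr(site, "position", None)
    if direction is None:
        direction = getattr(site, "direction", site)
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        raise ValueError("site direction must be non-zero")
    return SubParticleVector(direction=direction / norm, radius=float(radius))


def distinct_orbit_ops(vector: SubParticleVector, group: icosa.RotationGroup, tol: float):
    """Indices/operators giving distinct images of the vector (special-position dedup).

    Deduplication is by 3D position with tolerance ``tol`` relative to the
    sub-particle radius, not by operator index: a site on an n-fold axis
    keeps 60/n operators.
    """
    point = vector.point()
    kept: list = []
    positions: list = []
    for i, g in enumerate(group):
        p = g @ point
        if positions and np.min(np.linalg.norm(np.stack(positions) - p, axis=1)) <= tol * vector.radius:
            continue
        kept.append((i, g, p))
        positions.append(p)
    return kept


def expand_subparticles(
    particles: list,
    vector: SubParticleVector,
    group: icosa.RotationGroup,
    align_local_axis: bool = True,
    tol: float = 1e-6,
) -> list:
    """Symmetry-expand particles into sub-particle records.

    One record per particle and per distinct image of the vector under
    the group: 60 for a general position, 20 on a three-fold, 12 on a
    five-fold.  Offsets are the in-plane projection of the rotated
    sub-particle position in pixels (plus the parent origin); ``z_shift``
    is the out-of-plane component in Angstrom, used for per-sub-particle
    defocus adjustment.
    """
    if not particles:
        raise ValueError("particle list is empty")
    if tol <= 0:
        raise ValueError("tol must be positive")
    ops = distinct_orbit_ops(vector, group, tol)
    align = icosa.minimal_rotation_to_z(vector.direction) if align_local_axis else np.eye(3)
    # capsid-frame quantities, shared by all particles
    sym_idx = [i for i, _, _ in ops]
    local_to_capsid = np.stack([g @ align.T for _, g, _ in ops])  # (k,3,3)
    positions = np.stack([p for _, _, p in ops])  # (k,3) Angstrom

    parent_mats = Rotation.from_euler(
        "ZYZ",
        [[p.euler_rot, p.euler_tilt, p.euler_psi] for p in particles],
        degrees=True,
    ).as_matrix()  # (n,3,3)

    lab_pos = np.einsum("nij,kj->nki", parent_mats, positions)  # (n,k,3)
    sub_mats = np.einsum("nij,kjl->nkil", parent_mats, local_to_capsid)
    n, k = lab_pos.shape[:2]
    eulers = Rotation.from_matrix(sub_mats.reshape(n * k, 3, 3)).as_euler(
        "ZYZ", degrees=True
    ).reshape(n, k, 3)

    records = []
    for a, particle in enumerate(particles):
        for b in range(k):
            records.append(
                SubParticleRecord(
                    parent_id=particle.id,
                    sym_index=sym_idx[b],
                    euler_rot=float(eulers[a, b, 0]),
                    euler_tilt=float(eulers[a, b, 1]),
                    euler_psi=float(eulers[a, b, 2]),
                    offset_x=float(particle.origin_x + lab_pos[a, b, 0] / particle.pixel_size),
                    offset_y=float(particle.origin_y + lab_pos[a, b, 1] / particle.pixel_size),
                    defocus_u=particle.defocus_u,
                    defocus_v=particle.defocus_v,
                    z_shift=float(lab_pos[a, b, 2]),
                )
            )
    return records


def adjust_defocus(subparticles: list, z_toward_source_decreases: bool = True) -> list:
    """Apply the per-sub-particle defocus gradient.

    With the default sign convention a sub-particle displaced toward the
    electron source (positive ``z_shift``) is imaged at *smaller* defocus,
    so ``z_shift`` is subtracted from both defocus values; the flag flips
    the sign for packages with the opposite convention.  Over a complete
    orbit the adjustments sum to zero (the orbit centroid is the capsid
    centre).
    """
    sign = -1.0 if z_toward_source_decreases else 1.0
    return [
        replace(s, defocus_u=s.defocus_u + sign * s.z_shift, defocus_v=s.defocus_v + sign * s.z_shift)
        for s in subparticles
    ]


def relax_candidates(orientation: tuple, n: int) -> RelaxationSet:
    """The n orientations related by the local Cn symmetry axis.

    Symmetry relaxation classifies a sub-particle over the n in-plane
    rotations by 360k/n about its local symmetry axis (on z in the
    aligned frame); for a five-fold vertex spike this is the
    "relax_sym C5" candidate set.
    """
    if n < 2:
        raise ValueError("relaxation needs a symmetry order n >= 2")
    base = euler_to_matrix(*orientation)
    candidates = []
    for k in range(n):
        inplane = Rotation.from_euler("z", 360.0 * k / n, degrees=True).as_matrix()
        candidates.append(matrix_to_euler(base @ inplane))
    return RelaxationSet(candidates=candidates, n=n)


def stitch_composite(components: list, pixel_size: float) -> CapsidPointModel:
    """Combine localized reconstructions into a composite capsid model.

    Each component's points are mapped from its local frame back to the
    capsid frame (inverse of the sub-particle alignment, then translation
    to the site) and replicated over the site's orbit.  Where components
    overlap, *later* components take precedence: points of an earlier
    component falling inside the spherical mask of a later one are
    dropped.  Listing the penton before the spike therefore carves the
    spike-mask region out of the penton, emulating the mask subtraction
    used when compositing penton and spike maps.
    """
    if not components:
        raise ValueError("no components to stitch")
    group = icosa.build_icosahedral_group()
    placed = []  # per component: (points list, centres array, mask radius in Angstrom)
    for comp in components:
        if comp.pixel_size is not None and not np.isclose(comp.pixel_size, pixel_size):
            raise ValueError(
                f"component pixel size {comp.pixel_size} != composite pixel size {pixel_size}"
            )
        vec = define_subparticle_vector(comp.site_direction, comp.radius)
        align = icosa.minimal_rotation_to_z(vec.direction)
        ops = distinct_orbit_ops(vec, group, tol=1e-6)
        pts = []
        centres = []
        for _, g, centre in ops:
            local_to_capsid = g @ align.T
            centres.append(centre)
            for p, label in comp.points:
                pts.append((local_to_capsid @ np.asarray(p, float) + centre, label))
        placed.append((pts, np.stack(centres), comp.mask_diameter / 2.0 * pixel_size))

    out = []
    for i, (pts, _, _) in enumerate(placed):
        later = placed[i + 1 :]
        for p, label in pts:
            if any(
                np.min(np.linalg.norm(centres - p, axis=1)) < mask_r
                for _, centres, mask_r in later
            ):
                continue
            out.append((p, label))
    radius = max(c.radius for c in components)
    return CapsidPointModel(points=out, capsid_radius=radius)
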