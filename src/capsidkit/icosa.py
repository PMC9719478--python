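"""Icosahedral rotation group, symmetry axes and orbits.

The 532 (I) point group is generated from one five-fold and one two-fold
generator and closed under multiplication, so the 60 operators are
self-verifying rather than tabulated.  The axis setting places two-fold
axes on the Cartesian x, y and z axes (icosahedron vertices at the cyclic
permutations of (0, ±1, ±phi)); this is the common cryo-EM "I" setting
with a two-fold on z.  ``convert_setting`` re-expresses the group in any
other frame given the rotation between settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PHI = (1.0 + np.sqrt(5.0)) / 2.0

#: Default tolerance for identifying two rotation operators / directions.
DEDUP_TOL = 1e-6

__all__ = [
    "RotationGroup",
    "SymmetryAxis",
    "Orbit",
    "build_icosahedral_group",
    "icosahedron_vertices",
    "symmetry_axes",
    "orbit_of",
    "cyclic_group",
    "write_operators",
]


@dataclass(frozen=True)
class SymmetryAxis:
    """A proper rotation axis of the icosahedral group.

    ``direction`` is a unit vector; antipodal directions describe the same
    axis and only one representative (lexicographically positive) is kept.
    ``fold`` is 2, 3 or 5.
    """

    direction: np.ndarray
    fold: int

    def rotation(self) -> np.ndarray:
        """The rotation by 360/fold degrees about this axis."""
        return _axis_angle(self.direction, 2.0 * np.pi / self.fold)


@dataclass(frozen=True)
class RotationGroup:
    """A finite group of proper rotations given as 3x3 matrices."""

    operators: tuple
    convention_tag: str = "I setting, two-fold axes on x/y/z"

    def __len__(self) -> int:
        return len(self.operators)

    def __iter__(self):
        return iter(self.operators)

    def matrix_stack(self) -> np.ndarray:
        return np.stack(self.operators)

    def validate(self, tol: float = 1e-9) -> None:
        """Raise ``ValueError`` unless this is a closed group of proper rotations."""
        ops = self.matrix_stack()
        dets = np.linalg.det(ops)
        if not np.allclose(dets, 1.0, atol=tol):
            raise ValueError("operators must be proper rotations (det +1)")
        if not _contains(ops, np.eye(3), tol=1e-6):
            raise ValueError("group lacks the identity")
        for a in ops:
            for b in ops:
                if not _contains(ops, a @ b, tol=1e-6):
                    raise ValueError("group is not closed under composition")

    def contains(self, matrix: np.ndarray, tol: float = DEDUP_TOL) -> bool:
        return _contains(self.matrix_stack(), matrix, tol)


@dataclass
class Orbit:
    """Orbit of a point under a rotation group, with its stabilizer order."""

    representative: np.ndarray
    members: list = field(default_factory=list)
    stabilizer_order: int = 1

    def __len__(self) -> int:
        return len(self.members)


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _contains(stack: np.ndarray, matrix: np.ndarray, tol: float) -> bool:
    return bool((np.abs(stack - matrix).max(axis=(1, 2)) < tol).any())


def icosahedron_vertices() -> np.ndarray:
    """The 12 unit vertices: cyclic permutations of (0, ±1, ±phi), normalized."""
    v = []
    for a in (-1.0, 1.0):
        for b in (-PHI, PHI):
            v.extend([(0.0, a, b), (a, b, 0.0), (b, 0.0, a)])
    v = np.array(v)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def build_icosahedral_group() -> RotationGroup:
    """Generate the 60 proper rotations of the icosahedron.

    Closure from a five-fold generator (through a vertex) and the two-fold
    on z; breadth-first multiplication terminates at exactly 60 operators.
    """
    five = _axis_angle(np.array([0.0, 1.0, PHI]), 2.0 * np.pi / 5.0)
    two = _axis_angle(np.array([0.0, 0.0, 1.0]), np.pi)
    ops = [np.eye(3)]
    frontier = [np.eye(3)]
    while frontier:
        nxt = []
        for m in frontier:
            for g in (five, two):
                cand = g @ m
                if not _contains(np.stack(ops), cand, DEDUP_TOL):
                    ops.append(cand)
                    nxt.append(cand)
        frontier = nxt
    if len(ops) != 60:  # pragma: no cover - generator sanity
        raise RuntimeError(f"icosahedral closure produced {len(ops)} operators")
    return RotationGroup(operators=tuple(ops))


def cyclic_group(n: int, axis=(0.0, 0.0, 1.0)) -> RotationGroup:
    """Cn about ``axis`` (needed for local symmetry relaxation)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ops = tuple(_axis_angle(np.asarray(axis, float), 2.0 * np.pi * k / n) for k in range(n))
    return RotationGroup(operators=ops, convention_tag=f"C{n} about {tuple(axis)}")


def _canonical_direction(d: np.ndarray) -> np.ndarray:
    # one representative per antipodal pair: first non-negligible component > 0
    for c in d:
        if abs(c) > 1e-9:
            return d if c > 0 else -d
    raise ValueError("zero direction")


def symmetry_axes(group: RotationGroup) -> list:
    """Extract the 6 five-fold, 10 three-fold and 15 two-fold axes.

    Each non-identity operator's rotation axis is the eigenvector for
    eigenvalue +1; the fold is recovered from the rotation angle.  Raises
    if the group is malformed (wrong censuses signal non-closure).
    """
    found: dict = {2: [], 3: [], 5: []}
    for op in group:
        tr = np.trace(op)
        if np.isclose(tr, 3.0, atol=1e-9):
            continue  # identity
        angle = np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))
        # icosahedral rotation angles: 180 (2-fold), 120 (3-fold), 72/144 (5-fold)
        if np.isclose(angle, np.pi, atol=1e-9):
            fold = 2
        elif np.isclose(angle, 2.0 * np.pi / 3.0, atol=1e-9):
            fold = 3
        elif np.isclose(angle, 2.0 * np.pi / 5.0, atol=1e-9) or np.isclose(
            angle, 4.0 * np.pi / 5.0, atol=1e-9
        ):
            fold = 5
        else:
            raise ValueError("operator with non-icosahedral rotation angle")
        w, vec = np.linalg.eigh((op + op.T) / 2.0)
        direction = _canonical_direction(vec[:, np.argmax(w)])
        bucket = found[fold]
        if not any(abs(float(np.dot(direction, d))) > 1.0 - 1e-9 for d in bucket):
            bucket.append(direction)
    axes = [
        SymmetryAxis(direction=d, fold=fold) for fold, ds in found.items() for d in ds
    ]
    out = sorted(axes, key=lambda a: (a.fold, tuple(np.round(a.direction, 6))))
    census = {f: sum(1 for a in out if a.fold == f) for f in (2, 3, 5)}
    if census != {2: 15, 3: 10, 5: 6}:
        raise ValueError(f"axis census {census} != {{2:15, 3:10, 5:6}}; group malformed")
    return out


def axes_by_fold(axes: list, fold: int) -> np.ndarray:
    return np.stack([a.direction for a in axes if a.fold == fold])


def orbit_of(point: np.ndarray, group: RotationGroup, tol: float = DEDUP_TOL) -> Orbit:
    """Orbit of a unit vector under the group, deduplicated within ``tol``.

    ``tol`` is relative to the (unit) vector length.  The orbit-stabilizer
    relation |orbit| * stabilizer = 60 holds exactly after deduplication.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    p = np.asarray(point, dtype=float)
    n = np.linalg.norm(p)
    if n < 1e-12:
        raise ValueError("cannot take the orbit of the zero vector")
    p = p / n
    images = group.matrix_stack() @ p
    members = _dedup_rows(images, tol)
    order = len(group)
    if order % len(members):  # pragma: no cover - tol pathology guard
        raise ValueError("orbit size does not divide the group order; tol unsuitable")
    return Orbit(representative=p, members=list(members), stabilizer_order=order // len(members))


def _dedup_rows(rows: np.ndarray, tol: float) -> np.ndarray:
    kept: list = []
    for r in rows:
        if not kept or np.min(np.linalg.norm(np.stack(kept) - r, axis=1)) > tol:
            kept.append(r)
    return np.stack(kept)


def minimal_rotation_to_z(direction: np.ndarray) -> np.ndarray:
    """The minimal-angle rotation taking ``direction`` onto +z.

    For a direction already on -z the rotation is 180 degrees about x
    (documented tie-break).  Used to align local symmetry axes.
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(d, z))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return _axis_angle(np.array([1.0, 0.0, 0.0]), np.pi)
    axis = np.cross(d, z)
    return _axis_angle(axis, np.arccos(np.clip(c, -1.0, 1.0)))


def write_operators(group: RotationGroup, path) -> None:
    """Export the operators as a whitespace-delimited 60x9 text matrix."""
    flat = group.matrix_stack().reshape(len(group), 9)
    np.savetxt(path, flat, fmt="%.12f")


def read_operators(path) -> RotationGroup:
    flat = np.loadtxt(path)
    ops = tuple(row.reshape(3, 3) for row in np.atleast_2d(flat))
    return RotationGroup(operators=ops, convention_tag="loaded from file")
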