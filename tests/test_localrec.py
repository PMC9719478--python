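"""Sub-particle expansion, defocus adjustment, relaxation and stitching."""

import numpy as np
import pytest

from capsidkit import icosa, localrec, synth


@pytest.fixture(scope="module")
def small_particles():
    return synth.gen_particle_table(11, seed=5).particles


def _axis(axes, fold):
    return icosa.axes_by_fold(axes, fold)[0]


def test_vector_definition(axes):
    five = _axis(axes, 5)
    v = localrec.define_subparticle_vector(five, 315.0)
    assert np.isclose(np.linalg.norm(v.direction), 1.0)
    assert np.allclose(v.point(), five * 315.0)
    with pytest.raises(ValueError):
        localrec.define_subparticle_vector(five, 0.0)
    with pytest.raises(ValueError):
        localrec.define_subparticle_vector(np.zeros(3), 315.0)


@pytest.mark.parametrize("site,per_capsid", [("generic", 60), ("threefold", 20), ("fivefold", 12)])
def test_count_law(group, axes, small_particles, site, per_capsid):
    direction = {
        "generic": np.array([0.123, 0.456, 0.789]),
        "threefold": _axis(axes, 3),
        "fivefold": _axis(axes, 5),
    }[site]
    vec = localrec.define_subparticle_vector(direction, 315.0)
    subs = localrec.expand_subparticles(small_particles, vec, group)
    assert len(subs) == len(small_particles) * per_capsid


def test_identity_particle_reproduces_orbit(group):
    p = localrec.ParticleRecord(id="p0", euler_rot=0, euler_tilt=0, euler_psi=0, pixel_size=1.0)
    direction = np.array([0.3, -0.5, 0.81])
    direction /= np.linalg.norm(direction)
    vec = localrec.define_subparticle_vector(direction, 100.0)
    subs = localrec.expand_subparticles([p], vec, group)
    got = sorted(
        (round(s.offset_x, 6), round(s.offset_y, 6), round(s.z_shift, 6)) for s in subs
    )
    orbit = icosa.orbit_of(direction, group)
    expected = sorted(
        (round(m[0] * 100, 6), round(m[1] * 100, 6), round(m[2] * 100, 6)) for m in orbit.members
    )
    assert got == expected


def test_round_trip_offsets_and_zshift(group, small_particles):
    vec = localrec.define_subparticle_vector(np.array([0.2, 0.3, 0.93]), 315.0)
    subs = localrec.expand_subparticles(small_particles, vec, group)
    by_parent = {p.id: p for p in small_particles}
    for s in subs[:50]:
        p = by_parent[s.parent_id]
        pos = p.matrix() @ (group.operators[s.sym_index] @ vec.point())
        assert s.offset_x == pytest.approx(p.origin_x + pos[0] / p.pixel_size, abs=1e-9)
        assert s.offset_y == pytest.approx(p.origin_y + pos[1] / p.pixel_size, abs=1e-9)
        assert s.z_shift == pytest.approx(pos[2], abs=1e-9)


def test_orientation_places_local_axis_on_z(group, small_particles):
    """Sub-particle orientation maps local +z to the rotated site direction."""
    direction = np.array([0.123, 0.456, 0.789])
    direction /= np.linalg.norm(direction)
    vec = localrec.define_subparticle_vector(direction, 315.0)
    subs = localrec.expand_subparticles(small_particles, vec, group)
    by_parent = {p.id: p for p in small_particles}
    z = np.array([0.0, 0.0, 1.0])
    for s in subs[:40]:
        p = by_parent[s.parent_id]
        m = localrec.euler_to_matrix(s.euler_rot, s.euler_tilt, s.euler_psi)
        expected = p.matrix() @ (group.operators[s.sym_index] @ direction)
        assert np.allclose(m @ z, expected, atol=1e-9)


def test_expansion_commutes_with_global_rotation(group, small_particles):
    """A global rotation permutes sub-particle 3D positions but preserves the set."""
    from scipy.spatial.transform import Rotation

    vec = localrec.define_subparticle_vector(np.array([0.9, 0.1, 0.42]), 200.0)
    g17 = group.operators[17]

    def positions(particles):
        subs = localrec.expand_subparticles(particles, vec, group)
        by_parent = {p.id: p for p in particles}
        out = []
        for s in subs:
            p = by_parent[s.parent_id]
            out.append(p.matrix() @ (group.operators[s.sym_index] @ vec.point()))
        return out

    rotated = []
    for p in small_particles[:3]:
        m = p.matrix() @ g17
        rot, tilt, psi = localrec.matrix_to_euler(m)
        rotated.append(
            localrec.ParticleRecord(
                id=p.id, euler_rot=rot, euler_tilt=tilt, euler_psi=psi,
                origin_x=p.origin_x, origin_y=p.origin_y, pixel_size=p.pixel_size,
            )
        )
    base = positions(list(small_particles[:3]))
    perm = positions(rotated)
    for q in perm:
        assert min(np.linalg.norm(np.stack(base) - q, axis=1)) < 1e-6


def test_defocus_adjustment_sums_to_zero_over_orbit(group):
    p = localrec.ParticleRecord(
        id="p0", euler_rot=31.0, euler_tilt=75.0, euler_psi=-12.0,
        defocus_u=15000.0, defocus_v=15000.0, pixel_size=1.24,
    )
    vec = localrec.define_subparticle_vector(np.array([0.5, 0.5, 0.707]), 315.0)
    subs = localrec.expand_subparticles([p], vec, group)
    adjusted = localrec.adjust_defocus(subs)
    total = sum(s.defocus_u - 15000.0 for s in adjusted)
    assert abs(total) < 1e-6
    # zero z-shift leaves defocus unchanged; sign convention flips symmetric
    flat = [s for s in subs if abs(s.z_shift) < 1e-9]
    for s in localrec.adjust_defocus(flat):
        assert s.defocus_u == pytest.approx(15000.0)
    other = localrec.adjust_defocus(subs, z_toward_source_decreases=False)
    for a, b in zip(adjusted, other):
        assert (a.defocus_u - 15000.0) == pytest.approx(-(b.defocus_u - 15000.0))


def test_relax_candidates_identity_case():
    rs = localrec.relax_candidates((0.0, 0.0, 0.0), 5)
    # at zero tilt the in-plane angle is rot + psi (ZYZ degeneracy)
    inplane = sorted((c[0] + c[2]) % 360 for c in rs.candidates)
    assert np.allclose(inplane, [0.0, 72.0, 144.0, 216.0, 288.0], atol=1e-9)


def test_relax_candidates_closure_and_cosets():
    rs = localrec.relax_candidates((10.0, 20.0, 30.0), 5)
    assert rs.n == 5 and len(rs.candidates) == 5
    mats = [localrec.euler_to_matrix(*c) for c in rs.candidates]
    c5 = localrec.euler_to_matrix(0.0, 0.0, 72.0)
    for m in mats:
        assert any(np.allclose(m @ c5, other, atol=1e-9) for other in mats)
    # orientations differing by a C5 rotation yield the same candidate set
    shifted = localrec.matrix_to_euler(mats[0] @ c5)
    rs2 = localrec.relax_candidates(shifted, 5)
    mats2 = [localrec.euler_to_matrix(*c) for c in rs2.candidates]
    for m in mats2:
        assert any(np.allclose(m, other, atol=1e-9) for other in mats)


def test_relax_candidates_n2_and_error():
    rs = localrec.relax_candidates((5.0, 40.0, 10.0), 2)
    m0, m1 = (localrec.euler_to_matrix(*c) for c in rs.candidates)
    angle = np.degrees(
        np.arccos(np.clip((np.trace(m0.T @ m1) - 1) / 2, -1, 1))
    )
    assert angle == pytest.approx(180.0)
    with pytest.raises(ValueError):
        localrec.relax_candidates((0.0, 0.0, 0.0), 1)


def test_stitch_replicates_threefold_site_20x(axes):
    three = _axis(axes, 3)
    comp = localrec.CompositeComponent(
        points=[(np.array([2.0, 1.0, 3.0]), "T3")],
        site_direction=three, radius=300.0, mask_diameter=80.0,
    )
    model = localrec.stitch_composite([comp], pixel_size=1.24)
    assert len(model.points) == 20


def test_stitch_mask_precedence_spike_over_penton(axes):
    five = _axis(axes, 5)
    penton = localrec.CompositeComponent(
        points=[(np.array([0.0, 0.0, 5.0]), "PEN"), (np.array([0.0, 0.0, -80.0]), "PEN")],
        site_direction=five, radius=300.0, mask_diameter=80.0,
    )
    spike = localrec.CompositeComponent(
        points=[(np.array([0.0, 0.0, 0.0]), "SPK")],
        site_direction=five, radius=315.0, mask_diameter=100.0,
    )
    model = localrec.stitch_composite([penton, spike], pixel_size=1.24)
    labels = [l for _, l in model.points]
    # penton points inside the later spike mask are carved away
    assert labels.count("SPK") == 12
    assert labels.count("PEN") == 12


def test_stitch_round_trip_recovers_positions(axes):
    three = _axis(axes, 3)
    align = icosa.minimal_rotation_to_z(three)
    originals = [three * 300.0 + off for off in (np.array([4.0, -2.0, 3.0]), np.array([0.0, 7.0, -1.0]))]
    local = [(align @ (p - three * 300.0), "X") for p in originals]
    model = localrec.stitch_composite(
        [localrec.CompositeComponent(local, three, 300.0, 80.0)], pixel_size=1.24
    )
    got = np.array([p for p, _ in model.points])
    for orig in originals:
        assert np.min(np.linalg.norm(got - orig, axis=1)) < 1e-6


def test_stitch_rejects_inconsistent_pixel_size(axes):
    comp = localrec.CompositeComponent(
        points=[(np.zeros(3), "X")], site_direction=_axis(axes, 5),
        radius=300.0, mask_diameter=80.0, pixel_size=1.1,
    )
    with pytest.raises(ValueError):
        localrec.stitch_composite([comp], pixel_size=1.24)
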