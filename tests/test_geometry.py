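import numpy as np
import pytest

from torsionnet.geometry import (
    DihedralTopology,
    MolecularConformer,
    UndefinedTorsionError,
    XYZParseError,
    detect_clash,
    measure_all_dihedrals,
    measure_dihedral,
    read_xyz,
    set_all_dihedrals,
    set_dihedral,
    write_xyz,
    _rotation_matrix,
    _torsion_from_points,
)


# -- XYZ I/O ------------------------------------------------------------------


def test_read_xyz_single_atom(tmp_path):
    f = tmp_path / "one.xyz"
    f.write_text("1\n\nC 0.0 0.0 0.0\n")
    conf = read_xyz(f)
    assert conf.elements == ["C"]
    np.testing.assert_array_equal(conf.coords, [[0.0, 0.0, 0.0]])


def test_xyz_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    conf = MolecularConformer(["C", "N", "O", "H"], rng.normal(size=(4, 3)))
    f = tmp_path / "rt.xyz"
    write_xyz(conf, f, comment="round trip")
    back = read_xyz(f)
    assert back.elements == conf.elements
    np.testing.assert_allclose(back.coords, conf.coords, atol=1e-6)


def test_read_xyz_matches_reference_parse(tmp_path):
    # independently written line-by-line parse of a random 10-atom file
    rng = np.random.default_rng(1)
    coords = rng.uniform(-5, 5, size=(10, 3))
    lines = ["10", "random fixture"]
    for (x, y, z) in coords:
        lines.append(f"C {x:.8f} {y:.8f} {z:.8f}")
    f = tmp_path / "ten.xyz"
    f.write_text("\n".join(lines) + "\n")

    ref_elements, ref_coords = [], []
    for line in f.read_text().splitlines()[2:]:
        parts = line.split()
        ref_elements.append(parts[0])
        ref_coords.append([float(p) for p in parts[1:4]])

    conf = read_xyz(f)
    assert conf.n_atoms == 10
    assert conf.elements == ref_elements
    np.testing.assert_allclose(conf.coords, np.asarray(ref_coords), atol=0)


@pytest.mark.parametrize(
    "content, fragment",
    [
        ("x\n\nC 0 0 0\n", "line 1"),          # malformed count
        ("1\n\nC a b c\n", "line 3"),          # non-numeric coordinate
        ("3\n\nC 0 0 0\nC 1 0 0\n", "expected 3 atom rows"),  # row mismatch
    ],
)
def test_read_xyz_errors_name_location(tmp_path, content, fragment):
    f = tmp_path / "bad.xyz"
    f.write_text(content)
    with pytest.raises(XYZParseError, match=fragment):
        read_xyz(f)


# -- torsion measurement ------------------------------------------------------


def _proj_torsion(pi, pj, pk, pl):
    """Independent oracle: signed angle between the projections of the
    i- and l-side bond vectors onto the plane perpendicular to j-k."""
    u = pk - pj
    u = u / np.linalg.norm(u)
    a = pi - pj
    b = pl - pk
    ap = a - np.dot(a, u) * u
    bp = b - np.dot(b, u) * u
    x = np.dot(ap, bp)
    y = np.dot(np.cross(ap, bp), u)
    return np.degrees(np.arctan2(y, x)) % 360.0


def test_planar_cis_is_zero():
    pts = np.array([[1.0, 1, 0], [0, 0, 0], [0, 0, 1], [1, 0.5, 1]])
    # i and l on the same side of the j-k (z) axis
    pts[3] = [1.0, 1.0, 1.0]
    assert _torsion_from_points(*pts) == pytest.approx(0.0, abs=1e-10)


def test_planar_trans_is_180():
    pts = np.array([[1.0, 0, 0], [0, 0, 0], [0, 0, 1], [-1.0, 0, 1]])
    assert _torsion_from_points(*pts) == pytest.approx(180.0, abs=1e-10)


def test_measure_matches_projection_oracle():
    rng = np.random.default_rng(2)
    checked = 0
    while checked < 100:
        pts = rng.normal(size=(4, 3))
        try:
            got = _torsion_from_points(*pts)
        except UndefinedTorsionError:
            continue
        want = _proj_torsion(*pts)
        assert abs((got - want + 180) % 360 - 180) < 1e-8
        checked += 1


def test_collinear_torsion_raises():
    pts = np.array([[0.0, 0, -1], [0, 0, 0], [0, 0, 1], [1.0, 0, 1]])
    with pytest.raises(UndefinedTorsionError):
        _torsion_from_points(*pts)


# -- setting torsions ---------------------------------------------------------


def test_set_to_current_is_identity(chain):
    conf, topo = chain
    current = measure_dihedral(conf, topo, 1)
    out = set_dihedral(conf, topo, 1, current)
    np.testing.assert_allclose(out.coords, conf.coords, atol=1e-9)


def test_set_then_measure_round_trip(chain):
    conf, topo = chain
    rng = np.random.default_rng(3)
    for target in rng.uniform(0, 360, size=50):
        d = int(rng.integers(topo.n_dihedrals))
        out = set_dihedral(conf, topo, d, target)
        assert measure_dihedral(out, topo, d) == pytest.approx(target, abs=1e-6)


def test_set_dihedral_matches_rotation_matrix_oracle():
    # 4-atom chain with unit geometry: explicit axis-angle rotation of atom l
    coords = np.array([[1.0, 0, 0], [0, 0, 0], [0, 0, 1], [1.0, 0, 1]])
    topo = DihedralTopology(
        n_atoms=4,
        bonds={(0, 1), (1, 2), (2, 3)},
        dihedrals=[(0, 1, 2, 3)],
        rigid_fragments=[[0, 1], [2, 3]],
    )
    conf = MolecularConformer(["C"] * 4, coords)
    out = set_dihedral(conf, topo, 0, 90.0)
    # current torsion is 0 (cis); rotating l by +90 deg about the j->k (+z) axis
    rot = _rotation_matrix(np.array([0.0, 0, 1]), np.radians(90.0))
    expected_l = rot @ (coords[3] - coords[2]) + coords[2]
    np.testing.assert_allclose(out.coords[3], expected_l, atol=1e-10)
    np.testing.assert_allclose(out.coords[:3], coords[:3], atol=0)


def test_rigid_fragments_and_spectators_preserved(chain):
    conf, topo = chain
    out = set_all_dihedrals(conf, topo, [33.0, 155.0, 287.0])
    for frag in topo.rigid_fragments:
        sub_before = conf.coords[frag]
        sub_after = out.coords[frag]
        d_before = np.linalg.norm(sub_before[:, None] - sub_before[None, :], axis=-1)
        d_after = np.linalg.norm(sub_after[:, None] - sub_after[None, :], axis=-1)
        np.testing.assert_allclose(d_after, d_before, atol=1e-9)
    # atoms outside the moving set of the last dihedral unmoved by it
    before_last = set_all_dihedrals(conf, topo, [33.0, 155.0, 0.0])
    static = sorted(set(range(conf.n_atoms)) - topo.moving_sets[2])
    np.testing.assert_allclose(out.coords[static], before_last.coords[static],
                               atol=1e-9)


def test_set_dihedral_reversible(chain):
    conf, topo = chain
    original = measure_dihedral(conf, topo, 0)
    there = set_dihedral(conf, topo, 0, 123.456)
    back = set_dihedral(there, topo, 0, original)
    np.testing.assert_allclose(back.coords, conf.coords, atol=1e-6)


def test_set_dihedral_commutes_on_tree_topology(chain):
    conf, topo = chain
    ab = set_dihedral(set_dihedral(conf, topo, 0, 70.0), topo, 2, 210.0)
    ba = set_dihedral(set_dihedral(conf, topo, 2, 210.0), topo, 0, 70.0)
    np.testing.assert_allclose(ab.coords, ba.coords, atol=1e-8)


def test_branched_hub_moving_sets_disjoint(branched):
    conf, topo = branched
    assert topo.n_dihedrals == 3
    for a in range(3):
        for b in range(a + 1, 3):
            assert not (topo.moving_sets[a] & topo.moving_sets[b])
    out = set_all_dihedrals(conf, topo, [45.0, 120.0, 300.0])
    got = measure_all_dihedrals(out, topo).angles
    np.testing.assert_allclose(got, [45.0, 120.0, 300.0], atol=1e-6)


# -- clash detection ----------------------------------------------------------


def _two_fragment_rod():
    """Six-atom rod: fragments more than 4 bonds apart at controllable distance."""
    topo = DihedralTopology(
        n_atoms=6,
        bonds={(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)},
        dihedrals=[],
        rigid_fragments=[[0, 1, 2], [3, 4, 5]],
    )
    return topo


def _rod_conformer(end_separation):
    # atoms 0 and 5 are 5 bonds apart and in different fragments: eligible
    coords = np.array([
        [0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0],
        [2.0, 3.0, 0], [1.0, 3.0, 0],
        [0.0, end_separation, 0.0],
    ])
    return MolecularConformer(["C"] * 6, coords)


def test_clash_below_threshold():
    topo = _two_fragment_rod()
    assert detect_clash(_rod_conformer(2.0), topo, threshold=2.1) is True


def test_no_clash_at_exact_threshold():
    topo = _two_fragment_rod()
    assert detect_clash(_rod_conformer(2.1), topo, threshold=2.1) is False


def test_clash_matches_brute_force(branched):
    conf, topo = branched
    rng = np.random.default_rng(4)
    eligible = {tuple(p) for p in topo.clash_eligible_pairs().tolist()}
    for _ in range(25):
        c = set_all_dihedrals(conf, topo, rng.uniform(0, 360, 3))
        threshold = rng.uniform(1.5, 4.0)
        brute = False
        for a in range(c.n_atoms):
            for b in range(a + 1, c.n_atoms):
                if (a, b) in eligible:
                    if np.linalg.norm(c.coords[a] - c.coords[b]) < threshold:
                        brute = True
        assert detect_clash(c, topo, threshold) == brute


def test_clash_invariant_under_rigid_motion(branched):
    conf, topo = branched
    rng = np.random.default_rng(5)
    c = set_all_dihedrals(conf, topo, rng.uniform(0, 360, 3))
    base = detect_clash(c, topo, 3.0)
    rot = _rotation_matrix(np.array([1.0, 2.0, 2.0]) / 3.0, 1.234)
    moved = MolecularConformer(
        list(c.elements), c.coords @ rot.T + np.array([10.0, -3.0, 7.0])
    )
    assert detect_clash(moved, topo, 3.0) == base
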