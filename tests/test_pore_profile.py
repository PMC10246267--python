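import numpy as np
import pytest

from navgate.pore_profile import (Structure, find_constrictions,
                                  lining_residues, load_structure,
                                  map_residues, trace_pore)


def _ring(radial, z, n=8, res_start=1, name="LEU"):
    angles = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    coords = np.column_stack([radial * np.cos(angles),
                              radial * np.sin(angles),
                              np.full(n, float(z))])
    res_ids = np.arange(res_start, res_start + n)
    return coords, res_ids, np.full(n, name)


def _structure(ring_specs, vdw=1.7):
    """ring_specs: list of (radial, z, res_start, res_name)."""
    coords, res_ids, res_names = [], [], []
    for radial, z, res_start, name in ring_specs:
        c, r, nm = _ring(radial, z, res_start=res_start, name=name)
        coords.append(c)
        res_ids.append(r)
        res_names.append(nm)
    coords = np.vstack(coords)
    res_ids = np.concatenate(res_ids)
    res_names = np.concatenate(res_names)
    n = len(coords)
    return Structure(coords=coords, radii=np.full(n, vdw),
                     elements=np.full(n, "C"), res_names=res_names,
                     res_ids=res_ids, chain_ids=np.full(n, "A"),
                     atom_names=np.full(n, "CB"))


def _cylinder(radial=5.0, z_lo=-12.0, z_hi=12.0, spacing=2.0, res_start=100):
    specs = []
    rs = res_start
    for z in np.arange(z_lo, z_hi + spacing / 2, spacing):
        specs.append((radial, z, rs, "ALA"))
        rs += 8
    return specs


def test_single_ring_slice_radius():
    # ring of 8 atoms (vdW 1.7 A) at radial distance 5.0 -> radius 3.3
    s = _structure(_cylinder())
    profile = trace_pore(s, (0.0, 0.0, 0.0), n_starts=8, escape_radius=6.0)
    at_zero = profile.radius[np.argmin(np.abs(profile.z))]
    assert at_zero == pytest.approx(3.3, abs=0.01)


def test_two_stacked_rings_give_two_minima():
    # constriction rings radial 4.0 and 4.5, 5.4 A apart -> minima 2.3, 2.8
    specs = _cylinder(res_start=100)
    specs += [(4.0, -2.7, 1, "ILE"), (4.5, 2.7, 9, "VAL")]
    s = _structure(specs)
    profile = trace_pore(s, (0.0, 0.0, 0.0), n_starts=8, escape_radius=6.0)
    report = find_constrictions(profile, prominence=0.3, max_separation=8.0)
    assert len(report.minima) == 2
    radii = sorted(m.radius for m in report.minima)
    assert radii[0] == pytest.approx(2.3, abs=0.02)
    assert radii[1] == pytest.approx(2.8, abs=0.02)
    assert len(report.pairs) == 1
    a, b = report.pairs[0]
    assert b.z - a.z == pytest.approx(5.4, abs=0.3)


def test_monotone_funnel_has_no_minima():
    specs = []
    rs = 1
    for k, z in enumerate(np.arange(-10.0, 10.1, 2.0)):
        specs.append((4.0 + 0.35 * k, z, rs, "GLY"))
        rs += 8
    s = _structure(specs)
    profile = trace_pore(s, (0.0, 0.0, -9.0), n_starts=8, escape_radius=9.0)
    # restrict to the funnel interior (the trace runs past the open mouth)
    inside = (profile.z >= -10.0) & (profile.z <= 10.0)
    profile.z = profile.z[inside]
    profile.radius = profile.radius[inside]
    profile.centers = profile.centers[inside]
    report = find_constrictions(profile)
    assert report.minima == []
    assert report.pairs == []


def test_lining_residues_of_constructed_rings():
    specs = _cylinder(res_start=100)
    specs += [(4.0, -2.7, 1, "ILE"), (4.5, 2.7, 9, "VAL")]
    s = _structure(specs)
    profile = trace_pore(s, (0.0, 0.0, 0.0), n_starts=8, escape_radius=6.0)
    report = find_constrictions(profile)
    lower = min(report.minima, key=lambda m: m.z)
    residues = lining_residues(s, lower, contact_margin=1.0)
    ids = {rid for _, rid, _, _ in residues}
    assert ids == set(range(1, 9))             # exactly the ILE ring
    names = {name for _, _, name, _ in residues}
    assert names == {"ILE"}


def test_seed_inside_atom_error():
    s = _structure(_cylinder())
    with pytest.raises(ValueError, match="inside an atom"):
        trace_pore(s, (5.0, 0.0, 0.0))


def test_profile_too_short_error():
    s = _structure(_cylinder())
    profile = trace_pore(s, (0.0, 0.0, 0.0), n_starts=4, escape_radius=6.0)
    profile.z = profile.z[:10]
    profile.radius = profile.radius[:10]
    with pytest.raises(ValueError, match="too short"):
        find_constrictions(profile)


def test_maximality_against_random_probes():
    rng = np.random.default_rng(3)
    s = _structure(_cylinder())
    profile = trace_pore(s, (0.0, 0.0, 0.0), n_starts=8, escape_radius=6.0)
    for _ in range(200):
        k = rng.integers(len(profile.z))
        xy = rng.uniform(-1.5, 1.5, size=2)
        point = np.array([xy[0], xy[1], profile.z[k]])
        d = np.linalg.norm(s.coords - point, axis=1) - s.radii
        probe_radius = d.min()
        assert probe_radius <= profile.radius[k] + 1e-6


def test_rigid_motion_invariance():
    specs = _cylinder(res_start=100)
    specs += [(4.0, -2.7, 1, "ILE"), (4.5, 2.7, 9, "VAL")]
    s = _structure(specs)
    base = trace_pore(s, (0.0, 0.0, 0.0), n_starts=8, escape_radius=6.0)

    # rotate 30 deg about x, then translate
    angle = np.pi / 6
    rot = np.array([[1, 0, 0],
                    [0, np.cos(angle), -np.sin(angle)],
                    [0, np.sin(angle), np.cos(angle)]])
    shift = np.array([3.0, -2.0, 7.0])
    moved = s.transformed(rotation=rot, translation=shift)
    new_axis = rot @ np.array([0.0, 0.0, 1.0])
    new_seed = rot @ np.zeros(3) + shift
    prof2 = trace_pore(moved, new_seed, axis=new_axis, n_starts=8,
                       escape_radius=6.0)

    # compare radius at matching axial offsets from the seed slice
    mid1 = np.argmin(np.abs(base.z))
    mid2 = np.argmin(np.abs(prof2.z - prof2.z[len(prof2.z) // 2]))
    n = min(mid1, 20, len(prof2.z) // 2)
    r1 = base.radius[mid1 - n: mid1 + n]
    z2_seed = new_seed @ (new_axis / np.linalg.norm(new_axis))
    mid2 = np.argmin(np.abs(prof2.z - z2_seed))
    r2 = prof2.radius[mid2 - n: mid2 + n]
    assert np.abs(r1 - r2).max() < 0.05


# ---------------------------------------------------------------------------
# file loading
# ---------------------------------------------------------------------------

PDB_TEMPLATE = (
    "ATOM  {serial:>5d}  {name:<3s}{res:>4s} A{resid:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}\n")


def _write_pdb(path, atoms):
    lines = []
    for k, (name, res, resid, xyz, element) in enumerate(atoms, start=1):
        lines.append(PDB_TEMPLATE.format(serial=k, name=name, res=res,
                                         resid=resid, x=xyz[0], y=xyz[1],
                                         z=xyz[2], element=element))
    path.write_text("".join(lines) + "END\n")


def test_load_small_pdb(tmp_path):
    path = tmp_path / "mini.pdb"
    atoms = [("CB", "ALA", i + 1,
              (5 * np.cos(i * np.pi / 4), 5 * np.sin(i * np.pi / 4), 0.0), "C")
             for i in range(8)]
    _write_pdb(path, atoms)
    s = load_structure(path)
    assert s.n_atoms == 8
    assert np.allclose(s.radii, 1.7)           # Bondi carbon


def test_load_drops_hydrogens_and_water(tmp_path):
    path = tmp_path / "mix.pdb"
    atoms = [("CB", "ALA", 1, (0.0, 0.0, 0.0), "C"),
             ("H", "ALA", 1, (1.0, 0.0, 0.0), "H"),
             ("O", "HOH", 2, (9.0, 9.0, 9.0), "O")]
    _write_pdb(path, atoms)
    s = load_structure(path)
    assert s.n_atoms == 1


def test_unknown_element_error(tmp_path):
    path = tmp_path / "weird.pdb"
    _write_pdb(path, [("XX", "UNK", 1, (0.0, 0.0, 0.0), "X")])
    with pytest.raises(ValueError, match="unknown element"):
        load_structure(path)
    # with an override it loads
    s = load_structure(path, radius_overrides={"X": 2.0})
    assert s.radii[0] == 2.0


# ---------------------------------------------------------------------------
# residue mapping
# ---------------------------------------------------------------------------

S6_LIKE = "FLALFQVATFKGWMDIMYAAVDSR"


def test_map_identity():
    mapping, identity, warn = map_residues(S6_LIKE, S6_LIKE, [3, 10, 24])
    assert mapping == {3: 3, 10: 10, 24: 24}
    assert identity == pytest.approx(1.0)
    assert warn == []


def test_map_with_author_numbering_offsets():
    # same sequence, numbered from 1453 in the query and 1284 in the ref
    mapping, identity, _ = map_residues(S6_LIKE, S6_LIKE, [1284, 1288],
                                        ref_start=1284, query_start=1453)
    assert mapping == {1284: 1453, 1288: 1457}


def test_map_through_gap_reports_unmapped():
    ref = S6_LIKE
    query = S6_LIKE[:8] + S6_LIKE[12:]          # 4-residue deletion
    mapping, identity, _ = map_residues(query, ref, [5, 10, 20])
    assert mapping[5] == 5
    assert mapping[10] is None                  # deleted region
    assert mapping[20] == 16


def test_map_low_identity_warning():
    other = "WWWWWWWWWWWWWWWWGGGGGGGG"
    with pytest.warns(UserWarning):
        mapping, identity, warn = map_residues(other, S6_LIKE, [1])
    assert warn


def test_map_rejects_short_sequences():
    with pytest.raises(ValueError, match="15"):
        map_residues("ACDEFG", S6_LIKE, [1])
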