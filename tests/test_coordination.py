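"""Metal coordination spheres, substitutions, distances, salt bridges."""
import numpy as np
import pytest

from flexmd.errors import SelectionError
from flexmd.model import Atom, Topology, Trajectory
from flexmd.coordination import (
    CoordinationRecord,
    detect_salt_bridges,
    detect_substitutions,
    metal_coordination,
    pair_distance_series,
)


def _traj(atoms, coords, box=(90.0, 90.0, 90.0)):
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[0]
    times = np.arange(n, dtype=float)
    boxes = np.tile(box, (n, 1))
    return Trajectory(Topology(atoms), times, coords, boxes)


@pytest.fixture
def zn_with_donors():
    atoms = [
        Atom(1, "ZN", "ZN", 100, "Z", "Zn", 2),
        Atom(2, "OD1", "ASP", 34, "A", "O", 0),
        Atom(3, "SG", "CYS", 57, "A", "S", 0),
        Atom(4, "OE1", "GLU", 28, "A", "O", 0),
    ]
    coords = [
        [0.0, 0.0, 0.0],
        [2.0, 0.0, 0.0],  # D34:OD1 at 2.0 A
        [0.0, 2.3, 0.0],  # C57:SG at 2.3 A
        [0.0, 0.0, 3.5],  # E28:OE1 at 3.5 A
    ]
    return _traj(atoms, coords)


def test_coordination_sphere_by_manual_distances(zn_with_donors):
    (rec,) = [
        r for r in metal_coordination(zn_with_donors, [0], cutoff=2.8)
    ]
    assert rec.ligands == frozenset(
        {(34, "ASP", "OD1"), (57, "CYS", "SG")}
    )


def test_no_donor_within_cutoff_gives_empty_set(zn_with_donors):
    (rec,) = metal_coordination(zn_with_donors, [0], cutoff=1.0)
    assert rec.ligands == frozenset()


def test_cutoff_boundary_is_inclusive(zn_with_donors):
    (rec,) = metal_coordination(zn_with_donors, [0], cutoff=2.0)
    assert (34, "ASP", "OD1") in rec.ligands


def test_coordination_monotone_in_cutoff(zn_with_donors):
    small = metal_coordination(zn_with_donors, [0], cutoff=2.2)[0].ligands
    large = metal_coordination(zn_with_donors, [0], cutoff=3.6)[0].ligands
    assert small <= large


def test_coordination_respects_minimum_image():
    atoms = [
        Atom(1, "ZN", "ZN", 100, "Z", "Zn", 2),
        Atom(2, "OD1", "ASP", 34, "A", "O", 0),
    ]
    # donor sits across the z boundary: true separation is 2.0 A
    coords = [[0.0, 0.0, 44.0], [0.0, 0.0, -44.0]]
    traj = _traj(atoms, coords, box=(90.0, 90.0, 90.0))
    (rec,) = metal_coordination(traj, [0], cutoff=2.8)
    assert rec.ligands == frozenset({(34, "ASP", "OD1")})


def test_unknown_metal_index_raises(zn_with_donors):
    with pytest.raises(SelectionError, match="metal"):
        metal_coordination(zn_with_donors, [99])


# ---------------------------------------------------------------------------
# substitutions
# ---------------------------------------------------------------------------

def _records(compositions):
    return [
        CoordinationRecord(frame=f, metal_index=0, ligands=frozenset(c))
        for f, c in enumerate(compositions)
    ]


def test_substitution_called_between_stable_runs():
    before = {(28, "GLU", "OE1"), (57, "CYS", "SG")}
    after = {(29, "ASP", "OD1"), (57, "CYS", "SG")}
    recs = _records([before] * 100 + [after] * 100)
    (ev,) = detect_substitutions(recs, persistence=25)
    assert ev.frame == 100
    assert ev.lost == frozenset({(28, "GLU", "OE1")})
    assert ev.gained == frozenset({(29, "ASP", "OD1")})


def test_stable_coordination_yields_no_events():
    recs = _records([{(28, "GLU", "OE1")}] * 200)
    assert detect_substitutions(recs, persistence=25) == []


def test_flicker_below_persistence_is_ignored():
    a = {(28, "GLU", "OE1")}
    b = {(29, "ASP", "OD1")}
    compositions = [a] * 60 + [a, b] * 30 + [a] * 60
    recs = _records(compositions)
    assert detect_substitutions(recs, persistence=50) == []


def test_pure_loss_or_gain_is_not_a_substitution():
    full = {(28, "GLU", "OE1"), (57, "CYS", "SG")}
    partial = {(57, "CYS", "SG")}
    recs = _records([full] * 100 + [partial] * 100)
    assert detect_substitutions(recs, persistence=25) == []


def test_scripted_substitution_recovered_from_ligase_mimic(ligase_sim):
    cfg, traj, truth = ligase_sim
    records = metal_coordination(traj, truth.zn_indices, cutoff=2.8)
    events = detect_substitutions(records, persistence=25)
    frame, lost, gained = truth.substitution
    assert len(events) == 1
    assert events[0].frame == frame
    assert events[0].lost == frozenset({lost})
    assert events[0].gained == frozenset({gained})


# ---------------------------------------------------------------------------
# pair distances
# ---------------------------------------------------------------------------

def test_static_pair_distance():
    atoms = [
        Atom(1, "ZN", "ZN", 100, "Z", "Zn", 2),
        Atom(2, "ZN", "ZN", 101, "Z", "Zn", 2),
    ]
    coords = np.zeros((3, 2, 3))
    coords[:, 1, 0] = 7.0
    d = pair_distance_series(_traj(atoms, coords), 0, 1)
    np.testing.assert_allclose(d, 7.0)


def test_pair_distance_minimum_image():
    atoms = [
        Atom(1, "ZN", "ZN", 100, "Z", "Zn", 2),
        Atom(2, "ZN", "ZN", 101, "Z", "Zn", 2),
    ]
    coords = [[0.0, 0.0, 44.0], [0.0, 0.0, -44.0]]
    d = pair_distance_series(_traj(atoms, coords), 0, 1)
    np.testing.assert_allclose(d, 2.0)


def test_pair_distance_same_atom_rejected(zn_with_donors):
    with pytest.raises(SelectionError, match="twice"):
        pair_distance_series(zn_with_donors, 0, 0)


def test_distance_invariant_under_box_translation(zn_with_donors):
    base = pair_distance_series(zn_with_donors, 0, 1)
    shifted = zn_with_donors.coordinates.copy()
    shifted[:, 1] += np.array([90.0, -90.0, 180.0])  # whole box vectors
    traj2 = Trajectory(zn_with_donors.topology, zn_with_donors.times,
                       shifted, zn_with_donors.boxes)
    np.testing.assert_allclose(pair_distance_series(traj2, 0, 1), base,
                               atol=1e-9)


def test_zn_zn_distance_stable_on_rigid_core(ligase_sim):
    cfg, traj, truth = ligase_sim
    d = pair_distance_series(traj, int(truth.zn_indices[0]),
                             int(truth.zn_indices[1]))
    assert d.std() < 3 * cfg.sigma_core


# ---------------------------------------------------------------------------
# salt bridges
# ---------------------------------------------------------------------------

def _bridge_traj(n_on, n_off):
    atoms = [
        Atom(1, "NZ", "LYS", 17, "A", "N", 0),
        Atom(2, "OD1", "ASP", 55, "A", "O", 0),
        Atom(3, "OD2", "ASP", 55, "A", "O", 0),
    ]
    frames = []
    for i in range(n_on + n_off):
        d = 3.0 if i < n_on else 6.0
        frames.append([[d, 0, 0], [0, 0, 0], [-1.1, 0, 0]])
    return _traj(atoms, np.asarray(frames))


def test_scripted_occupancy_reported():
    traj = _bridge_traj(60, 40)
    (rec,) = detect_salt_bridges(traj, cutoff=4.0, occupancy_min=0.5)
    assert rec.basic_residue == (17, "LYS")
    assert rec.acidic_residue == (55, "ASP")
    assert rec.occupancy == pytest.approx(0.60)


def test_occupancy_threshold_filters_pair():
    traj = _bridge_traj(60, 40)
    assert detect_salt_bridges(traj, cutoff=4.0, occupancy_min=0.7) == []


def test_minimum_over_donor_acceptor_atom_pairs():
    atoms = [
        Atom(1, "NZ", "LYS", 17, "A", "N", 0),
        Atom(2, "OD1", "ASP", 55, "A", "O", 0),
        Atom(3, "OD2", "ASP", 55, "A", "O", 0),
    ]
    coords = [[0.0, 0.0, 0.0], [3.5, 0.0, 0.0], [5.0, 0.0, 0.0]]
    (rec,) = detect_salt_bridges(_traj(atoms, coords), cutoff=4.0,
                                 occupancy_min=0.5)
    np.testing.assert_allclose(rec.distances, [3.5])


def test_apolar_topology_yields_no_bridges():
    atoms = [Atom(1, "CA", "ALA", 1, "A", "C", 0)]
    assert detect_salt_bridges(_traj(atoms, [[0.0, 0.0, 0.0]])) == []


def test_scripted_bridges_recovered_from_ligase_mimic(ligase_sim):
    cfg, traj, truth = ligase_sim
    found = {
        (r.basic_residue[0], r.acidic_residue[0]): r.occupancy
        for r in detect_salt_bridges(traj, cutoff=4.0, occupancy_min=0.1)
    }
    for b_rid, a_rid, occ, _ in truth.salt_bridges:
        assert found[(b_rid, a_rid)] == pytest.approx(occ)
    assert len(found) == len(truth.salt_bridges)
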