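"""Contact criteria, occupancy bookkeeping, and oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_pair_distances, make_point_topology
from memborient.contacts import (
    ContactCriterion,
    OccupancyMap,
    cg_lipid_contacts,
    nearest_partner_distance,
    pool_occupancy,
    protein_protein_contacts,
    residue_lipid_contacts,
    threshold_mask,
)
from memborient.synthetic_data import copy_selections, make_multicopy_scene
from memborient.traj_model import Atom, Frame, Selection, Topology, Trajectory, select


def _protein_with_sidechains(n_res=3):
    """Tiny atomistic-like protein: N/CA/C backbone plus one CB per residue."""
    atoms = []
    for r in range(1, n_res + 1):
        for nm in ("N", "CA", "C", "CB"):
            atoms.append(
                Atom(index=len(atoms), name=nm, residue_name="ALA",
                     residue_id=r, segment_id="A", mass=12.0)
            )
    return Topology(atoms)


def _frame_with_cb_positions(top, cb_positions, p_positions, box=(10, 10, 10)):
    """Backbone parked far away; CB and lipid-P positions set explicitly."""
    n_prot = top.n_atoms
    coords = np.zeros((n_prot + len(p_positions), 3))
    cb_i = 0
    for i in range(n_prot):
        if top.names[i] == "CB":
            coords[i] = cb_positions[cb_i]
            cb_i += 1
        else:
            coords[i] = [8.5, 8.5, 8.5]
    coords[n_prot:] = p_positions
    return coords


def _combined(top_protein, n_p):
    atoms = list(top_protein.atoms)
    for k in range(n_p):
        atoms.append(
            Atom(index=len(atoms), name="P", residue_name="POPC",
                 residue_id=100 + k, segment_id="M", mass=30.97)
        )
    return Topology(atoms)


class TestResidueLipidContacts:
    def _build(self, cb_to_p_distance, n_frames=1):
        prot = _protein_with_sidechains(1)
        top = _combined(prot, 1)
        frames = []
        for t in range(n_frames):
            coords = _frame_with_cb_positions(
                prot, [[5.0, 5.0, 5.0]], [[5.0 + cb_to_p_distance, 5.0, 5.0]]
            )
            frames.append(Frame(coords, np.array([10.0, 10, 10]), float(t)))
        traj = Trajectory(top, frames)
        return traj, select(top, "segment A"), select(top, "name P")

    def test_boundary_inside(self):
        traj, prot, lip = self._build(0.49)
        cs = residue_lipid_contacts(traj, prot, lip)
        assert cs.hits[0, 0]

    def test_boundary_outside_strict(self):
        traj, prot, lip = self._build(0.51)
        cs = residue_lipid_contacts(traj, prot, lip)
        assert not cs.hits[0, 0]
        # exactly at the cutoff: strict < means no contact
        traj, prot, lip = self._build(0.5)
        assert not residue_lipid_contacts(traj, prot, lip).hits[0, 0]

    def test_planted_occupancy_fraction(self):
        prot = _protein_with_sidechains(1)
        top = _combined(prot, 1)
        frames = []
        for t in range(10):
            d = 0.3 if t < 4 else 2.0  # contact in exactly 4 of 10 frames
            coords = _frame_with_cb_positions(prot, [[5, 5, 5]], [[5 + d, 5, 5]])
            frames.append(Frame(coords, np.array([10.0, 10, 10]), float(t)))
        traj = Trajectory(top, frames)
        cs = residue_lipid_contacts(traj, select(top, "segment A"), select(top, "name P"))
        assert cs.occupancy[0] == pytest.approx(0.4)

    def test_glycine_falls_back_to_backbone(self):
        atoms = [
            Atom(index=i, name=nm, residue_name="GLY", residue_id=1,
                 segment_id="A", mass=12.0)
            for i, nm in enumerate(("N", "CA", "C"))
        ]
        atoms.append(Atom(index=3, name="P", residue_name="POPC",
                          residue_id=2, segment_id="M", mass=31.0))
        top = Topology(atoms)
        coords = np.array([[4.9, 5, 5], [5, 5, 5], [5.1, 5, 5], [5.2, 5, 5]])
        traj = Trajectory(top, [Frame(coords, np.array([10.0, 10, 10]))])
        with pytest.warns(UserWarning, match="side-chain"):
            cs = residue_lipid_contacts(
                traj, select(top, "segment A"), select(top, "name P")
            )
        assert cs.hits[0, 0]  # CA at 0.2 nm from P

    def test_periodic_image_contact(self):
        prot = _protein_with_sidechains(1)
        top = _combined(prot, 1)
        coords = _frame_with_cb_positions(prot, [[0.1, 5, 5]], [[9.8, 5, 5]])
        traj = Trajectory(top, [Frame(coords, np.array([10.0, 10, 10]))])
        cs = residue_lipid_contacts(traj, select(top, "segment A"), select(top, "name P"))
        assert cs.hits[0, 0]  # 0.3 nm across the boundary


class TestCGLipidContacts:
    def _cg_scene(self):
        atoms = []
        # one CG residue: backbone bead + side-chain bead
        for nm in ("BB", "SC1"):
            atoms.append(Atom(index=len(atoms), name=nm, residue_name="CPY",
                              residue_id=1, segment_id="P", mass=72.0, is_bead=True))
        for k, lt in enumerate(("GM3", "POPC")):
            atoms.append(Atom(index=len(atoms), name="HG", residue_name=lt,
                              residue_id=2 + k, segment_id="M", mass=72.0, is_bead=True))
        top = Topology(atoms)
        coords = np.array([[5, 5, 5], [5.3, 5, 5], [5.3, 5.5, 5], [5.3, 8.0, 5]])
        traj = Trajectory(top, [Frame(coords, np.array([10.0, 10, 10]), 0.0)])
        return top, traj

    def test_per_type_series(self):
        top, traj = self._cg_scene()
        series = cg_lipid_contacts(
            traj,
            select(top, "segment P"),
            {"GM3": select(top, "resname GM3"), "POPC": select(top, "resname POPC")},
        )
        assert series["GM3"].occupancy[0] == 1.0  # SC1↔GM3 0.5 nm < 0.65
        assert series["POPC"].occupancy[0] == 0.0  # 2.5 nm away

    def test_unknown_lipid_type_rejected(self):
        top, traj = self._cg_scene()
        with pytest.raises(ValueError, match="unknown lipid type"):
            cg_lipid_contacts(traj, select(top, "segment P"),
                              {"XXX": select(top, "resname GM3")})

    def test_equidistant_types_counted_independently(self):
        top, traj = self._cg_scene()
        # move POPC to mirror GM3's distance
        traj.frames[0].coordinates[3] = [5.3, 4.5, 5]
        series = cg_lipid_contacts(
            traj,
            select(top, "segment P"),
            {"GM3": select(top, "resname GM3"), "POPC": select(top, "resname POPC")},
        )
        assert series["GM3"].occupancy[0] == 1.0
        assert series["POPC"].occupancy[0] == 1.0


class TestOracleEquivalence:
    @pytest.mark.parametrize("cutoff", [0.5, 0.65])
    @pytest.mark.parametrize("periodic", [True, False])
    def test_nearest_distance_matches_dense_oracle(self, rng, cutoff, periodic):
        for _ in range(8):
            n_a, n_b = rng.integers(20, 120, 2)
            box = rng.uniform(3.0, 6.0, 3)
            a = rng.random((n_a, 3)) * box
            b = rng.random((n_b, 3)) * box
            d_fast = nearest_partner_distance(a, b, box if periodic else None)
            d_brute = brute_pair_distances(a, b, box if periodic else None).min(axis=1)
            np.testing.assert_allclose(d_fast, d_brute, atol=1e-10)
            np.testing.assert_array_equal(d_fast < cutoff, d_brute < cutoff)


class TestProteinProteinContacts:
    def test_far_copies_zero_occupancy(self):
        top, traj, _ = make_multicopy_scene([1, 1], n_frames=2, box=(12, 12, 6), seed=1)
        occ, pairs = protein_protein_contacts(traj, copy_selections(top), cutoff=0.65)
        assert occ.occupancy.max() == 0.0
        assert pairs.empty

    def test_planted_dimer_interface(self):
        top, traj, _ = make_multicopy_scene([2], n_frames=3, box=(12, 12, 6), seed=1)
        occ, pairs = protein_protein_contacts(traj, copy_selections(top), cutoff=0.65)
        df = occ.to_frame()
        # tip of copy 0 and base of copy 1 touch in every frame
        touching = df[df.occupancy == 1.0]
        assert len(touching) == 2
        assert occ.mask.sum() == 2  # both pass the 2.5 % mask
        assert set(zip(pairs.copy_i, pairs.copy_j)) == {(0, 1)}

    def test_overlapping_copies_rejected(self):
        top, traj, _ = make_multicopy_scene([1, 1], n_frames=1, box=(12, 12, 6), seed=1)
        sels = copy_selections(top)
        bad = [sels[0], Selection("dup", sels[0].atom_indices)]
        with pytest.raises(ValueError, match="overlap"):
            protein_protein_contacts(traj, bad)

    def test_random_scene_matches_brute_force(self, rng):
        n_copies, beads = 4, 5
        box = np.array([4.0, 4.0, 4.0])
        coords = rng.random((n_copies * beads, 3)) * box
        top = make_point_topology(n_copies * beads)
        sels = [
            Selection(f"c{k}", np.arange(k * beads, (k + 1) * beads))
            for k in range(n_copies)
        ]
        traj = Trajectory(top, [Frame(coords, box)])
        cutoff = 0.8
        occ, pairs = protein_protein_contacts(traj, sels, cutoff=cutoff)
        D = brute_pair_distances(coords, coords, box)
        # point topology: residue r of the pooled map is exactly atom r
        for r in range(n_copies * beads):
            k = r // beads
            others = np.concatenate(
                [sels[m].atom_indices for m in range(n_copies) if m != k]
            )
            expect = bool((D[r, others] < cutoff).any())
            assert bool(occ.occupancy[r] > 0) == expect


class TestThresholdMask:
    def _map(self, occs):
        meta = pd.DataFrame(
            {"segment": "A", "resid": range(1, len(occs) + 1), "resname": "ALA"}
        )
        return OccupancyMap(residues=meta, occupancy=np.array(occs))

    def test_strictly_greater(self):
        m = self._map([0.026, 0.025, 0.0])
        out = threshold_mask(m, 0.025)
        assert list(out["resid"]) == [1]

    def test_all_zero_empty(self):
        assert threshold_mask(self._map([0.0, 0.0]), 0.025).empty

    def test_zero_threshold_returns_any_contact(self):
        out = threshold_mask(self._map([0.4, 0.0, 0.1]), 0.0)
        assert list(out["resid"]) == [1, 3]  # sorted by occupancy desc

    def test_occupancy_bounds_enforced(self):
        with pytest.raises(ValueError):
            self._map([1.2])


class TestPooling:
    def test_frame_order_invariance(self):
        traj_args = TestResidueLipidContacts()
        traj, prot, lip = traj_args._build(0.3, n_frames=4)
        cs = residue_lipid_contacts(traj, prot, lip)
        reversed_traj = Trajectory(
            traj.topology,
            [Frame(f.coordinates, f.box, t) for t, f in enumerate(reversed(traj.frames))],
        )
        cs2 = residue_lipid_contacts(reversed_traj, prot, lip)
        np.testing.assert_allclose(cs.occupancy, cs2.occupancy)

    def test_pooled_equals_mean_for_equal_length_replicas(self):
        builder = TestResidueLipidContacts()
        t1, prot, lip = builder._build(0.3, n_frames=5)
        t2, _, _ = builder._build(0.8, n_frames=5)
        s1 = residue_lipid_contacts(t1, prot, lip)
        s2 = residue_lipid_contacts(t2, prot, lip)
        pooled = pool_occupancy([s1, s2])
        np.testing.assert_allclose(
            pooled.occupancy, (s1.occupancy + s2.occupancy) / 2
        )


def test_bfactor_stamped_pdb_roundtrip(tmp_path):
    """Per-residue occupancy written into the PDB B-factor column (×100)."""
    import pandas as pd
    from memborient.contacts import write_occupancy_bfactors

    top = _protein_with_sidechains(2)
    coords = np.tile(np.array([[5.0, 5.0, 5.0]]), (top.n_atoms, 1))
    frame = Frame(coords, np.array([10.0, 10.0, 10.0]))
    meta = pd.DataFrame(
        {"segment": ["A", "A"], "resid": [1, 2], "resname": ["ALA", "ALA"]}
    )
    occ = OccupancyMap(residues=meta, occupancy=np.array([0.4, 0.0]))
    path = tmp_path / "occ.pdb"
    write_occupancy_bfactors(str(path), top, frame, occ)
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    res1 = u.select_atoms("resid 1")
    res2 = u.select_atoms("resid 2")
    assert np.allclose(res1.tempfactors, 40.0)
    assert np.allclose(res2.tempfactors, 0.0)
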