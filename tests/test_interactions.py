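"""Contact maps, salt bridges, hydrogen bonds, insertion profiling."""

import numpy as np
import pytest

from pepmem import synth
from pepmem.core import DomainError, MolecularSystem, Trajectory
from pepmem.interactions import (
    classify_contact_range,
    com_distance_series,
    enumerate_salt_bridge_pairs,
    hydrogen_bonds,
    insertion_profile,
    peptide_lipid_contacts,
    residue_contact_map,
    salt_bridge_distance_series,
    salt_bridges,
)

from conftest import make_point_system, static_trajectory


class TestContactMap:
    @pytest.mark.parametrize("separation,pct", [(6.4, 100.0), (6.6, 0.0)])
    def test_fixed_pair(self, separation, pct):
        system = make_point_system("GLY", [[0.0, 0, 0], [separation, 0, 0]])
        traj = static_trajectory(system.coords, n_frames=3)
        cm = residue_contact_map(traj, system)
        assert cm.matrix[0, 1] == pct
        assert cm.matrix[1, 0] == pct

    def test_boundary_is_strict(self):
        system = make_point_system("GLY", [[0.0, 0, 0], [6.5, 0, 0]])
        traj = static_trajectory(system.coords)
        assert residue_contact_map(traj, system).matrix[0, 1] == 0.0

    def test_matches_frame_loop_oracle(self):
        rng = np.random.default_rng(0)
        n_res, n_frames = 6, 20
        system = make_point_system("GLY", np.zeros((n_res, 3)))
        walk = np.cumsum(rng.normal(0, 2.0, (n_frames, n_res, 3)), axis=0) + \
            rng.uniform(-5, 5, (1, n_res, 3))
        traj = Trajectory(walk, np.tile([50.0, 50, 50], (n_frames, 1)),
                          np.arange(float(n_frames)))
        cm = residue_contact_map(traj, system)
        for i in range(n_res):
            for j in range(n_res):
                if i == j:
                    continue
                hits = sum(
                    1 for f in range(n_frames)
                    if np.linalg.norm(walk[f, i] - walk[f, j]) < 6.5
                )
                assert cm.matrix[i, j] == pytest.approx(100.0 * hits / n_frames)

    def test_bounds_and_symmetry(self, small_run):
        system, traj, _ = small_run
        cm = residue_contact_map(traj, system)
        assert np.allclose(cm.matrix, cm.matrix.T)
        assert cm.matrix.min() >= 0 and cm.matrix.max() <= 100
        assert np.all(np.diag(cm.matrix) == 0)

    def test_planted_contacts_recovered_exactly(self, small_run):
        system, traj, manifest = small_run
        cm = residue_contact_map(traj, system)
        found = {
            (int(cm.residues[i]), int(cm.residues[j]))
            for i in range(len(cm.residues)) for j in range(i + 1, len(cm.residues))
            if cm.matrix[i, j] == 100.0
        }
        assert found == set(map(tuple, manifest.planted_contacts))


class TestContactRange:
    @pytest.mark.parametrize("sep,cls", [
        (1, "local"), (5, "local"), (6, "short"), (8, "short"), (11, "short"),
        (12, "medium"), (15, "medium"), (23, "medium"),
        (24, "long"), (30, "long"), (41, "long"),
    ])
    def test_classes(self, sep, cls):
        assert classify_contact_range(1, 1 + sep) == cls

    def test_same_residue_rejected(self):
        with pytest.raises(DomainError):
            classify_contact_range(5, 5)


class TestPeptideLipidContacts:
    def test_far_peptide_all_zero(self, small_run):
        system, traj, _ = small_run
        far = Trajectory(traj.coords.copy(), traj.box, traj.times)
        far.coords[:, system.peptide_indices, 2] += 200.0
        table = peptide_lipid_contacts(far, system)
        assert (table.values == 0).all()

    def test_planted_surface_contacts_match_manifest(self):
        pspec = synth.PeptideSpec(com_z_path=np.full(3, 21.0))
        bspec = synth.BilayerSpec(lipids_per_leaflet=16, box_xy=(40.0, 40.0),
                                  head_z_sigma=0.0)
        system, traj, manifest = synth.generate_trajectory(
            bspec, pspec, synth.IonSpec(n_ca=0, n_cl=3), n_frames=3, seed=2
        )
        table = peptide_lipid_contacts(traj, system)
        found = set(table.index[(table > 0).any(axis=1)])
        assert found == set(manifest.surface_contact_residues)

    def test_unassigned_segment_rejected(self, small_run):
        system, traj, _ = small_run
        from pepmem.core import MappingError
        with pytest.raises(MappingError):
            peptide_lipid_contacts(traj, system, segments=("S9",))


class TestSaltBridges:
    def test_default_sequence_yields_18_pairs(self, small_run):
        system, _, _ = small_run
        assert len(enumerate_salt_bridge_pairs(system)) == 18

    @pytest.mark.parametrize("distance,occ", [(4.4, 100.0), (4.6, 0.0)])
    def test_occupancy_thresholds(self, distance, occ):
        pspec = synth.PeptideSpec(planted_salt_bridges=[(28, 23, distance)])
        system, traj, _ = synth.generate_trajectory(
            peptide=pspec, n_frames=2, seed=1
        )
        table = salt_bridges(traj, system).table
        row = table[(table.pos_residue == 28) & (table.neg_residue == 23)]
        assert row.occupancy_pct.iloc[0] == occ

    def test_matches_frame_loop_oracle(self, small_run):
        system, traj, _ = small_run
        result = salt_bridges(traj, system)
        from pepmem.interactions import representative_atom_index
        for _, row in result.table.iterrows():
            ap = representative_atom_index(system, row.pos_residue)
            an = representative_atom_index(system, row.neg_residue)
            hits = 0
            for f in range(traj.n_frames):
                d = min(
                    np.linalg.norm(traj.coords[f, i] - traj.coords[f, j])
                    for i in ap for j in an
                )
                hits += d - 4.5 <= 0
            assert row.occupancy_pct == pytest.approx(100.0 * hits / traj.n_frames)

    def test_counts_bounded_by_pairs(self, small_run):
        system, traj, _ = small_run
        result = salt_bridges(traj, system)
        assert result.counts.values.max() <= 18


class TestSaltBridgeDistanceSeries:
    @pytest.mark.parametrize("d,frac", [(3.9, 1.0), (6.0, 0.0)])
    def test_constant_distance(self, d, frac):
        system = make_point_system("GLY", [[0.0, 0, 0], [d, 0, 0]])
        traj = static_trajectory(system.coords, n_frames=4)
        _, got = salt_bridge_distance_series(traj, 0, 1)
        assert got == frac

    def test_alternating_schedule(self):
        pspec = synth.PeptideSpec(
            planted_salt_bridges=[(28, 22, [4.0, 6.0] * 5)])
        system, traj, _ = synth.generate_trajectory(
            peptide=pspec, n_frames=10, seed=1
        )
        i = system.find_atom(28, "NZ")
        j = system.find_atom(22, "CD")
        series, frac = salt_bridge_distance_series(traj, i, j)
        assert frac == 0.5
        assert np.allclose(sorted(set(np.round(series.values, 6))), [4.0, 6.0])

    def test_identical_atoms_rejected(self):
        system = make_point_system("GLY", [[0.0, 0, 0]])
        traj = static_trajectory(system.coords)
        with pytest.raises(DomainError):
            salt_bridge_distance_series(traj, 0, 0)


def _hbond_system(d_xy, angle_deg):
    """N–H donor in residue 1, O acceptor in residue 2, angle at H."""
    h = np.array([1.0, 0.0, 0.0])
    theta = np.deg2rad(180.0 - angle_deg)
    y = h + (d_xy - 1.0) * np.array([np.cos(theta), np.sin(theta), 0.0])
    coords = [[0.0, 0, 0], h, y]
    return MolecularSystem(
        names=["N", "H", "O"], residue_names=["GLY", "GLY", "GLY"],
        residue_indices=[1, 1, 2], chain_ids=["A"] * 3,
        elements=["N", "H", "O"], masses=[14.007, 1.008, 15.999],
        coords=np.asarray(coords),
    )


class TestHydrogenBonds:
    def test_linear_bond_counted(self):
        system = _hbond_system(3.4, 180.0)
        traj = static_trajectory(system.coords)
        table, counts = hydrogen_bonds(traj, system)
        assert counts.values[0] == 1
        assert table.occupancy_pct.iloc[0] == 100.0

    def test_distance_gate(self):
        system = _hbond_system(3.6, 180.0)
        traj = static_trajectory(system.coords)
        _, counts = hydrogen_bonds(traj, system)
        assert counts.values[0] == 0

    def test_angle_gate(self):
        # X–Y distance satisfied but the X–H···Y angle is too bent
        n = np.array([0.0, 0, 0])
        h = np.array([1.0, 0, 0])
        theta = np.deg2rad(180.0 - 130.0)
        y = h + 2.0 * np.array([np.cos(theta), np.sin(theta), 0.0])
        assert np.linalg.norm(y - n) < 3.5
        system = _hbond_system(3.4, 180.0)
        coords = np.array([n, h, y])
        traj = static_trajectory(coords)
        _, counts = hydrogen_bonds(traj, system)
        assert counts.values[0] == 0

    def test_planted_hbonds_recovered(self):
        pspec = synth.PeptideSpec(planted_hbonds=[(10, 30), (5, 25)])
        system, traj, manifest = synth.generate_trajectory(
            peptide=pspec, n_frames=2, seed=4
        )
        table, _ = hydrogen_bonds(traj, system)
        found = set(zip(table.donor_residue, table.acceptor_residue))
        for (ni, hi, oi) in manifest.planted_hbonds:
            pair = (int(system.residue_indices[ni]), int(system.residue_indices[oi]))
            assert pair in found
            row = table[(table.donor_atom == ni) & (table.acceptor_atom == oi)]
            assert row.occupancy_pct.iloc[0] == 100.0


@pytest.fixture(scope="module")
def planted():
    offsets = np.tile([-8.0, 0.0, 9.0], 14)
    pspec = synth.PeptideSpec(residue_z_offsets=offsets,
                              com_z_path=np.full(20, 20.0))
    return synth.generate_trajectory(peptide=pspec, n_frames=20, seed=6)


class TestInsertionProfile:
    def test_noiseless_classification_matches_manifest(self, planted):
        system, traj, manifest = planted
        prof = insertion_profile(traj, system)
        assert list(prof.classification) == list(manifest.insertion_class_true)
        assert {"inserted", "surface", "detached"} == set(prof.classification)

    def test_jittered_classification_mostly_matches(self):
        offsets = np.tile([-8.0, 0.0, 9.0], 14)
        pspec = synth.PeptideSpec(residue_z_offsets=offsets,
                                  com_z_path=np.full(20, 20.0), noise_sigma=0.3)
        system, traj, manifest = synth.generate_trajectory(
            peptide=pspec, n_frames=20, seed=6
        )
        prof = insertion_profile(traj, system)
        agree = np.mean([
            a == b for a, b in zip(prof.classification, manifest.insertion_class_true)
        ])
        assert agree >= 0.95

    def test_histograms_normalized(self, planted):
        system, traj, _ = planted
        prof = insertion_profile(traj, system)
        assert np.allclose(prof.histograms.sum(axis=1), 1.0)

    def test_outward_shift_never_reinserts(self, planted):
        system, traj, _ = planted
        prof = insertion_profile(traj, system)
        shifted = Trajectory(traj.coords.copy(), traj.box, traj.times)
        pep = system.peptide_indices
        shifted.coords[:, pep, 2] += 5.0
        prof2 = insertion_profile(shifted, system, Zp=prof.Zp)
        order = {"inserted": 0, "surface": 1, "detached": 2}
        for before, after in zip(prof.classification, prof2.classification):
            assert order[after] >= order[before]


class TestComDistance:
    def test_coincident_groups(self):
        system = make_point_system("GLY", [[1.0, 2, 3], [1.0, 2, 3]])
        traj = static_trajectory(system.coords, n_frames=3)
        series, frac = com_distance_series(traj, system, [0], [1])
        assert np.allclose(series.values, 0.0) and frac == 1.0

    def test_static_separation(self):
        system = make_point_system("GLY", [[0.0, 0, 0], [10.0, 0, 0]])
        traj = static_trajectory(system.coords, n_frames=3)
        series, frac = com_distance_series(traj, system, [0], [1])
        assert np.allclose(series.values, 10.0) and frac == 0.0

    def test_planted_approach_schedule(self):
        com_path = np.array([40.0, 30.0, 22.0, 20.0, 19.0])
        pspec = synth.PeptideSpec(com_z_path=com_path)
        system, traj, _ = synth.generate_trajectory(
            peptide=pspec, n_frames=5, seed=3
        )
        mem = np.concatenate([l.indices for l in system.lipids])
        series, frac = com_distance_series(
            traj, system, system.peptide_indices, mem, contact_cutoff=21.0
        )
        assert np.allclose(series.values, com_path, atol=1.0)
        assert frac == pytest.approx((com_path < 21.0).mean(), abs=0.21)

    def test_empty_group_rejected(self, small_run):
        system, traj, _ = small_run
        with pytest.raises(DomainError):
            com_distance_series(traj, system, [], [0])
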