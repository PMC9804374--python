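"""RMSD/Rg/RMSF, SASA, secondary-structure aggregation, equilibration window."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pepmem import synth
from pepmem.core import DomainError, RegionMap, Trajectory, WindowError
from pepmem.peptide import (
    assign_ss_from_dihedrals,
    compute_phi_psi,
    equilibration_window,
    radius_of_gyration,
    rmsd,
    rmsf,
    sasa,
    ss_aggregate,
)

from conftest import make_point_system, static_trajectory


class TestRMSD:
    def test_identical_structures(self):
        x = np.random.default_rng(0).normal(0, 3, (10, 3))
        assert rmsd(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 3, (10, 3))
        rot = Rotation.from_euler("zyx", [30, 50, -20], degrees=True)
        y = rot.apply(x) + np.array([5.0, -3.0, 8.0])
        assert rmsd(x, y, weights=rng.uniform(1, 12, 10)) < 1e-8

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 2, (8, 3))
        b = a + rng.normal(0, 0.5, (8, 3))
        assert rmsd(a, b) == pytest.approx(rmsd(b, a), abs=1e-10)

    def test_triangle_inequality_spot_check(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b, c = rng.normal(0, 2, (3, 6, 3))
            assert rmsd(a, c) <= rmsd(a, b) + rmsd(b, c) + 1e-9

    def test_matches_rotation_grid_oracle(self):
        # brute-force minimization over a rotation grid on 5-atom instances
        rng = np.random.default_rng(4)
        ref = rng.normal(0, 2, (5, 3))
        frame = ref + rng.normal(0, 0.4, (5, 3))
        got = rmsd(ref, frame)

        r0 = ref - ref.mean(0)
        f0 = frame - frame.mean(0)

        def best_on_grid(center, half_width, step):
            grids = [np.arange(c - half_width, c + half_width + 1e-9, step)
                     for c in center]
            ee = np.stack(np.meshgrid(*grids, indexing="ij"), -1).reshape(-1, 3)
            mats = Rotation.from_euler("zyz", ee, degrees=True).as_matrix()
            moved = np.einsum("rij,aj->rai", mats, f0)
            vals = np.sqrt(((moved - r0) ** 2).sum(-1).mean(-1))
            k = int(np.argmin(vals))
            return ee[k], float(vals[k])

        center, val = best_on_grid(np.zeros(3), 180.0, 6.0)
        for hw, st in ((6.0, 1.0), (1.0, 0.1), (0.1, 0.02)):
            center, val = best_on_grid(center, hw, st)
        assert abs(got - val) < 1e-3

    def test_too_few_atoms_rejected(self):
        with pytest.raises(DomainError):
            rmsd(np.zeros((2, 3)), np.ones((2, 3)))


class TestRg:
    def test_single_atom(self):
        assert radius_of_gyration(np.array([[3.0, 1.0, 2.0]])) == 0.0

    def test_two_unit_masses_2A_apart(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(coords) == pytest.approx(1.0)

    def test_matches_direct_sum_oracle(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(0, 4, (20, 3))
        m = rng.uniform(1, 16, 20)
        com = sum(mi * ri for mi, ri in zip(m, coords)) / m.sum()
        oracle = np.sqrt(
            sum(mi * np.sum((ri - com) ** 2) for mi, ri in zip(m, coords)) / m.sum()
        )
        assert radius_of_gyration(coords, m) == pytest.approx(oracle, rel=1e-12)

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(0, 4, (15, 3))
        m = rng.uniform(1, 16, 15)
        moved = Rotation.from_euler("xyz", [10, 70, 33], degrees=True).apply(coords)
        moved += [4.0, 5.0, -6.0]
        assert radius_of_gyration(moved, m) == pytest.approx(
            radius_of_gyration(coords, m), rel=1e-12
        )


class TestRMSF:
    def test_static_trajectory_zero(self):
        coords = np.random.default_rng(7).normal(0, 3, (6, 3))
        traj = static_trajectory(coords, n_frames=5)
        assert np.allclose(rmsf(traj, range(6)), 0.0)

    def test_single_oscillating_atom_closed_form(self):
        a = 0.8
        base = np.zeros((4, 3))
        frames = np.tile(base, (10, 1, 1))
        frames[::2, 0, 0] = +a
        frames[1::2, 0, 0] = -a
        traj = Trajectory(frames, np.tile([50.0, 50, 50], (10, 1)), np.arange(10.0))
        vals = rmsf(traj, range(4), align=False)
        assert vals[0] == pytest.approx(a)
        assert np.allclose(vals[1:], 0.0)

    def test_isotropic_gaussian_jitter(self):
        sigma = 0.5
        rng = np.random.default_rng(8)
        base = rng.normal(0, 5, (5, 3))
        frames = base + rng.normal(0, sigma, (500, 5, 3))
        traj = Trajectory(frames, np.tile([50.0, 50, 50], (500, 1)), np.arange(500.0))
        vals = rmsf(traj, range(5), align=False)
        assert np.all(np.abs(vals - sigma * np.sqrt(3)) < 0.05 * sigma * np.sqrt(3) * 3)

    def test_requires_two_frames(self):
        traj = static_trajectory(np.zeros((3, 3)), n_frames=1)
        with pytest.raises(DomainError):
            rmsf(traj, range(3))


class TestSASA:
    def test_isolated_carbon_closed_form(self):
        system = make_point_system("GLY", [[0.0, 0, 0]], atom_names=["C"],
                                   elements=["C"])
        area = sasa(system.coords, system)["sasa"].sum()
        assert area == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2, rel=1e-3)

    def test_coincident_atoms_count_once(self):
        one = make_point_system("GLY", [[0.0, 0, 0]], atom_names=["C"])
        two = make_point_system("GLY", [[0.0, 0, 0], [0.0, 0, 0]],
                                atom_names=["C1", "C2"])
        a1 = sasa(one.coords, one)["sasa"].sum()
        a2 = sasa(two.coords, two)["sasa"].sum()
        assert a2 == pytest.approx(a1, rel=1e-9)

    def test_against_dense_point_sampling_oracle(self):
        rng = np.random.default_rng(9)
        coords = np.array([[0.0, 0, 0], [1.8, 0, 0], [0.6, 1.5, 0.4]])
        system = make_point_system("GLY", coords, atom_names=["C1", "C2", "C3"])
        got = sasa(coords, system, n_points=5000)["sasa"].sum()

        # oracle: Fibonacci-sphere sampling at 10⁵ points per atom
        n = 100_000
        k = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * k / n)
        theta = np.pi * (1 + 5 ** 0.5) * k
        sphere = np.stack([np.sin(phi) * np.cos(theta),
                           np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1)
        r = 1.7 + 1.4
        total = 0.0
        for i in range(3):
            pts = coords[i] + r * sphere
            free = np.ones(n, bool)
            for j in range(3):
                if j != i:
                    free &= np.linalg.norm(pts - coords[j], axis=1) >= r
            total += 4 * np.pi * r * r * free.mean()
        assert got == pytest.approx(total, rel=0.01)

    def test_monotone_under_atom_removal(self):
        rng = np.random.default_rng(10)
        coords = rng.normal(0, 1.5, (5, 3))
        system = make_point_system("GLY", coords,
                                   atom_names=[f"C{i}" for i in range(5)])
        full = sasa(coords, system).set_index("residue")["sasa"]
        reduced = sasa(coords, system, indices=range(4)).set_index("residue")["sasa"]
        for res in reduced.index:
            assert reduced[res] >= full[res] - 1e-6


class TestSSAggregate:
    def test_all_helix(self):
        content = ss_aggregate(["H" * 42] * 5)
        assert content.percent.loc["H", "Peptide"] == 100.0
        assert content.percent.loc["BS", "Peptide"] == 0.0

    def test_uniform_classes(self):
        frames = ["EHTC"] * 4
        content = ss_aggregate(frames, regions=RegionMap(
            R1=(1, 1), R2=(2, 2), R3=(3, 3), R4=(4, 4)))
        col = content.percent["Peptide"]
        assert np.allclose(col.values, 25.0)

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(11)
        codes = "HGIEBTSC"
        n_res, n_frames = 42, 30
        frames = ["".join(rng.choice(list(codes), n_res)) for _ in range(n_frames)]
        content = ss_aggregate(frames)
        from pepmem.peptide import SS_CLASS_OF_CODE
        counts = {"BS": 0, "H": 0, "T": 0, "RC": 0}
        for s in frames:
            for ch in s:
                counts[SS_CLASS_OF_CODE[ch]] += 1
        total = n_res * n_frames
        for cls in counts:
            assert content.percent.loc[cls, "Peptide"] == pytest.approx(
                100.0 * counts[cls] / total
            )

    def test_percentages_sum_to_100_per_scope(self):
        rng = np.random.default_rng(12)
        frames = ["".join(rng.choice(list("HETC"), 42)) for _ in range(10)]
        content = ss_aggregate(frames)
        for scope in content.percent.columns:
            assert content.percent[scope].sum() == pytest.approx(100.0, abs=0.01)

    def test_replica_standard_errors(self):
        reps = [["H" * 42] * 4, ["C" * 42] * 4]
        content = ss_aggregate(reps)
        assert content.percent.loc["H", "Peptide"] == pytest.approx(50.0)
        assert content.stderr.loc["H", "Peptide"] > 0

    def test_unknown_code_rejected(self):
        with pytest.raises(DomainError):
            ss_aggregate(["H" * 41 + "X"])


class TestDihedralAssigner:
    def test_windows(self):
        assert assign_ss_from_dihedrals(np.array([-60.0]), np.array([-45.0])) == "H"
        assert assign_ss_from_dihedrals(np.array([-140.0]), np.array([135.0])) == "E"
        assert assign_ss_from_dihedrals(np.array([60.0]), np.array([60.0])) == "C"

    def test_generated_conformations(self):
        for conf, expected in (("extended", "E"), ("helix_C_term", "H")):
            system, traj, _ = synth.generate_trajectory(
                peptide=synth.PeptideSpec(conformation=conf), n_frames=1, seed=0
            )
            phi, psi = compute_phi_psi(system, traj.coords[0])
            codes = assign_ss_from_dihedrals(phi, psi)
            assert codes[30] == expected


class TestEquilibrationWindow:
    def test_standard_window(self):
        times = np.arange(0.0, 501.0, 1.0)
        idx = equilibration_window(times, 200.0)
        assert times[idx[0]] == 200.0 and times[idx[-1]] == 500.0

    def test_tau_zero_full_series(self):
        times = np.arange(10.0)
        assert len(equilibration_window(times, 0.0)) == 10

    def test_short_series_rejected(self):
        with pytest.raises(WindowError):
            equilibration_window(np.arange(0.0, 100.0), 200.0)
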