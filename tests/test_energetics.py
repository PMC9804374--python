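"""Charge bookkeeping and gas-phase interaction-energy decomposition."""

import numpy as np
import pandas as pd
import pytest

from pepmem import synth
from pepmem.core import DomainError, Trajectory, WindowError
from pepmem.energetics import (
    COULOMB_CONSTANT,
    ChargeModel,
    default_charge_model,
    formal_charge,
    interaction_energy,
    per_residue_decomposition,
    windowed_binding_series,
)

from conftest import make_point_system, static_trajectory


class TestFormalCharge:
    def test_ab42_free(self):
        assert formal_charge(synth.AB42_SEQUENCE) == -3

    def test_ab42_cu_bound(self):
        assert formal_charge(synth.AB42_SEQUENCE, cu_bound=True) == -1

    def test_termini_cancel(self):
        assert formal_charge("GG") == 0

    def test_simple_sums(self):
        assert formal_charge("KKDD") == 0
        assert formal_charge("RRR") == 3

    def test_unknown_letter_rejected(self):
        with pytest.raises(DomainError):
            formal_charge("GXZ")


def _toy_charges(q, sigma=3.5, epsilon=0.1):
    n = len(q)
    return ChargeModel(np.asarray(q, float), np.full(n, sigma), np.full(n, epsilon))


class TestInteractionEnergy:
    def test_coulomb_constant_closed_form(self):
        coords = np.array([[0.0, 0, 0], [COULOMB_CONSTANT, 0, 0]])
        charges = _toy_charges([1.0, -1.0], epsilon=0.0)
        e = interaction_energy(coords, charges, [0], [1])
        assert e.e_elec == pytest.approx(-1.0, rel=1e-12)

    def test_lj_zero_at_sigma(self):
        coords = np.array([[0.0, 0, 0], [3.5, 0, 0]])
        charges = _toy_charges([0.0, 0.0])
        e = interaction_energy(coords, charges, [0], [1])
        assert e.e_vdw == pytest.approx(0.0, abs=1e-12)
        assert e.e_elec == 0.0

    def test_matches_pair_loop_oracle(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(-5, 5, (4, 3))
        q = rng.uniform(-1, 1, 4)
        sig = rng.uniform(2, 4, 4)
        eps = rng.uniform(0.01, 0.3, 4)
        charges = ChargeModel(q, sig, eps)
        got = interaction_energy(coords, charges, [0, 1], [2, 3])
        elec = vdw = 0.0
        for i in (0, 1):
            for j in (2, 3):
                r = np.linalg.norm(coords[i] - coords[j])
                elec += COULOMB_CONSTANT * q[i] * q[j] / r
                s = 0.5 * (sig[i] + sig[j])
                e = np.sqrt(eps[i] * eps[j])
                vdw += 4 * e * ((s / r) ** 12 - (s / r) ** 6)
        assert got.e_elec == pytest.approx(elec, abs=1e-10)
        assert got.e_vdw == pytest.approx(vdw, abs=1e-10)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(-5, 5, (6, 3))
        charges = _toy_charges(rng.uniform(-1, 1, 6))
        ab = interaction_energy(coords, charges, [0, 1, 2], [3, 4, 5])
        ba = interaction_energy(coords, charges, [3, 4, 5], [0, 1, 2])
        assert ab.e_elec == pytest.approx(ba.e_elec, rel=1e-12)
        assert ab.e_vdw == pytest.approx(ba.e_vdw, rel=1e-12)

    def test_charge_scaling_quadruples_elec(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(-5, 5, (4, 3))
        q = rng.uniform(-1, 1, 4)
        e1 = interaction_energy(coords, _toy_charges(q), [0, 1], [2, 3])
        e2 = interaction_energy(coords, _toy_charges(2 * q), [0, 1], [2, 3])
        assert e2.e_elec == pytest.approx(4 * e1.e_elec, rel=1e-12)
        assert e2.e_vdw == pytest.approx(e1.e_vdw, rel=1e-12)

    def test_overlapping_atoms_rejected(self):
        coords = np.array([[0.0, 0, 0], [0.05, 0, 0]])
        with pytest.raises(DomainError):
            interaction_energy(coords, _toy_charges([1.0, 1.0]), [0], [1])

    def test_cutoff_skips_far_pairs(self):
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0], [50.0, 0, 0]])
        charges = _toy_charges([1.0, -1.0, -1.0], epsilon=0.0)
        e = interaction_energy(coords, charges, [0], [1, 2], cutoff=12.0)
        assert e.e_elec == pytest.approx(COULOMB_CONSTANT * -1 / 5.0, rel=1e-12)


class TestWindowedSeries:
    def _traj_with_distances(self, distances, dt=1.0):
        n = len(distances)
        coords = np.zeros((n, 2, 3))
        coords[:, 1, 0] = distances
        return Trajectory(coords, np.tile([1e3, 1e3, 1e3], (n, 1)),
                          dt * np.arange(n))

    def test_constant_energy(self):
        traj = self._traj_with_distances([COULOMB_CONSTANT / 5.0] * 30)
        charges = _toy_charges([1.0, -1.0], epsilon=0.0)
        df = windowed_binding_series(traj, charges, [0], [1], window_ns=10.0)
        assert np.allclose(df.e_mm, -5.0)
        assert np.allclose(df.stderr, 0.0)

    def test_step_series(self):
        # 20 ns at −2 then 20 ns at ≈0, 10-ns windows → [−2, −2, 0, 0]
        near = COULOMB_CONSTANT / 2.0
        far = 1.0e6
        traj = self._traj_with_distances([near] * 20 + [far] * 20)
        charges = _toy_charges([1.0, -1.0], epsilon=0.0)
        df = windowed_binding_series(traj, charges, [0], [1], window_ns=10.0)
        assert len(df) == 4
        assert np.allclose(df.e_mm, [-2.0, -2.0, 0.0, 0.0], atol=1e-3)

    def test_matches_streaming_oracle(self):
        rng = np.random.default_rng(3)
        dists = rng.uniform(3.0, 20.0, 25)
        traj = self._traj_with_distances(dists)
        charges = _toy_charges(rng.uniform(-1, 1, 2))
        df = windowed_binding_series(traj, charges, [0], [1], window_ns=5.0)
        per_frame = np.array([
            interaction_energy(traj.coords[f], charges, [0], [1]).e_mm
            for f in range(25)
        ])
        expected = [per_frame[a:b].mean() for a, b in
                    ((0, 5), (5, 10), (10, 15), (15, 20), (20, 25))]
        assert np.allclose(df.e_mm, expected)

    def test_window_longer_than_trajectory_rejected(self):
        traj = self._traj_with_distances([5.0] * 5)
        with pytest.raises(WindowError):
            windowed_binding_series(traj, _toy_charges([1.0, -1.0]), [0], [1],
                                    window_ns=100.0)


class TestPerResidue:
    def test_single_charged_residue_gets_all_elec(self):
        pspec = synth.PeptideSpec(com_z_path=np.full(2, 22.0))
        system, traj, _ = synth.generate_trajectory(
            peptide=pspec, n_frames=2, seed=0
        )
        charges = default_charge_model(system)
        # zero out all side-chain charges except Arg5
        for i in system.peptide_indices:
            if system.residue_indices[i] != 5:
                charges.q[i] = 0.0
        mem = np.concatenate(system.segment_atom_indices("S2"))
        df = per_residue_decomposition(traj, system, charges, mem)
        elec_by_res = df.set_index("residue")["e_elec"]
        assert abs(elec_by_res.drop(5)).max() == 0.0
        assert elec_by_res[5] != 0.0

    def test_additivity(self, small_run):
        system, traj, _ = small_run
        charges = default_charge_model(system)
        mem = np.concatenate(system.segment_atom_indices("S2"))
        df = per_residue_decomposition(traj, system, charges, mem)
        total = interaction_energy(
            traj.coords[0], charges, system.peptide_indices, mem
        )
        for f in range(1, traj.n_frames):
            e = interaction_energy(
                traj.coords[f], charges, system.peptide_indices, mem
            )
            total = type(total)(total.e_elec + e.e_elec, total.e_vdw + e.e_vdw)
        assert df.e_elec.sum() == pytest.approx(total.e_elec / traj.n_frames, abs=1e-6)
        assert df.e_vdw.sum() == pytest.approx(total.e_vdw / traj.n_frames, abs=1e-6)

    def test_far_peptide_with_cutoff_all_zero(self, small_run):
        system, traj, _ = small_run
        far = Trajectory(traj.coords.copy(), traj.box, traj.times)
        far.coords[:, system.peptide_indices, 2] += 500.0
        charges = default_charge_model(system)
        mem = np.concatenate(system.segment_atom_indices("S2"))
        df = per_residue_decomposition(far, system, charges, mem, cutoff=12.0)
        assert (df[["e_elec", "e_vdw", "e_mm"]].values == 0).all()


def test_calcium_bridge_sign_pattern():
    """A Ca²⁺ between a negative residue atom and a phosphate screens their
    repulsion: both ion-mediated terms attractive, the direct term repulsive."""
    system, traj, _ = synth.generate_trajectory(
        ions=synth.IonSpec(n_ca=5, placement="bridging"), n_frames=1, seed=1
    )
    charges = default_charge_model(system)
    coords = traj.coords[0]
    # pick the bridge around Glu22's carboxylate carbon
    res_atom = system.find_atom(22, "CD")
    ca_idx = system.ion_indices["CA"]
    ion = ca_idx[np.argmin(np.linalg.norm(coords[ca_idx] - coords[res_atom], axis=1))]
    p_idx = system.phosphorus_indices()
    phos = p_idx[np.argmin(np.linalg.norm(coords[p_idx] - coords[ion], axis=1))]
    e_ri = interaction_energy(coords, charges, [res_atom], [ion]).e_elec
    e_ip = interaction_energy(coords, charges, [ion], [phos]).e_elec
    e_rp = interaction_energy(coords, charges, [res_atom], [phos]).e_elec
    assert e_ri < 0 and e_ip < 0 and e_rp > 0
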