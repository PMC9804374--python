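import numpy as np
import pytest

from pepmem import synth
from pepmem.core import MolecularSystem, Trajectory


@pytest.fixture(scope="session")
def small_run():
    """A small but complete bilayer+peptide+ion run (16 lipids/leaflet)."""
    bspec = synth.BilayerSpec(lipids_per_leaflet=16, box_xy=(40.0, 40.0))
    pspec = synth.PeptideSpec(com_z_path=np.full(5, 25.0))
    ispec = synth.IonSpec(n_ca=8)
    return synth.generate_trajectory(bspec, pspec, ispec, n_frames=5, seed=42)


@pytest.fixture(scope="session")
def default_run():
    """Default-spec system (77 lipids/leaflet, 80 Ca²⁺), a few frames."""
    return synth.generate_trajectory(n_frames=5, seed=7)


def make_point_system(residue_names, positions, atom_names=None, elements=None,
                      masses=None, chains=None):
    """Minimal system: one or more residues with explicit single atoms."""
    n = len(positions)
    atom_names = atom_names or ["CA"] * n
    elements = elements or ["C"] * n
    masses = masses or [12.011] * n
    chains = chains or ["A"] * n
    res_ids = list(range(1, n + 1)) if isinstance(residue_names, str) else None
    if isinstance(residue_names, str):
        residue_names = [residue_names] * n
    if res_ids is None:
        res_ids = list(range(1, n + 1))
    return MolecularSystem(
        names=atom_names, residue_names=residue_names, residue_indices=res_ids,
        chain_ids=chains, elements=elements, masses=masses,
        coords=np.asarray(positions, float),
    )


def static_trajectory(coords, n_frames=1, box=(50.0, 50.0, 50.0), dt=1.0):
    """Trajectory repeating one coordinate set."""
    coords = np.asarray(coords, float)
    return Trajectory(
        np.tile(coords, (n_frames, 1, 1)),
        np.tile(np.asarray(box, float), (n_frames, 1)),
        dt * np.arange(n_frames),
    )
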