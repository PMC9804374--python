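"""Synthetic bilayer + peptide + ion trajectory generator with known ground truth.

The generator emulates the geometry and statistical structure of a
peptide–membrane simulation — a two-leaflet DMPC-like bilayer (77 lipids
per leaflet, leaflet phosphorus centers near ±Zp), a 42-residue peptide
with a controllable center-of-mass z-path, and Ca²⁺/Cl⁻ ions — without
any physics: lipids are coarse but atom-named realistically so that
segment rules and order-parameter analysis both apply, and every
quantity a downstream analysis estimates is planted with a known value
recorded in a :class:`TruthManifest`.

C–H bond orientations are drawn from a two-point mixture over the tilt
angle θ ∈ {0°, 90°} with weight w = (2·S + 1)/3 on θ = 0, which makes
the deuterium order parameter ⟨(3cos²θ − 1)/2⟩ exactly S.  This is
deliberately non-physical (a real chain samples a continuous
distribution); it is chosen because the target is exactly solvable, so
recovery tests have a closed-form expectation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import (
    ATOMIC_MASSES,
    DomainError,
    MolecularSystem,
    Trajectory,
    assign_lipid_segments,
    center_of_mass,
)
from .energetics import formal_charge

__all__ = [
    "AB42_SEQUENCE",
    "BilayerSpec",
    "PeptideSpec",
    "IonSpec",
    "TruthManifest",
    "PackingError",
    "generate_trajectory",
    "generate_ch_orientation",
    "sample_ch_orientations",
    "neutralize",
]

#: Human amyloid-β 1–42 sequence (one-letter codes).
AB42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"

AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: Representative charged-group atom per residue type (PDB naming):
#: Lys terminal amine N (NZ), Arg guanidinium N (NH1/NH2), Asp carboxylate
#: C (CG), Glu carboxylate C (CD).
REPRESENTATIVE_ATOM = {"K": "NZ", "R": "NH1", "D": "CG", "E": "CD"}


class PackingError(DomainError):
    """Requested lipid count exceeds the xy grid capacity."""


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class BilayerSpec:
    """Geometry and order-parameter targets for the synthetic bilayer."""

    lipids_per_leaflet: int = 77
    Zp: float = 17.0
    box_xy: Tuple[float, float] = (74.88, 74.37)
    box_z: float = 124.39
    head_z_sigma: float = 1.5
    chain_length: int = 13
    target_SCD: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.lipids_per_leaflet < 1:
            raise DomainError("lipids_per_leaflet must be ≥ 1")
        if 2 * self.Zp >= self.box_z:
            raise DomainError("box_z must exceed the bilayer thickness 2·Zp")
        if self.target_SCD is None:
            # smooth plateau-then-decay profile, qualitatively like a fluid
            # saturated chain: ~0.20 near the glycerol, ~0.05 at the terminus
            self.target_SCD = tuple(
                round(float(v), 4)
                for v in np.linspace(0.20, 0.05, self.chain_length)
            )
        self.target_SCD = tuple(float(v) for v in self.target_SCD)
        if len(self.target_SCD) != self.chain_length:
            raise DomainError("target_SCD must have one value per tail carbon")
        for v in self.target_SCD:
            if not -0.5 <= v <= 1.0:
                raise DomainError(f"target S_CD {v} outside [-0.5, 1]")


@dataclass
class PeptideSpec:
    """Sequence, conformation and motion plan for the synthetic peptide."""

    sequence: str = AB42_SEQUENCE
    com_z_path: Optional[Sequence[float]] = None  # per-frame COM z (Å); default constant 25
    conformation: str = "extended"  # extended | helix_C_term | hairpin_17_33
    planted_salt_bridges: Sequence[Tuple[int, int, Union[float, Sequence[float]]]] = ()
    planted_hbonds: Sequence[Tuple[int, int]] = ()  # (donor residue, acceptor residue)
    residue_z_offsets: Optional[Sequence[float]] = None
    cu_bound: bool = False
    noise_sigma: float = 0.0  # per-frame Gaussian jitter on peptide atoms (Å)

    def __post_init__(self) -> None:
        if any(c not in AA_1TO3 for c in self.sequence):
            raise DomainError("sequence contains non-standard one-letter codes")
        if self.conformation not in ("extended", "helix_C_term", "hairpin_17_33"):
            raise DomainError(f"unknown conformation {self.conformation!r}")
        for i, j, d in self.planted_salt_bridges:
            dist = np.atleast_1d(np.asarray(d, dtype=float))
            if np.any(dist <= 0):
                raise DomainError("planted salt-bridge distances must be > 0")


@dataclass
class IonSpec:
    """Calcium/chloride counts and placement mode."""

    n_ca: int = 80
    n_cl: Optional[int] = None  # default: exact neutralization
    placement: str = "bulk"  # bulk | interfacial | bridging

    def __post_init__(self) -> None:
        if self.n_ca < 0 or (self.n_cl is not None and self.n_cl < 0):
            raise DomainError("ion counts must be ≥ 0")
        if self.placement not in ("bulk", "interfacial", "bridging"):
            raise DomainError(f"unknown placement {self.placement!r}")


@dataclass
class TruthManifest:
    """Exact generator-side parameters, for parameter-recovery tests.

    Every field is the value the sampler actually used (or the exact
    noiseless frame-0 geometry it constructed), never a re-estimate
    from the emitted trajectory.
    """

    seed: int
    Zp_true: float
    A_L_true: float
    SCD_true: Tuple[float, ...]
    insertion_depth_true: Tuple[float, ...]
    insertion_class_true: Tuple[str, ...]
    planted_contacts: Tuple[Tuple[int, int], ...]
    planted_salt_bridges: Tuple[Tuple[int, int], ...]
    planted_hbonds: Tuple[Tuple[int, int, int], ...]
    surface_contact_residues: Tuple[int, ...]
    peptide_net_charge: int
    n_ca: int
    n_cl: int

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        for key in (
            "SCD_true", "insertion_depth_true", "insertion_class_true",
            "surface_contact_residues",
        ):
            d[key] = tuple(d[key])
        for key in ("planted_contacts", "planted_salt_bridges", "planted_hbonds"):
            d[key] = tuple(tuple(p) for p in d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# Elementary samplers
# ---------------------------------------------------------------------------

def sample_ch_orientations(
    targets: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Unit C–H vectors whose ⟨(3cos²θ − 1)/2⟩ equals ``targets`` element-wise.

    θ is drawn from {0, 90°} with P(θ=0) = (2·target + 1)/3; the azimuth
    is uniform.
    """
    targets = np.asarray(targets, dtype=float)
    if np.any((targets < -0.5) | (targets > 1.0)):
        raise DomainError("target S_CD outside [-0.5, 1]")
    w = (2.0 * targets + 1.0) / 3.0
    aligned = rng.random(targets.shape) < w
    phi = rng.uniform(0.0, 2.0 * np.pi, targets.shape)
    sin_t = np.where(aligned, 0.0, 1.0)
    cos_t = np.where(aligned, 1.0, 0.0)
    return np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=-1)


def generate_ch_orientation(target_scd: float, rng: np.random.Generator) -> np.ndarray:
    """Single unit C–H vector for one target order-parameter value."""
    return sample_ch_orientations(np.asarray([target_scd]), rng)[0]


def neutralize(peptide_charge: int, n_ca: int) -> int:
    """Number of Cl⁻ counter-ions that makes the total formal charge zero."""
    n_cl = int(peptide_charge) + 2 * int(n_ca)
    if n_cl < 0:
        raise DomainError(
            f"cannot neutralize: peptide charge {peptide_charge} with {n_ca} Ca²⁺ "
            "would require a negative Cl⁻ count"
        )
    return n_cl


# ---------------------------------------------------------------------------
# Peptide construction (ideal internal geometry via sequential placement)
# ---------------------------------------------------------------------------

_BOND_N_CA, _BOND_CA_C, _BOND_C_N = 1.458, 1.525, 1.329
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA = 111.0, 116.6, 121.7

_PHI_PSI = {
    "extended": lambda i, n: (-140.0, 135.0),
    "helix_C_term": lambda i, n: (-140.0, 135.0) if i < 28 else (-60.0, -45.0),
    "hairpin_17_33": lambda i, n: (-60.0, -30.0) if 23 <= i <= 25 else (-140.0, 135.0),
}


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place a new atom D given A-B-C with |CD|, ∠BCD and torsion A-B-C-D."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(-torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(sequence: str, conformation: str) -> np.ndarray:
    """(n_res, 3, 3) array of N, CA, C positions from ideal geometry."""
    n_res = len(sequence)
    phi_psi = _PHI_PSI[conformation]
    bb = np.zeros((n_res, 3, 3))
    bb[0, 0] = (0.0, 0.0, 0.0)                    # N
    bb[0, 1] = (_BOND_N_CA, 0.0, 0.0)             # CA
    ang = np.deg2rad(_ANG_N_CA_C)
    bb[0, 2] = bb[0, 1] + _BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res):
        phi, psi = phi_psi(i, n_res)
        if i > 0:
            # N(i): torsion psi(i-1) about N(i-1)-CA(i-1)-C(i-1)
            bb[i, 0] = _place_atom(bb[i - 1, 0], bb[i - 1, 1], bb[i - 1, 2],
                                   _BOND_C_N, _ANG_CA_C_N, phi_psi(i - 1, n_res)[1])
            # CA(i): omega = 180 about CA(i-1)-C(i-1)-N(i)
            bb[i, 1] = _place_atom(bb[i - 1, 1], bb[i - 1, 2], bb[i, 0],
                                   _BOND_N_CA, _ANG_C_N_CA, 180.0)
            # C(i): torsion phi(i) about C(i-1)-N(i)-CA(i)
            bb[i, 2] = _place_atom(bb[i - 1, 2], bb[i, 0], bb[i, 1],
                                   _BOND_CA_C, _ANG_N_CA_C, phi)
    return bb


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _build_peptide(spec: PeptideSpec):
    """Names/elements/residue ids/coords for the peptide, one atom list."""
    seq = spec.sequence
    bb = _build_backbone(seq, spec.conformation)
    names: List[str] = []
    elements: List[str] = []
    res_ids: List[int] = []
    res_names: List[str] = []
    coords: List[np.ndarray] = []

    def add(res_i: int, name: str, pos: np.ndarray) -> None:
        names.append(name)
        elements.append(name[0])
        res_ids.append(res_i + 1)
        res_names.append(AA_1TO3[seq[res_i]])
        coords.append(np.asarray(pos, dtype=float))

    for i, letter in enumerate(seq):
        n_pos, ca, c = bb[i]
        add(i, "N", n_pos)
        if i == 0:
            h = n_pos + 1.01 * _unit(n_pos - ca)
        else:
            h = n_pos + 1.01 * _unit(n_pos - 0.5 * (bb[i - 1, 2] + ca))
        add(i, "H", h)
        add(i, "CA", ca)
        add(i, "C", c)
        d1 = _unit(c - ca)
        ref = _unit(n_pos - ca)
        perp = _unit(np.cross(np.cross(d1, ref), d1))
        add(i, "O", c + 1.23 * perp)
        if letter != "G":
            side = _unit(np.cross(d1, ref))
            cb = ca + 1.53 * _unit(side - 0.4 * (d1 + ref))
            add(i, "CB", cb)
            rep = REPRESENTATIVE_ATOM.get(letter)
            if rep is not None:
                out = _unit(cb - ca)
                if letter == "K":
                    add(i, "NZ", cb + 3.3 * out)
                elif letter == "R":
                    lat = _unit(np.cross(out, d1))
                    add(i, "NH1", cb + 3.6 * out + 0.6 * lat)
                    add(i, "NH2", cb + 3.6 * out - 0.6 * lat)
                elif letter == "D":
                    add(i, "CG", cb + 1.5 * out)
                elif letter == "E":
                    add(i, "CD", cb + 2.6 * out)
    return names, elements, res_ids, res_names, np.asarray(coords)


# ---------------------------------------------------------------------------
# Lipid construction
# ---------------------------------------------------------------------------

_TAIL_STEP = 1.1   # Å per tail carbon toward the midplane
_CH_BOND = 1.09    # Å


def _build_lipid(x: float, y: float, sign: int, head_z: float, chain_length: int):
    """One coarse DMPC-like lipid.  Returns (names, elements, coords, ch_pairs).

    ``ch_pairs`` lists (carbon_local_index, hydrogen_local_index,
    tail_carbon_position) for the per-frame orientation resampler.
    """
    names: List[str] = []
    elements: List[str] = []
    coords: List[Tuple[float, float, float]] = []
    ch_pairs: List[Tuple[int, int, int]] = []

    def add(name: str, el: str, pos) -> int:
        names.append(name)
        elements.append(el)
        coords.append(tuple(pos))
        return len(names) - 1

    z = lambda dz: sign * (head_z + dz)
    add("N4", "N", (x + 0.5, y, z(2.0)))
    add("C15", "C", (x + 0.5, y + 1.0, z(2.8)))
    add("P", "P", (x, y, z(0.0)))
    add("O13", "O", (x + 0.6, y + 0.6, z(0.4)))
    add("O14", "O", (x - 0.6, y - 0.6, z(0.4)))
    add("CG1", "C", (x - 0.5, y, z(-1.5)))
    add("CG2", "C", (x, y + 0.5, z(-1.8)))
    add("CG3", "C", (x + 0.5, y, z(-2.1)))
    for chain, dx in ((2, -1.5), (3, 1.5)):
        for k in range(chain_length):
            letter = chr(65 + k)
            cz = head_z - 3.0 - _TAIL_STEP * k
            ci = add(f"C{chain}{letter}", "C", (x + dx, y, sign * cz))
            for h in "12":
                hi = add(f"H{chain}{letter}{h}", "H", (x + dx, y, sign * cz))
                ch_pairs.append((ci, hi, k))
    return names, elements, coords, ch_pairs


# ---------------------------------------------------------------------------
# Full-system generator
# ---------------------------------------------------------------------------

def generate_trajectory(
    bilayer: Optional[BilayerSpec] = None,
    peptide: Optional[PeptideSpec] = None,
    ions: Optional[IonSpec] = None,
    n_frames: int = 10,
    seed: int = 0,
    dt_ns: float = 1.0,
    surface_band: float = 6.5,
    include_peptide: bool = True,
) -> Tuple[MolecularSystem, Trajectory, TruthManifest]:
    """Generate a deterministic synthetic system, trajectory and truth manifest.

    Lipid head groups are placed on an xy grid with phosphorus z drawn
    once per lipid from N(±Zp, head_z_sigma); tail C–H orientations are
    resampled every frame from the exact two-point mixture for the
    per-carbon target order parameters.  The peptide is built from ideal
    backbone geometry and translated so its center of mass follows
    ``com_z_path``.  All randomness flows from ``seed``.
    """
    if n_frames < 1:
        raise DomainError("n_frames must be ≥ 1")
    bilayer = bilayer or BilayerSpec()
    peptide = peptide or PeptideSpec()
    ions = ions or IonSpec()
    rng = np.random.default_rng(seed)

    lx, ly = bilayer.box_xy
    names: List[str] = []
    elements: List[str] = []
    res_ids: List[int] = []
    res_names: List[str] = []
    chains: List[str] = []
    base: List[np.ndarray] = []
    charges: List[float] = []

    # ---- peptide ----------------------------------------------------------
    pep_charge = formal_charge(peptide.sequence, cu_bound=peptide.cu_bound)
    pep_atom_slice = slice(0, 0)
    if include_peptide:
        p_names, p_el, p_rid, p_rn, p_xyz = _build_peptide(peptide)
        p_xyz = p_xyz - p_xyz.mean(axis=0)
        # lay the chain flat: principal axes of inertia mapped to (x, y, z)
        # so the long axis is in-plane and residue z-offsets act cleanly
        _, _, vt = np.linalg.svd(p_xyz, full_matrices=False)
        p_xyz = p_xyz @ vt.T
        if peptide.residue_z_offsets is not None:
            offs = np.asarray(peptide.residue_z_offsets, dtype=float)
            if len(offs) != len(peptide.sequence):
                raise DomainError("residue_z_offsets must have one entry per residue")
            for a, rid in enumerate(p_rid):
                p_xyz[a, 2] += offs[rid - 1]
        for nm, el, rid, rn, xyz in zip(p_names, p_el, p_rid, p_rn, p_xyz):
            names.append(nm); elements.append(el)
            res_ids.append(rid); res_names.append(rn); chains.append("A")
            base.append(xyz)
            q = 0.0
            letter = peptide.sequence[rid - 1]
            if (letter, nm) in (("K", "NZ"),):
                q = 1.0
            elif letter == "R" and nm in ("NH1", "NH2"):
                q = 0.5
            elif (letter, nm) in (("D", "CG"), ("E", "CD")):
                q = -1.0
            charges.append(q)
        if peptide.cu_bound:
            # bound Cu²⁺ near the N-terminal coordination site (Asp1);
            # carries the metal's +2 so the formal-charge bookkeeping of
            # the Cu-bound peptide (−1 net for the default sequence) and
            # exact system neutrality both hold
            n_term = p_xyz[0]
            names.append("CU"); elements.append("Cu")
            res_ids.append(len(peptide.sequence) + 1); res_names.append("CU")
            chains.append("A"); base.append(n_term + np.array([0.0, 0.0, 2.0]))
            charges.append(2.0)
        pep_atom_slice = slice(0, len(names))

    # ---- bilayer ----------------------------------------------------------
    spacing = 8.0
    nx, ny = int(lx // spacing), int(ly // spacing)
    if nx * ny < bilayer.lipids_per_leaflet:
        raise PackingError(
            f"{bilayer.lipids_per_leaflet} lipids/leaflet exceed the "
            f"{nx}×{ny} grid capacity at box {lx:.2f}×{ly:.2f} Å"
        )
    ch_registry: List[Tuple[int, int, int]] = []  # (C index, H index, carbon pos)
    lipid_res = 0
    p_atom_indices: List[int] = []
    lipid_atom_owner: List[Tuple[int, int]] = []  # (atom index, lipid ordinal)
    for leaf_sign in (1, -1):
        for k in range(bilayer.lipids_per_leaflet):
            gx, gy = k % nx, k // nx
            x = (gx + 0.5) * lx / nx - lx / 2.0
            y = (gy + 0.5) * ly / ny - ly / 2.0
            l_names, l_el, l_xyz, l_ch = _build_lipid(
                x, y, leaf_sign, bilayer.Zp, bilayer.chain_length
            )
            offset = len(names)
            lipid_res += 1
            lipid_atom_owner.extend(
                (offset + a, lipid_res - 1) for a in range(len(l_names))
            )
            for nm, el, xyz in zip(l_names, l_el, l_xyz):
                names.append(nm); elements.append(el)
                res_ids.append(lipid_res); res_names.append("DMP"); chains.append("L")
                base.append(np.asarray(xyz))
                charges.append({"P": -1.0, "N4": 1.0}.get(nm, 0.0))
                if nm == "P":
                    p_atom_indices.append(offset + l_names.index("P"))
            for ci, hi, carbon in l_ch:
                ch_registry.append((offset + ci, offset + hi, carbon))

    # ---- ions --------------------------------------------------------------
    n_cl = ions.n_cl if ions.n_cl is not None else neutralize(pep_charge, ions.n_ca)
    ion_res = lipid_res
    ca_start = len(names)
    bridging_targets: List[Tuple[int, int]] = []  # (charged atom idx, P atom idx)
    if ions.placement == "bridging" and include_peptide:
        rep_atoms = [
            a for a in range(pep_atom_slice.stop)
            if charges[a] != 0.0 and names[a] in ("NZ", "NH1", "CG", "CD")
        ]
        upper_p = [i for i in p_atom_indices if base[i][2] > 0]
        for a in rep_atoms:
            nearest = min(upper_p, key=lambda i: np.linalg.norm(base[a][:2] - base[i][:2]))
            base[a] = base[nearest] + np.array([0.0, 0.0, 3.0])
            bridging_targets.append((a, nearest))
    bridge_ions: List[Tuple[int, int, int, np.ndarray]] = []  # (ion, charged, P, jitter)
    for k in range(ions.n_ca):
        ion_res += 1
        if ions.placement == "bridging" and bridging_targets:
            a, p = bridging_targets[k % len(bridging_targets)]
            jit = rng.normal(0.0, 0.1, 3)
            pos = 0.5 * (base[a] + base[p]) + jit
            bridge_ions.append((len(names), a, p, jit))
        elif ions.placement == "interfacial":
            s = 1 if k % 2 == 0 else -1
            pos = np.array([
                rng.uniform(-lx / 2, lx / 2), rng.uniform(-ly / 2, ly / 2),
                s * (bilayer.Zp + 2.0),
            ])
        else:
            s = 1 if k % 2 == 0 else -1
            pos = np.array([
                rng.uniform(-lx / 2, lx / 2), rng.uniform(-ly / 2, ly / 2),
                s * rng.uniform(bilayer.Zp + 8.0, bilayer.box_z / 2.0 - 3.0),
            ])
        names.append("CA"); elements.append("Ca")
        res_ids.append(ion_res); res_names.append("CA"); chains.append("I")
        base.append(pos); charges.append(2.0)
    for k in range(n_cl):
        ion_res += 1
        s = 1 if k % 2 == 0 else -1
        pos = np.array([
            rng.uniform(-lx / 2, lx / 2), rng.uniform(-ly / 2, ly / 2),
            s * rng.uniform(bilayer.Zp + 8.0, bilayer.box_z / 2.0 - 3.0),
        ])
        names.append("CL"); elements.append("Cl")
        res_ids.append(ion_res); res_names.append("CL"); chains.append("I")
        base.append(pos); charges.append(-1.0)

    masses = [ATOMIC_MASSES[str(e).upper()] for e in elements]
    base_arr = np.asarray(base)
    system = MolecularSystem(
        names=names, residue_names=res_names, residue_indices=res_ids,
        chain_ids=chains, elements=elements, masses=masses,
        coords=base_arr.copy(), charges=charges,
    )
    assign_lipid_segments(system)

    # ---- frames ------------------------------------------------------------
    com_path = peptide.com_z_path
    if com_path is None:
        com_path = np.full(n_frames, 25.0)
    com_path = np.asarray(com_path, dtype=float)
    if com_path.shape == ():
        com_path = np.full(n_frames, float(com_path))
    if len(com_path) != n_frames:
        raise DomainError("com_z_path must have one value per frame")

    pep_idx = np.arange(pep_atom_slice.stop) if include_peptide else np.array([], int)
    pep_masses = np.asarray(masses)[pep_idx] if include_peptide else None
    targets = np.asarray(bilayer.target_SCD)
    ch = np.asarray(ch_registry, dtype=int) if ch_registry else np.zeros((0, 3), int)
    carbon_targets = targets[ch[:, 2]] if len(ch) else np.zeros(0)

    sb_atoms: List[Tuple[int, int]] = []
    sb_dists: List[np.ndarray] = []
    for (ri, rj, d) in peptide.planted_salt_bridges:
        ai = _find_peptide_atom(names, res_ids, pep_atom_slice, ri,
                                REPRESENTATIVE_ATOM[peptide.sequence[ri - 1]])
        aj = _find_peptide_atom(names, res_ids, pep_atom_slice, rj,
                                REPRESENTATIVE_ATOM[peptide.sequence[rj - 1]])
        dist = np.atleast_1d(np.asarray(d, dtype=float))
        if dist.size == 1:
            dist = np.full(n_frames, dist[0])
        if dist.size != n_frames:
            raise DomainError("per-frame salt-bridge schedule length mismatch")
        sb_atoms.append((ai, aj))
        sb_dists.append(dist)

    hb_triples: List[Tuple[int, int, int]] = []
    for (rd, ra) in peptide.planted_hbonds:
        ni = _find_peptide_atom(names, res_ids, pep_atom_slice, rd, "N")
        hi = _find_peptide_atom(names, res_ids, pep_atom_slice, rd, "H")
        oi = _find_peptide_atom(names, res_ids, pep_atom_slice, ra, "O")
        hb_triples.append((ni, hi, oi))

    u_sb = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)

    lip_flat = np.asarray([a for a, _ in lipid_atom_owner], dtype=int)
    lip_owner = np.asarray([o for _, o in lipid_atom_owner], dtype=int)
    n_lipids_total = lipid_res

    def make_frame(f: int, with_noise: bool) -> np.ndarray:
        xyz = base_arr.copy()
        # per-frame rigid z displacement of each lipid emulates head-group
        # thermal motion: phosphorus z ~ N(±Zp, head_z_sigma) across frames
        if with_noise and n_lipids_total and bilayer.head_z_sigma > 0:
            dz = rng.normal(0.0, bilayer.head_z_sigma, n_lipids_total)
            xyz[lip_flat, 2] += dz[lip_owner]
        if len(ch):
            dirs = sample_ch_orientations(
                np.tile(carbon_targets, 1), rng
            )
            xyz[ch[:, 1]] = xyz[ch[:, 0]] + _CH_BOND * dirs
        if include_peptide:
            cur = center_of_mass(xyz, np.asarray(masses), pep_idx)
            xyz[pep_idx, 2] += com_path[f] - cur[2]
            for (ai, aj), dist in zip(sb_atoms, sb_dists):
                xyz[aj] = xyz[ai] + dist[f] * u_sb
            for (ni, hi, oi) in hb_triples:
                xyz[oi] = xyz[hi] + 1.9 * _unit(xyz[hi] - xyz[ni])
            # re-pin bridging geometry after the COM translation so the
            # ion sits between the charged atom and its phosphate every frame
            for (a, p) in bridging_targets:
                xyz[a] = xyz[p] + np.array([0.0, 0.0, 3.0])
            for (ion, a, p, jit) in bridge_ions:
                xyz[ion] = 0.5 * (xyz[a] + xyz[p]) + jit
            if with_noise and peptide.noise_sigma > 0:
                xyz[pep_idx] += rng.normal(0.0, peptide.noise_sigma, (len(pep_idx), 3))
        return xyz

    # noiseless frame 0 for the manifest (uses its own rng so the emitted
    # trajectory's stream is unaffected by manifest construction)
    manifest_rng = np.random.default_rng(seed)
    saved_rng, rng = rng, manifest_rng
    frame0 = make_frame(0, with_noise=False)
    rng = saved_rng

    frames = np.empty((n_frames, len(names), 3))
    for f in range(n_frames):
        frames[f] = make_frame(f, with_noise=True)
    box = np.tile([lx, ly, bilayer.box_z], (n_frames, 1))
    traj = Trajectory(frames, box, dt_ns * np.arange(n_frames))

    manifest = _build_manifest(
        system, frame0, bilayer, peptide, ions, seed, n_cl,
        pep_charge, sb_atoms, hb_triples, surface_band,
    )
    return system, traj, manifest


def _find_peptide_atom(names, res_ids, pep_slice: slice, residue: int, name: str) -> int:
    for a in range(pep_slice.stop):
        if res_ids[a] == residue and names[a] == name:
            return a
    raise DomainError(f"peptide residue {residue} has no atom {name!r}")


def _build_manifest(
    system: MolecularSystem, frame0: np.ndarray, bilayer: BilayerSpec,
    peptide: PeptideSpec, ions: IonSpec, seed: int, n_cl: int,
    pep_charge: int, sb_atoms, hb_triples, surface_band: float,
) -> TruthManifest:
    res_atoms = system.peptide_residue_atom_indices()
    depths: List[float] = []
    classes: List[str] = []
    res_coms = []
    for idx in res_atoms:
        com = center_of_mass(frame0, system.masses, idx)
        res_coms.append(com)
        depth = abs(float(com[2]))
        depths.append(depth)
        if depth < bilayer.Zp:
            classes.append("inserted")
        elif depth <= bilayer.Zp + surface_band:
            classes.append("surface")
        else:
            classes.append("detached")
    res_coms = np.asarray(res_coms) if res_coms else np.zeros((0, 3))
    contacts: List[Tuple[int, int]] = []
    for i in range(len(res_coms)):
        for j in range(i + 1, len(res_coms)):
            if np.linalg.norm(res_coms[i] - res_coms[j]) < 6.5:
                contacts.append((i + 1, j + 1))
    surface_res: List[int] = []
    if system.lipids and len(res_coms):
        seg_coms = []
        for seg in ("S1", "S2", "S3", "S4"):
            for idx in system.segment_atom_indices(seg):
                seg_coms.append(center_of_mass(frame0, system.masses, idx))
        seg_coms = np.asarray(seg_coms)
        for r, com in enumerate(res_coms):
            if np.min(np.linalg.norm(seg_coms - com, axis=1)) <= 6.5:
                surface_res.append(r + 1)
    return TruthManifest(
        seed=seed,
        Zp_true=bilayer.Zp,
        A_L_true=bilayer.box_xy[0] * bilayer.box_xy[1] / bilayer.lipids_per_leaflet,
        SCD_true=tuple(bilayer.target_SCD),
        insertion_depth_true=tuple(depths),
        insertion_class_true=tuple(classes),
        planted_contacts=tuple(contacts),
        planted_salt_bridges=tuple(
            (int(system.residue_indices[a]), int(system.residue_indices[b]))
            for a, b in sb_atoms
        ),
        planted_hbonds=tuple((int(n), int(h), int(o)) for n, h, o in hb_triples),
        surface_contact_residues=tuple(surface_res),
        peptide_net_charge=pep_charge,
        n_ca=ions.n_ca,
        n_cl=n_cl,
    )
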