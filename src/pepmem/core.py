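"""Core containers and geometry shared by every analysis stage.

Conventions used throughout the package: coordinates in Å, time in ns,
masses in amu, charges in elementary-charge units, 1-based residue
numbering (Asp1 … Ala42 for the default amyloid-β peptide).  Boxes are
orthorhombic and molecules are assumed whole (no minimum-image
reconstruction inside center-of-mass calculations); a validation helper
flags suspiciously long intramolecular distances as wrapping artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "AtomRecord",
    "MolecularSystem",
    "Trajectory",
    "RegionMap",
    "ObservableSeries",
    "Lipid",
    "PepmemError",
    "FormatError",
    "ClassificationError",
    "MappingError",
    "TopologyError",
    "ShapeError",
    "WindowError",
    "MidplaneError",
    "DomainError",
    "center_of_mass",
    "assign_peptide_regions",
    "assign_lipid_segments",
    "flag_wrapping_artifacts",
    "ATOMIC_MASSES",
    "AMINO_ACIDS_3",
    "DEFAULT_RESIDUE_CLASSES",
    "DEFAULT_SEGMENT_RULES",
    "AA_3TO1",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class PepmemError(Exception):
    """Base class for all package errors."""


class FormatError(PepmemError):
    """Unparseable structure/trajectory record."""


class ClassificationError(PepmemError):
    """Residue name not covered by the residue-class dictionary."""


class MappingError(PepmemError):
    """Atom names not covered by a segment/selection rule set."""


class TopologyError(PepmemError):
    """Required atoms (hydrogens, Cα, representative atoms) missing."""


class ShapeError(PepmemError):
    """Frame/atom-count mismatch."""


class WindowError(PepmemError):
    """Requested analysis window empty or outside the trajectory."""


class MidplaneError(PepmemError):
    """Bilayer reference (phosphorus midplane) not computable."""


class DomainError(PepmemError):
    """Argument outside the mathematical domain of an operation."""


# ---------------------------------------------------------------------------
# Chemical bookkeeping tables (editable config)
# ---------------------------------------------------------------------------

#: Standard atomic weights (amu) for the elements this package handles.
ATOMIC_MASSES: Dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "NA": 22.990, "CL": 35.45, "K": 39.098, "CA": 40.078,
    "MG": 24.305, "CU": 63.546, "ZN": 65.38, "FE": 55.845,
}

AMINO_ACIDS_3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID", "HIE", "HIP",
}

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "HID": "H",
    "HIE": "H", "HIP": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T",
    "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: residue-name → class ("peptide" | "lipid" | "ion" | "water").
DEFAULT_RESIDUE_CLASSES: Dict[str, str] = {
    **{aa: "peptide" for aa in AMINO_ACIDS_3},
    "DMP": "lipid", "DMPC": "lipid", "DMC": "lipid", "PC": "lipid",
    "CA": "ion", "CAL": "ion", "CL": "ion", "CLA": "ion", "NA": "ion",
    "K": "ion", "CU": "ion",
    "HOH": "water", "WAT": "water", "TIP3": "water", "SOL": "water", "SPC": "water",
}

#: atom-name → lipid segment for the generator's DMPC-like lipid.
#: S1 choline, S2 phosphate, S3 glycerol, S4/S5 the two acyl tails.
DEFAULT_SEGMENT_RULES: Dict[str, str] = {
    "N4": "S1", "C15": "S1",
    "P": "S2", "O13": "S2", "O14": "S2",
    "CG1": "S3", "CG2": "S3", "CG3": "S3",
}
for _letter in "ABCDEFGHIJKLMNOPQRST":
    DEFAULT_SEGMENT_RULES[f"C2{_letter}"] = "S4"
    DEFAULT_SEGMENT_RULES[f"C3{_letter}"] = "S5"
    for _h in "12":
        DEFAULT_SEGMENT_RULES[f"H2{_letter}{_h}"] = "S4"
        DEFAULT_SEGMENT_RULES[f"H3{_letter}{_h}"] = "S5"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    """A single atom as read from (or written to) a PDB ATOM/HETATM record."""

    serial: int
    name: str
    residue_name: str
    residue_index: int
    chain_id: str
    element: str
    mass: float
    position: np.ndarray
    partial_charge: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.mass <= 0:
            raise DomainError(f"atom {self.serial}: mass must be > 0, got {self.mass}")
        if self.residue_index < 1:
            raise DomainError(f"atom {self.serial}: residue_index must be ≥ 1")
        if not np.all(np.isfinite(self.position)):
            raise DomainError(f"atom {self.serial}: non-finite position")


@dataclass
class Lipid:
    """One lipid molecule: its atom indices, leaflet tag and segment labels."""

    indices: np.ndarray
    leaflet: str  # "upper" | "lower"
    segments: Dict[str, np.ndarray] = field(default_factory=dict)


class MolecularSystem:
    """Topology + static metadata for a peptide/bilayer/ion system.

    Atom attributes are stored as parallel numpy arrays in file order.
    The peptide/lipid/ion/water partition is inferred from residue names
    via a configurable class dictionary and is guaranteed disjoint.
    """

    def __init__(
        self,
        names: Sequence[str],
        residue_names: Sequence[str],
        residue_indices: Sequence[int],
        chain_ids: Sequence[str],
        elements: Sequence[str],
        masses: Sequence[float],
        coords: np.ndarray,
        charges: Optional[Sequence[float]] = None,
        residue_classes: Optional[Mapping[str, str]] = None,
    ) -> None:
        n = len(names)
        self.names = np.asarray(names, dtype=object)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.residue_indices = np.asarray(residue_indices, dtype=int)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.masses = np.asarray(masses, dtype=float)
        self.coords = np.asarray(coords, dtype=float).reshape(n, 3)
        self.charges = (
            np.zeros(n) if charges is None else np.asarray(charges, dtype=float)
        )
        if np.any(self.masses <= 0):
            bad = np.flatnonzero(self.masses <= 0)[0]
            raise DomainError(f"atom {bad}: mass must be > 0")
        self._classes = dict(residue_classes or DEFAULT_RESIDUE_CLASSES)
        self._partition()

    # -- partition ----------------------------------------------------------

    def _partition(self) -> None:
        classes = np.empty(self.n_atoms, dtype=object)
        for i, rn in enumerate(self.residue_names):
            cls = self._classes.get(str(rn).strip().upper())
            if cls is None:
                raise ClassificationError(
                    f"residue name {rn!r} is not in the residue-class dictionary; "
                    "add it to residue_classes"
                )
            classes[i] = cls
        self.atom_classes = classes
        self.peptide_indices = np.flatnonzero(classes == "peptide")
        self.water_indices = np.flatnonzero(classes == "water")
        ion_mask = classes == "ion"
        self.ion_indices: Dict[str, np.ndarray] = {}
        for sp in sorted({str(r).strip().upper() for r in self.residue_names[ion_mask]}):
            self.ion_indices[sp] = np.flatnonzero(
                ion_mask & (np.char.upper(self.residue_names.astype(str)) == sp)
            )
        # group lipid atoms into molecules by (chain, residue index)
        lipid_mask = classes == "lipid"
        self.lipids: List[Lipid] = []
        if lipid_mask.any():
            keys = [
                (self.chain_ids[i], self.residue_indices[i])
                for i in np.flatnonzero(lipid_mask)
            ]
            seen: Dict[Tuple[str, int], List[int]] = {}
            for idx, key in zip(np.flatnonzero(lipid_mask), keys):
                seen.setdefault(key, []).append(int(idx))
            for key in seen:
                self.lipids.append(Lipid(np.asarray(seen[key]), leaflet=""))
            self._tag_leaflets()
        # peptide residues in order of first appearance
        self.peptide_residues: List[Tuple[int, str]] = []
        seen_res: set = set()
        for i in self.peptide_indices:
            key = int(self.residue_indices[i])
            if key not in seen_res:
                seen_res.add(key)
                self.peptide_residues.append((key, str(self.residue_names[i])))

    def _tag_leaflets(self) -> None:
        p_z = []
        for lip in self.lipids:
            p = [i for i in lip.indices if str(self.elements[i]).upper() == "P"]
            p_z.append(self.coords[p[0], 2] if p else np.mean(self.coords[lip.indices, 2]))
        mid = float(np.mean(p_z))
        for lip, z in zip(self.lipids, p_z):
            lip.leaflet = "upper" if z >= mid else "lower"
        # degenerate case (all heads at one z): split by rank so both
        # leaflets stay non-empty and a zero thickness is reportable
        if len(self.lipids) > 1 and all(l.leaflet == "upper" for l in self.lipids):
            order = np.argsort(p_z, kind="stable")
            for k in order[: len(order) // 2]:
                self.lipids[k].leaflet = "lower"

    # -- convenience --------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def sequence(self) -> str:
        """Peptide sequence as a one-letter string."""
        return "".join(AA_3TO1.get(rn.upper(), "X") for _, rn in self.peptide_residues)

    def peptide_residue_atom_indices(self) -> List[np.ndarray]:
        """Atom index arrays, one per peptide residue, in residue order."""
        out = []
        for rid, _ in self.peptide_residues:
            mask = (self.atom_classes == "peptide") & (self.residue_indices == rid)
            out.append(np.flatnonzero(mask))
        return out

    def phosphorus_indices(self, leaflet: Optional[str] = None) -> np.ndarray:
        idx: List[int] = []
        for lip in self.lipids:
            if leaflet is not None and lip.leaflet != leaflet:
                continue
            idx.extend(
                int(i) for i in lip.indices if str(self.elements[i]).upper() == "P"
            )
        return np.asarray(idx, dtype=int)

    def segment_atom_indices(self, segment: str) -> List[np.ndarray]:
        """Per-lipid atom indices of one segment (S1..S5)."""
        out = []
        for lip in self.lipids:
            if segment not in lip.segments:
                raise MappingError(
                    f"segment {segment!r} not assigned; run assign_lipid_segments first"
                )
            out.append(lip.segments[segment])
        return out

    def find_atom(self, residue_index: int, name: str) -> int:
        """Index of a uniquely named atom in a peptide residue."""
        mask = (self.residue_indices == residue_index) & (self.names == name) & (
            self.atom_classes == "peptide"
        )
        hits = np.flatnonzero(mask)
        if len(hits) == 0:
            raise TopologyError(
                f"atom {name!r} not found in peptide residue {residue_index}"
            )
        return int(hits[0])


@dataclass
class Trajectory:
    """Ordered frames of positions with orthorhombic boxes and times (ns)."""

    coords: np.ndarray  # (F, N, 3) Å
    box: np.ndarray     # (F, 3) Å
    times: np.ndarray   # (F,) ns

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float).reshape(-1, 3)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ShapeError(f"coords must be (F, N, 3), got {self.coords.shape}")
        f = self.coords.shape[0]
        if self.box.shape[0] != f or self.times.shape[0] != f:
            raise ShapeError("box/times length must equal the number of frames")
        if np.any(self.box <= 0):
            raise DomainError("box components must be > 0")
        if f > 1 and np.any(np.diff(self.times) <= 0):
            raise DomainError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def window(self, frame_slice: slice) -> "Trajectory":
        return Trajectory(self.coords[frame_slice], self.box[frame_slice], self.times[frame_slice])


@dataclass
class RegionMap:
    """Peptide region bounds (1-based, inclusive).

    Defaults follow the standard amyloid-β partition: hydrophilic
    N-terminus R1 (1–16), central hydrophobic region R2 (17–21), loop
    R3 (22–28) and hydrophobic C-terminus R4 (29–42).
    """

    R1: Tuple[int, int] = (1, 16)
    R2: Tuple[int, int] = (17, 21)
    R3: Tuple[int, int] = (22, 28)
    R4: Tuple[int, int] = (29, 42)

    def bounds(self) -> Dict[str, Tuple[int, int]]:
        return {"R1": self.R1, "R2": self.R2, "R3": self.R3, "R4": self.R4}

    def validate(self, n_residues: int) -> None:
        items = sorted(self.bounds().items(), key=lambda kv: kv[1][0])
        prev_hi = 0
        for name, (lo, hi) in items:
            if lo > hi:
                raise DomainError(f"region {name}: lower bound {lo} > upper bound {hi}")
            if lo != prev_hi + 1:
                raise DomainError(
                    f"regions must be contiguous and disjoint; {name} starts at {lo}, "
                    f"expected {prev_hi + 1}"
                )
            prev_hi = hi
        if prev_hi != n_residues:
            raise DomainError(
                f"regions cover 1..{prev_hi} but the peptide has {n_residues} residues"
            )

    def region_of(self, residue: int) -> str:
        for name, (lo, hi) in self.bounds().items():
            if lo <= residue <= hi:
                return name
        raise DomainError(f"residue {residue} outside all regions")


@dataclass
class ObservableSeries:
    """A per-frame (or per-window) scalar observable with units."""

    times: np.ndarray
    values: np.ndarray
    name: str = ""
    units: str = ""
    stderr: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sem(self) -> float:
        """Standard error of the mean over entries (no autocorrelation correction)."""
        n = len(self.values)
        if n < 2:
            return 0.0
        return float(np.std(self.values, ddof=1) / np.sqrt(n))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def center_of_mass(
    positions: np.ndarray, masses: np.ndarray, indices: Optional[Iterable[int]] = None
) -> np.ndarray:
    """Mass-weighted mean position of a set of atoms.

    No periodic unwrapping is performed: molecules are assumed whole.
    """
    positions = np.asarray(positions, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if indices is not None:
        indices = np.asarray(list(indices) if not isinstance(indices, np.ndarray) else indices, dtype=int)
        if indices.size == 0:
            raise DomainError("center_of_mass: empty index set")
        positions = positions[indices]
        masses = masses[indices]
    if positions.shape[0] == 0:
        raise DomainError("center_of_mass: empty index set")
    if np.any(masses <= 0):
        raise DomainError("center_of_mass: masses must be positive")
    return (masses[:, None] * positions).sum(axis=0) / masses.sum()


def assign_peptide_regions(
    n_residues: int, bounds: Optional[RegionMap] = None
) -> Dict[int, str]:
    """Map each 1-based residue index to its region label (R1..R4)."""
    bounds = bounds or RegionMap()
    bounds.validate(n_residues)
    return {r: bounds.region_of(r) for r in range(1, n_residues + 1)}


def assign_lipid_segments(
    system: MolecularSystem, rules: Optional[Mapping[str, str]] = None
) -> MolecularSystem:
    """Label every lipid atom with one segment S1..S5 (in place; returns system).

    ``rules`` maps atom names to segment labels; every lipid atom name must
    be covered.  After assignment each lipid's S2 set contains its
    phosphorus atom.
    """
    rules = dict(rules or DEFAULT_SEGMENT_RULES)
    uncovered: set = set()
    assignments: List[Dict[str, np.ndarray]] = []
    for lip in system.lipids:
        seg_map: Dict[str, List[int]] = {}
        for i in lip.indices:
            name = str(system.names[i]).strip()
            seg = rules.get(name)
            if seg is None:
                uncovered.add(name)
                continue
            seg_map.setdefault(seg, []).append(int(i))
        assignments.append({s: np.asarray(v, dtype=int) for s, v in seg_map.items()})
    if uncovered:
        raise MappingError(
            "lipid atom names not covered by segment rules: "
            + ", ".join(sorted(uncovered))
        )
    for lip, seg_map in zip(system.lipids, assignments):
        lip.segments = seg_map
    return system


def flag_wrapping_artifacts(
    system: MolecularSystem, coords: Optional[np.ndarray] = None, threshold: float = 5.0
) -> List[Tuple[int, int, float]]:
    """Flag consecutive intra-molecule atom pairs farther apart than ``threshold`` Å.

    A cheap whole-molecule sanity check: the package assumes unwrapped
    coordinates, and a bonded-scale gap larger than ~5 Å usually means a
    molecule was split across the periodic boundary.
    """
    coords = system.coords if coords is None else np.asarray(coords)
    flags: List[Tuple[int, int, float]] = []
    groups: List[np.ndarray] = [lip.indices for lip in system.lipids]
    groups.extend(system.peptide_residue_atom_indices())
    for idx in groups:
        if len(idx) < 2:
            continue
        sub = coords[idx]
        d = np.sqrt(((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2))
        np.fill_diagonal(d, np.inf)
        nearest = d.min(axis=1)
        for k in np.flatnonzero(nearest > threshold):
            j = int(np.argmin(d[k]))
            flags.append((int(idx[k]), int(idx[j]), float(nearest[k])))
    return flags
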