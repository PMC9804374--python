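"""Contacts, salt bridges, hydrogen bonds and membrane-insertion profiling.

Conventions:

* residue–residue contact: center-of-mass distance strictly below the
  6.5 Å cutoff (a Cα-based mode is also available);
* peptide–lipid contact: min-over-lipids segment COM distance ≤ 6.5 Å,
  by default against segments S1–S4 (S5 available on request);
* sequence-separation classes: local < 6, short 6–11, medium 12–23,
  long ≥ 24 (the boundary value 24 is long so the classes partition);
* salt bridge: representative-atom distance r with r − d₀ ≤ 0,
  d₀ = 4.5 Å; Lys uses NZ, Arg the nearer of NH1/NH2, Asp CG, Glu CD;
* hydrogen bond: X–Y distance < 3.5 Å and X–H···Y angle at H > 135°.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    DomainError,
    MappingError,
    MidplaneError,
    MolecularSystem,
    ObservableSeries,
    TopologyError,
    Trajectory,
    WindowError,
    center_of_mass,
)
from .bilayer import midplane_z

__all__ = [
    "ContactMap",
    "SaltBridgeTable",
    "InsertionProfile",
    "residue_contact_map",
    "classify_contact_range",
    "peptide_lipid_contacts",
    "salt_bridges",
    "salt_bridge_distance_series",
    "hydrogen_bonds",
    "insertion_profile",
    "com_distance_series",
    "enumerate_salt_bridge_pairs",
    "representative_atom_index",
]

_POS_RES = {"ARG", "LYS"}
_NEG_RES = {"ASP", "GLU"}


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class ContactMap:
    """Residue-pair contact frequencies (% of frames)."""

    matrix: np.ndarray  # (n_res, n_res), symmetric, diagonal 0
    residues: np.ndarray
    cutoff: float
    mode: str  # "com" | "ca"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        n = len(self.residues)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({
                    "i": int(self.residues[i]), "j": int(self.residues[j]),
                    "pct": self.matrix[i, j],
                    "range_class": classify_contact_range(
                        int(self.residues[i]), int(self.residues[j])
                    ),
                })
        return pd.DataFrame(rows)


@dataclass
class SaltBridgeTable:
    """Per-pair salt-bridge occupancy with the per-frame total count."""

    table: pd.DataFrame  # pos_residue, neg_residue, occupancy_pct, atoms
    counts: ObservableSeries
    d0: float


@dataclass
class InsertionProfile:
    """Per-residue |z| histograms, modal depths and insertion classes."""

    residues: np.ndarray
    depth_edges: np.ndarray
    histograms: np.ndarray  # (n_res, n_bins), each row sums to 1
    modal_depth: np.ndarray
    classification: List[str]  # inserted | surface | detached
    Zp: float
    surface_band: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "residue": self.residues,
            "modal_depth": self.modal_depth,
            "class": self.classification,
        })


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _frame_window(trajectory: Trajectory, window: Optional[Sequence[int]]) -> np.ndarray:
    frames = (np.arange(trajectory.n_frames) if window is None
              else np.asarray(list(window), int))
    if frames.size == 0:
        raise WindowError("empty analysis window")
    return frames


def _residue_coms(
    trajectory: Trajectory, system: MolecularSystem, frames: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """(len(frames), n_res, 3) residue COM array + residue ids."""
    res_atoms = system.peptide_residue_atom_indices()
    if len(res_atoms) < 1:
        raise DomainError("system has no peptide residues")
    out = np.empty((len(frames), len(res_atoms), 3))
    for fi, f in enumerate(frames):
        for r, idx in enumerate(res_atoms):
            out[fi, r] = center_of_mass(trajectory.coords[f], system.masses, idx)
    ids = np.asarray([rid for rid, _ in system.peptide_residues])
    return out, ids


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def classify_contact_range(i: int, j: int) -> str:
    """Sequence-separation class of a residue pair."""
    if i == j:
        raise DomainError("contact range undefined for i == j")
    s = abs(i - j)
    if s >= 24:
        return "long"
    if s >= 12:
        return "medium"
    if s >= 6:
        return "short"
    return "local"


def residue_contact_map(
    trajectory: Trajectory,
    system: MolecularSystem,
    cutoff: float = 6.5,
    window: Optional[Sequence[int]] = None,
    mode: str = "com",
) -> ContactMap:
    """Intramolecular residue contact map: % of frames with distance < cutoff."""
    frames = _frame_window(trajectory, window)
    if mode == "com":
        coms, ids = _residue_coms(trajectory, system, frames)
    elif mode == "ca":
        ids = np.asarray([rid for rid, _ in system.peptide_residues])
        ca = [system.find_atom(int(r), "CA") for r in ids]
        coms = trajectory.coords[np.ix_(frames, ca)]
    else:
        raise DomainError(f"unknown contact mode {mode!r}")
    if coms.shape[1] < 2:
        raise DomainError("contact map requires at least 2 residues")
    diff = coms[:, :, None, :] - coms[:, None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=3))
    freq = 100.0 * (dist < cutoff).mean(axis=0)
    np.fill_diagonal(freq, 0.0)
    return ContactMap(freq, ids, cutoff, mode)


def peptide_lipid_contacts(
    trajectory: Trajectory,
    system: MolecularSystem,
    cutoff: float = 6.5,
    segments: Sequence[str] = ("S1", "S2", "S3", "S4"),
    window: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Residue × lipid-segment contact frequency (% of frames).

    A contact is counted when the minimum over lipids of the residue
    COM–segment COM distance is ≤ cutoff.
    """
    frames = _frame_window(trajectory, window)
    coms, ids = _residue_coms(trajectory, system, frames)
    seg_idx = {s: system.segment_atom_indices(s) for s in segments}
    out = pd.DataFrame(0.0, index=ids, columns=list(segments))
    out.index.name = "residue"
    for s, lipid_lists in seg_idx.items():
        seg_coms = np.empty((len(frames), len(lipid_lists), 3))
        for fi, f in enumerate(frames):
            for k, idx in enumerate(lipid_lists):
                seg_coms[fi, k] = center_of_mass(
                    trajectory.coords[f], system.masses, idx
                )
        d = np.sqrt(
            ((coms[:, :, None, :] - seg_coms[:, None, :, :]) ** 2).sum(axis=3)
        ).min(axis=2)  # min over lipids → (frames, residues)
        out[s] = 100.0 * (d <= cutoff).mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# Salt bridges
# ---------------------------------------------------------------------------

def representative_atom_index(
    system: MolecularSystem, residue: int
) -> Tuple[int, ...]:
    """Representative charged-group atom(s) of a charged residue.

    Arg returns both NH1 and NH2 (the nearer one is used per frame)."""
    rn = dict(system.peptide_residues)[residue].upper()
    if rn == "LYS":
        return (system.find_atom(residue, "NZ"),)
    if rn == "ARG":
        return (system.find_atom(residue, "NH1"), system.find_atom(residue, "NH2"))
    if rn == "ASP":
        return (system.find_atom(residue, "CG"),)
    if rn == "GLU":
        return (system.find_atom(residue, "CD"),)
    raise TopologyError(f"residue {residue} ({rn}) is not a charged residue type")


def enumerate_salt_bridge_pairs(system: MolecularSystem) -> List[Tuple[int, int]]:
    """All (positive residue, negative residue) candidate pairs."""
    pos = [rid for rid, rn in system.peptide_residues if rn.upper() in _POS_RES]
    neg = [rid for rid, rn in system.peptide_residues if rn.upper() in _NEG_RES]
    return [(p, n) for p in pos for n in neg]


def salt_bridges(
    trajectory: Trajectory,
    system: MolecularSystem,
    d0: float = 4.5,
    window: Optional[Sequence[int]] = None,
) -> SaltBridgeTable:
    """Occupancy of every candidate salt bridge: S = 1 when r − d₀ ≤ 0."""
    frames = _frame_window(trajectory, window)
    pairs = enumerate_salt_bridge_pairs(system)
    rows = []
    formed = np.zeros((len(frames), len(pairs)), dtype=bool)
    for k, (p, n) in enumerate(pairs):
        ap = representative_atom_index(system, p)
        an = representative_atom_index(system, n)
        d = np.full(len(frames), np.inf)
        used = None
        for i in ap:
            for j in an:
                dij = np.linalg.norm(
                    trajectory.coords[np.ix_(frames, [i])][:, 0]
                    - trajectory.coords[np.ix_(frames, [j])][:, 0],
                    axis=1,
                )
                better = dij < d
                d = np.where(better, dij, d)
                if used is None or better.mean() > 0.5:
                    used = (i, j)
        formed[:, k] = d - d0 <= 0
        rows.append({
            "pos_residue": p,
            "neg_residue": n,
            "pos_name": dict(system.peptide_residues)[p],
            "neg_name": dict(system.peptide_residues)[n],
            "occupancy_pct": 100.0 * formed[:, k].mean(),
            "atom_i": used[0],
            "atom_j": used[1],
        })
    counts = ObservableSeries(
        trajectory.times[frames], formed.sum(axis=1).astype(float),
        name="salt_bridge_count", units="count",
    )
    return SaltBridgeTable(pd.DataFrame(rows), counts, d0)


def salt_bridge_distance_series(
    trajectory: Trajectory,
    donor_atom: int,
    acceptor_atom: int,
    formed_cutoff: float = 5.0,
    window: Optional[Sequence[int]] = None,
) -> Tuple[ObservableSeries, float]:
    """Per-frame representative-atom distance and the fraction of frames < cutoff."""
    if donor_atom == acceptor_atom:
        raise DomainError("donor and acceptor atoms must differ")
    frames = _frame_window(trajectory, window)
    d = np.linalg.norm(
        trajectory.coords[frames, donor_atom] - trajectory.coords[frames, acceptor_atom],
        axis=1,
    )
    series = ObservableSeries(trajectory.times[frames], d,
                              name="salt_bridge_distance", units="Å")
    return series, float((d < formed_cutoff).mean())


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _find_donors(
    system: MolecularSystem, candidates: np.ndarray, coords: np.ndarray
) -> List[Tuple[int, int]]:
    """(heavy atom, hydrogen) donor pairs: N/O with an H within 1.25 Å."""
    donors = []
    h_mask = np.array([str(e).upper() == "H" for e in system.elements])
    h_idx = np.flatnonzero(h_mask)
    for x in candidates:
        if str(system.elements[x]).upper() not in ("N", "O"):
            continue
        same_res = h_idx[
            (system.residue_indices[h_idx] == system.residue_indices[x])
            & (system.chain_ids[h_idx] == system.chain_ids[x])
        ]
        for h in same_res:
            if np.linalg.norm(coords[x] - coords[h]) < 1.25:
                donors.append((int(x), int(h)))
    return donors


def hydrogen_bonds(
    trajectory: Trajectory,
    system: MolecularSystem,
    d_cut: float = 3.5,
    angle_cut: float = 135.0,
    group_a: Optional[Iterable[int]] = None,
    group_b: Optional[Iterable[int]] = None,
    window: Optional[Sequence[int]] = None,
) -> Tuple[pd.DataFrame, ObservableSeries]:
    """Donor–acceptor occupancies and per-frame H-bond counts.

    A bond X–H···Y is counted when the X–Y distance is < ``d_cut`` and
    the angle at H is > ``angle_cut`` degrees.  Donors are N/O atoms
    with an attached hydrogen; acceptors are N/O atoms.  By default both
    groups are the peptide.
    """
    frames = _frame_window(trajectory, window)
    a = (system.peptide_indices if group_a is None
         else np.asarray(list(group_a), int))
    b = (system.peptide_indices if group_b is None
         else np.asarray(list(group_b), int))
    donors = _find_donors(system, a, trajectory.coords[frames[0]])
    if not donors:
        raise TopologyError("no donors with attached hydrogens in group A")
    acceptors = np.asarray(
        [i for i in b if str(system.elements[i]).upper() in ("N", "O")], int
    )
    occ: Dict[Tuple[int, int], int] = {}
    counts = np.zeros(len(frames))
    for fi, f in enumerate(frames):
        xyz = trajectory.coords[f]
        for (x, h) in donors:
            dxy = np.linalg.norm(xyz[acceptors] - xyz[x], axis=1)
            close = acceptors[(dxy < d_cut) & (acceptors != x) & (acceptors != h)]
            for y in close:
                v1 = xyz[x] - xyz[h]
                v2 = xyz[y] - xyz[h]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if ang > angle_cut:
                    occ[(x, int(y))] = occ.get((x, int(y)), 0) + 1
                    counts[fi] += 1
    rows = [{
        "donor_atom": x, "acceptor_atom": y,
        "donor_residue": int(system.residue_indices[x]),
        "acceptor_residue": int(system.residue_indices[y]),
        "occupancy_pct": 100.0 * c / len(frames),
    } for (x, y), c in sorted(occ.items())]
    table = pd.DataFrame(
        rows, columns=["donor_atom", "acceptor_atom", "donor_residue",
                       "acceptor_residue", "occupancy_pct"],
    )
    series = ObservableSeries(trajectory.times[frames], counts,
                              name="hbond_count", units="count")
    return table, series


# ---------------------------------------------------------------------------
# Insertion profiling
# ---------------------------------------------------------------------------

def insertion_profile(
    trajectory: Trajectory,
    system: MolecularSystem,
    window: Optional[Sequence[int]] = None,
    bin_width: float = 0.5,
    surface_band: float = 6.5,
    Zp: Optional[float] = None,
) -> InsertionProfile:
    """Per-residue |z|-to-midplane histograms with inserted/surface/detached calls.

    A residue is inserted when its modal depth is below Zp (the leaflet
    phosphorus COM height), a surface contact when the modal depth lies
    within ``surface_band`` above Zp, and detached beyond that.
    """
    if not system.lipids:
        raise MidplaneError("insertion profiling requires a bilayer")
    frames = _frame_window(trajectory, window)
    coms, ids = _residue_coms(trajectory, system, frames)
    depth = np.empty((len(frames), len(ids)))
    zp_frames = np.empty(len(frames))
    for fi, f in enumerate(frames):
        mid = midplane_z(trajectory.coords[f], system)
        depth[fi] = np.abs(coms[fi, :, 2] - mid)
        up = system.phosphorus_indices("upper")
        zp_frames[fi] = abs(
            center_of_mass(trajectory.coords[f], system.masses, up)[2] - mid
        )
    zp = float(np.mean(zp_frames)) if Zp is None else float(Zp)
    dmax = max(depth.max() + bin_width, zp + 2 * surface_band)
    n_bins = int(np.ceil(dmax / bin_width))
    edges = bin_width * np.arange(n_bins + 1)
    hists = np.empty((len(ids), n_bins))
    modal = np.empty(len(ids))
    classes = []
    mids = 0.5 * (edges[:-1] + edges[1:])
    for r in range(len(ids)):
        h, _ = np.histogram(depth[:, r], bins=edges)
        hists[r] = h / h.sum()
        vmax = h.max()
        at_max = np.flatnonzero(h == vmax)
        runs = np.split(at_max, np.flatnonzero(np.diff(at_max) > 1) + 1)
        longest = max(runs, key=len)
        modal[r] = float(mids[longest].mean())
        if modal[r] < zp:
            classes.append("inserted")
        elif modal[r] <= zp + surface_band:
            classes.append("surface")
        else:
            classes.append("detached")
    return InsertionProfile(ids, edges, hists, modal, classes, zp, surface_band)


# ---------------------------------------------------------------------------
# Group COM distance
# ---------------------------------------------------------------------------

def com_distance_series(
    trajectory: Trajectory,
    system: MolecularSystem,
    group_a: Iterable[int],
    group_b: Iterable[int],
    contact_cutoff: float = 8.0,
    window: Optional[Sequence[int]] = None,
) -> Tuple[ObservableSeries, float]:
    """Per-frame |COM_A − COM_B| and the fraction of frames below the cutoff."""
    a = np.asarray(list(group_a), int)
    b = np.asarray(list(group_b), int)
    if a.size == 0 or b.size == 0:
        raise DomainError("com_distance_series: empty group")
    frames = _frame_window(trajectory, window)
    d = np.empty(len(frames))
    for fi, f in enumerate(frames):
        ca = center_of_mass(trajectory.coords[f], system.masses, a)
        cb = center_of_mass(trajectory.coords[f], system.masses, b)
        d[fi] = np.linalg.norm(ca - cb)
    series = ObservableSeries(trajectory.times[frames], d,
                              name="com_distance", units="Å")
    return series, float((d < contact_cutoff).mean())
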