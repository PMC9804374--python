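"""Peptide conformational observables.

RMSD (optimal-superposition, mass-weighted), radius of gyration,
per-residue RMSF, solvent-accessible surface area (Shrake–Rupley), and
aggregation of DSSP-style secondary-structure strings into four-class
content tables.  All averaged quantities default to the equilibrated
part of a trajectory via :func:`equilibration_window`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import biotite.structure as struc
from scipy.spatial.transform import Rotation

from .core import (
    DomainError,
    MolecularSystem,
    ObservableSeries,
    RegionMap,
    TopologyError,
    Trajectory,
    WindowError,
    center_of_mass,
)

__all__ = [
    "SS_ALPHABET",
    "SS_CLASS_OF_CODE",
    "SSContent",
    "rmsd",
    "superpose",
    "radius_of_gyration",
    "rmsf",
    "sasa",
    "ss_aggregate",
    "assign_ss_from_dihedrals",
    "compute_phi_psi",
    "equilibration_window",
]

#: DSSP-style single-letter codes accepted in secondary-structure strings.
SS_ALPHABET = set("HGIEBTSC")

#: Four-class mapping: beta sheet ← {E, B}, helix ← {H, G, I}, turn ← {T},
#: random coil ← {S, C}.  Isolated bridges count as sheet and bends as
#: coil, the conservative reading of the four-class convention.
SS_CLASS_OF_CODE = {
    "E": "BS", "B": "BS",
    "H": "H", "G": "H", "I": "H",
    "T": "T",
    "S": "RC", "C": "RC",
}


# ---------------------------------------------------------------------------
# Superposition / RMSD / Rg / RMSF
# ---------------------------------------------------------------------------

def superpose(
    mobile: np.ndarray, reference: np.ndarray, weights: Optional[np.ndarray] = None
) -> Tuple[np.ndarray, float]:
    """Least-squares superpose ``mobile`` onto ``reference``.

    Returns the transformed coordinates and the weighted RMSD.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise DomainError("superpose: shape mismatch")
    n = mobile.shape[0]
    if n < 3:
        raise DomainError("superposition requires at least 3 atoms")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    com_m = (w[:, None] * mobile).sum(0) / w.sum()
    com_r = (w[:, None] * reference).sum(0) / w.sum()
    m = mobile - com_m
    r = reference - com_r
    rot, _ = Rotation.align_vectors(r, m, weights=w)
    moved = rot.apply(m) + com_r
    dev = moved - reference
    value = float(np.sqrt((w * (dev ** 2).sum(axis=1)).sum() / w.sum()))
    return moved, value


def rmsd(
    reference: np.ndarray, frame: np.ndarray, weights: Optional[np.ndarray] = None
) -> float:
    """Mass-weighted optimal-rotation RMSD after removing COM translation."""
    _, value = superpose(frame, reference, weights)
    return value


def radius_of_gyration(coords: np.ndarray, masses: Optional[np.ndarray] = None) -> float:
    """√(Σ mᵢ|rᵢ − r_com|² / Σ mᵢ)."""
    coords = np.asarray(coords, float)
    if coords.shape[0] == 0:
        raise DomainError("radius_of_gyration: empty input")
    m = np.ones(coords.shape[0]) if masses is None else np.asarray(masses, float)
    com = (m[:, None] * coords).sum(0) / m.sum()
    return float(np.sqrt((m * ((coords - com) ** 2).sum(axis=1)).sum() / m.sum()))


def rmsf(
    trajectory: Trajectory,
    indices: Iterable[int],
    align: bool = True,
    reference_frame: int = 0,
    weights: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the mean position.

    With ``align`` each frame's selection is first superposed onto the
    reference frame, removing rigid-body motion.
    """
    idx = np.asarray(list(indices), int)
    if trajectory.n_frames < 2:
        raise DomainError("rmsf requires at least 2 frames")
    sel = trajectory.coords[:, idx, :].copy()
    if align:
        ref = sel[reference_frame]
        for f in range(sel.shape[0]):
            sel[f], _ = superpose(sel[f], ref, weights)
    mean = sel.mean(axis=0)
    return np.sqrt(((sel - mean) ** 2).sum(axis=2).mean(axis=0))


# ---------------------------------------------------------------------------
# SASA (Shrake–Rupley)
# ---------------------------------------------------------------------------

def sasa(
    coords: np.ndarray,
    system: MolecularSystem,
    indices: Optional[Iterable[int]] = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
    vdw_radii: Optional[Dict[str, float]] = None,
) -> pd.DataFrame:
    """Shrake–Rupley solvent-accessible surface area, summed per residue (Å²).

    Exactly coincident atoms are collapsed to a single sphere before
    sampling, so duplicated positions do not double-count surface.
    """
    idx = (np.arange(system.n_atoms) if indices is None
           else np.asarray(list(indices), int))
    xyz = np.asarray(coords, float)[idx]
    # collapse exact duplicates (keep the first of each coincident set)
    order = np.lexsort(xyz.T)
    keep = np.ones(len(idx), bool)
    for a, b in zip(order[:-1], order[1:]):
        if np.allclose(xyz[a], xyz[b], atol=1e-6):
            keep[b] = False
    idx = idx[keep]
    xyz = xyz[keep]

    arr = struc.AtomArray(len(idx))
    arr.coord = xyz.astype(np.float32)
    arr.atom_name = system.names[idx].astype(str)
    arr.res_name = system.residue_names[idx].astype(str)
    arr.res_id = system.residue_indices[idx]
    arr.chain_id = system.chain_ids[idx].astype(str)
    arr.element = np.array([str(e).upper() for e in system.elements[idx]])
    if vdw_radii is not None:
        radii = np.array([vdw_radii[str(e).upper()] for e in system.elements[idx]])
        per_atom = struc.sasa(arr, probe_radius=probe_radius,
                              point_number=n_points, vdw_radii=radii)
    else:
        try:
            per_atom = struc.sasa(arr, probe_radius=probe_radius,
                                  point_number=n_points, vdw_radii="Single")
        except Exception as exc:
            raise TopologyError(f"missing van der Waals radius: {exc}") from exc
    out = pd.DataFrame({
        "residue": system.residue_indices[idx],
        "residue_name": system.residue_names[idx].astype(str),
        "sasa": per_atom,
    })
    per_res = out.groupby(["residue", "residue_name"], sort=True)["sasa"].sum()
    return per_res.reset_index()


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------

@dataclass
class SSContent:
    """Four-class secondary-structure content (%) per region and overall."""

    percent: pd.DataFrame  # rows BS/H/T/RC, columns R1..R4 + Peptide
    stderr: pd.DataFrame


def _class_counts(frames: Sequence[str], residue_mask: np.ndarray) -> Dict[str, int]:
    counts = {"BS": 0, "H": 0, "T": 0, "RC": 0}
    for s in frames:
        for r in np.flatnonzero(residue_mask):
            code = s[r]
            if code not in SS_ALPHABET:
                raise DomainError(f"unknown secondary-structure code {code!r}")
            counts[SS_CLASS_OF_CODE[code]] += 1
    return counts


def ss_aggregate(
    frames: Union[Sequence[str], Sequence[Sequence[str]]],
    regions: Optional[RegionMap] = None,
    window: Optional[slice] = None,
    n_blocks: int = 5,
) -> SSContent:
    """Average secondary-structure content (%) with standard errors.

    ``frames`` is either one replica (sequence of per-frame code
    strings) or several replicas (sequence of such sequences).  With
    multiple replicas the standard error is over replica means; with a
    single replica it comes from block averaging over ``n_blocks``
    contiguous blocks.
    """
    if len(frames) == 0:
        raise WindowError("no secondary-structure frames supplied")
    replicas: List[List[str]]
    if isinstance(frames[0], str):
        replicas = [list(frames)]
    else:
        replicas = [list(rep) for rep in frames]
    if window is not None:
        replicas = [rep[window] for rep in replicas]
        if any(len(rep) == 0 for rep in replicas):
            raise WindowError("analysis window is empty")
    n_res = len(replicas[0][0])
    for rep in replicas:
        for s in rep:
            if len(s) != n_res:
                raise DomainError("all code strings must have the residue count")
    regions = regions or RegionMap()
    regions.validate(n_res)
    scopes: Dict[str, np.ndarray] = {}
    for name, (lo, hi) in regions.bounds().items():
        mask = np.zeros(n_res, bool)
        mask[lo - 1: hi] = True
        scopes[name] = mask
    scopes["Peptide"] = np.ones(n_res, bool)

    # per-sample percentages: one sample per replica, or per block
    if len(replicas) > 1:
        samples = replicas
    else:
        rep = replicas[0]
        k = min(n_blocks, len(rep))
        bounds = np.linspace(0, len(rep), k + 1).astype(int)
        samples = [rep[a:b] for a, b in zip(bounds[:-1], bounds[1:]) if b > a]

    classes = ["BS", "H", "T", "RC"]
    pct = pd.DataFrame(index=classes, columns=list(scopes), dtype=float)
    err = pd.DataFrame(index=classes, columns=list(scopes), dtype=float)
    for scope, mask in scopes.items():
        per_sample = []
        for sample in samples:
            counts = _class_counts(sample, mask)
            total = sum(counts.values())
            per_sample.append([100.0 * counts[c] / total for c in classes])
        per_sample = np.asarray(per_sample)
        # the point estimate pools all frames (not the mean of block means)
        counts = _class_counts([s for sample in samples for s in sample], mask)
        total = sum(counts.values())
        pct[scope] = [100.0 * counts[c] / total for c in classes]
        if len(samples) > 1:
            err[scope] = per_sample.std(axis=0, ddof=1) / np.sqrt(len(samples))
        else:
            err[scope] = 0.0
    return SSContent(pct, err)


def compute_phi_psi(system: MolecularSystem, coords: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Backbone (φ, ψ) in degrees per peptide residue (NaN at chain ends)."""
    res = system.peptide_residues
    n = len(res)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)

    def atom(r: int, name: str) -> np.ndarray:
        return coords[system.find_atom(res[r][0], name)]

    for i in range(n):
        try:
            if i > 0:
                phi[i] = _dihedral(atom(i - 1, "C"), atom(i, "N"),
                                   atom(i, "CA"), atom(i, "C"))
            if i < n - 1:
                psi[i] = _dihedral(atom(i, "N"), atom(i, "CA"),
                                   atom(i, "C"), atom(i + 1, "N"))
        except TopologyError:
            continue
    return phi, psi


def _dihedral(a, b, c, d) -> float:
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def assign_ss_from_dihedrals(phi: np.ndarray, psi: np.ndarray) -> str:
    """Approximate dihedral-window secondary-structure assignment.

    Helix when φ ∈ [−100, −30] and ψ ∈ [−80, −5]; strand when
    φ ∈ [−180, −105] and ψ ∈ [105, 180]; otherwise coil.  This is a
    coarse stand-in for a hydrogen-bond-based assigner and is labelled
    approximate: it ignores H-bond topology entirely.
    """
    out = []
    for f, p in zip(np.atleast_1d(phi), np.atleast_1d(psi)):
        if np.isnan(f) or np.isnan(p):
            out.append("C")
        elif -100 <= f <= -30 and -80 <= p <= -5:
            out.append("H")
        elif -180 <= f <= -105 and 105 <= p <= 180:
            out.append("E")
        else:
            out.append("C")
    return "".join(out)


# ---------------------------------------------------------------------------
# Equilibration window
# ---------------------------------------------------------------------------

def equilibration_window(times: np.ndarray, tau_eq: float = 200.0) -> np.ndarray:
    """Indices of frames with time ≥ tau_eq (ns).

    All reported averages default to this window — the convention of
    analyzing only the equilibrated part of each trajectory.
    """
    times = np.asarray(times, float)
    if times.size == 0 or times[-1] < tau_eq:
        raise WindowError(
            f"trajectory ends at {times[-1] if times.size else 0} ns, "
            f"before tau_eq = {tau_eq} ns"
        )
    return np.flatnonzero(times >= tau_eq)
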