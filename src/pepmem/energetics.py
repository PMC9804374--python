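"""Gas-phase peptide–membrane interaction energies and charge bookkeeping.

Only the molecular-mechanics inter-group terms are computed: a pairwise
Coulomb sum (ΔE_elec) and a Lennard-Jones sum (ΔE_vdw), their total
ΔE_MM = ΔE_elec + ΔE_vdw, windowed time averages and a per-residue
decomposition.  Implicit-solvent (GB/SA) and entropy terms of a full
end-state binding free energy are deliberately not computed, so outputs
are named ΔE, never ΔG.

The default charge/Lennard-Jones table is a pedagogical surrogate —
formal charges on representative charged-group atoms with uniform LJ
parameters — not a force field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import (
    DomainError,
    MolecularSystem,
    ObservableSeries,
    Trajectory,
    WindowError,
)

__all__ = [
    "COULOMB_CONSTANT",
    "ChargeModel",
    "EnergyDecomposition",
    "formal_charge",
    "default_charge_model",
    "interaction_energy",
    "windowed_binding_series",
    "per_residue_decomposition",
]

#: Coulomb constant in Å·kcal/(mol·e²).
COULOMB_CONSTANT = 332.0637

_POSITIVE = set("RK")
_NEGATIVE = set("DE")
_AA = set("ACDEFGHIKLMNPQRSTVWY")


def formal_charge(sequence: str, cu_bound: bool = False) -> int:
    """Formal net charge (e) of a peptide at neutral pH.

    +1 per Arg/Lys, −1 per Asp/Glu, +1 for the N-terminus and −1 for
    the C-terminus.  ``cu_bound`` adds a coordinated Cu²⁺ (+2); with
    the metal's charge absorbed into the peptide's protonation
    bookkeeping this takes the default amyloid-β sequence from −3 to −1.
    """
    bad = [c for c in sequence if c not in _AA]
    if bad:
        raise DomainError(f"unknown amino-acid letters: {sorted(set(bad))}")
    q = sum(+1 for c in sequence if c in _POSITIVE)
    q -= sum(1 for c in sequence if c in _NEGATIVE)
    q += 1 - 1  # N-terminus (+1) and C-terminus (−1) cancel
    if cu_bound:
        q += 2
    return q


@dataclass
class ChargeModel:
    """Per-atom partial charges (e) and LJ parameters (σ Å, ε kcal/mol)."""

    q: np.ndarray
    sigma: np.ndarray
    epsilon: np.ndarray
    source: str = "formal-charge surrogate"

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if np.any(self.sigma <= 0):
            raise DomainError("LJ sigma must be > 0")
        if np.any(self.epsilon < 0):
            raise DomainError("LJ epsilon must be ≥ 0")


def default_charge_model(
    system: MolecularSystem, sigma: float = 3.5, epsilon: float = 0.1
) -> ChargeModel:
    """Formal charges on representative atoms, uniform LJ parameters.

    Lys NZ +1, Arg NH1/NH2 +0.5 each, Asp CG / Glu CD −1, lipid P −1 and
    choline N4 +1 (zwitterionic headgroup), Ca²⁺ +2, Cl⁻ −1; everything
    else neutral.
    """
    q = np.zeros(system.n_atoms)
    for i in range(system.n_atoms):
        cls = system.atom_classes[i]
        name = str(system.names[i])
        res = str(system.residue_names[i]).upper()
        if cls == "peptide":
            if res == "LYS" and name == "NZ":
                q[i] = 1.0
            elif res == "ARG" and name in ("NH1", "NH2"):
                q[i] = 0.5
            elif res == "ASP" and name == "CG":
                q[i] = -1.0
            elif res == "GLU" and name == "CD":
                q[i] = -1.0
        elif cls == "lipid":
            q[i] = {"P": -1.0, "N4": 1.0}.get(name, 0.0)
        elif cls == "ion":
            q[i] = {"CA": 2.0, "CAL": 2.0, "CL": -1.0, "CLA": -1.0,
                    "NA": 1.0, "K": 1.0, "CU": 2.0}.get(res, 0.0)
    return ChargeModel(
        q=q,
        sigma=np.full(system.n_atoms, sigma),
        epsilon=np.full(system.n_atoms, epsilon),
    )


@dataclass
class EnergyDecomposition:
    """Inter-group MM energy terms (kcal/mol) with optional per-residue split."""

    e_elec: float
    e_vdw: float
    per_residue: Optional[pd.DataFrame] = None  # columns e_elec, e_vdw, e_mm
    window: Optional[Tuple[float, float]] = None

    @property
    def e_mm(self) -> float:
        return self.e_elec + self.e_vdw


def _pair_terms(
    coords: np.ndarray,
    charges: ChargeModel,
    group_a: np.ndarray,
    group_b: np.ndarray,
    cutoff: Optional[float],
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-A-atom electrostatic and LJ sums over all B partners."""
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise DomainError("interaction groups must be non-empty")
    if np.intersect1d(a, b).size:
        raise DomainError("interaction groups must be disjoint")
    diff = coords[a][:, None, :] - coords[b][None, :, :]
    r = np.sqrt((diff ** 2).sum(axis=2))
    if np.any(r < 0.1):
        ia, ib = np.unravel_index(np.argmin(r), r.shape)
        raise DomainError(
            f"atoms {a[ia]} and {b[ib]} overlap (r = {r[ia, ib]:.3f} Å < 0.1 Å)"
        )
    mask = np.ones_like(r, dtype=bool) if cutoff is None else (r <= cutoff)
    qq = np.outer(charges.q[a], charges.q[b])
    elec = np.where(mask, COULOMB_CONSTANT * qq / r, 0.0).sum(axis=1)
    sig = 0.5 * (charges.sigma[a][:, None] + charges.sigma[b][None, :])
    eps = np.sqrt(np.outer(charges.epsilon[a], charges.epsilon[b]))
    sr6 = (sig / r) ** 6
    vdw = np.where(mask, 4.0 * eps * (sr6 ** 2 - sr6), 0.0).sum(axis=1)
    return elec, vdw


def interaction_energy(
    coords: np.ndarray,
    charges: ChargeModel,
    group_a: Iterable[int],
    group_b: Iterable[int],
    cutoff: Optional[float] = None,
) -> EnergyDecomposition:
    """Inter-group ΔE_elec + ΔE_vdw for one frame.

    ΔE_elec = Σ k_e·qᵢqⱼ/rᵢⱼ and ΔE_vdw = Σ 4ε[(σ/r)¹² − (σ/r)⁶] with
    Lorentz–Berthelot combining, over all pairs with i in A and j in B.
    No periodic images are included (whole-molecule convention).
    """
    elec, vdw = _pair_terms(np.asarray(coords, float), charges,
                            np.asarray(list(group_a), int),
                            np.asarray(list(group_b), int), cutoff)
    return EnergyDecomposition(e_elec=float(elec.sum()), e_vdw=float(vdw.sum()))


def windowed_binding_series(
    trajectory: Trajectory,
    charges: ChargeModel,
    group_a: Iterable[int],
    group_b: Iterable[int],
    window_ns: float = 10.0,
    cutoff: Optional[float] = None,
) -> pd.DataFrame:
    """Non-overlapping window means ± standard errors of ΔE terms.

    Negative values are attractive.  Returns one row per window with
    columns window_start_ns, e_elec, e_vdw, e_mm, stderr (frame-level
    standard error of e_mm, no autocorrelation correction).
    """
    a = np.asarray(list(group_a), int)
    b = np.asarray(list(group_b), int)
    span = trajectory.times[-1] - trajectory.times[0]
    if window_ns <= 0 or window_ns > span + 1e-9:
        raise WindowError(
            f"window of {window_ns} ns does not fit a {span:.3f} ns trajectory"
        )
    per_frame = np.empty((trajectory.n_frames, 2))
    for f in range(trajectory.n_frames):
        elec, vdw = _pair_terms(trajectory.coords[f], charges, a, b, cutoff)
        per_frame[f] = elec.sum(), vdw.sum()
    t0 = trajectory.times[0]
    widx = np.floor((trajectory.times - t0) / window_ns).astype(int)
    # a frame landing exactly on the final boundary joins the last window
    n_windows = max(int(np.ceil(span / window_ns - 1e-9)), 1)
    widx = np.minimum(widx, n_windows - 1)
    rows = []
    for w in np.unique(widx):
        sel = widx == w
        e = per_frame[sel]
        mm = e.sum(axis=1)
        sem = float(np.std(mm, ddof=1) / np.sqrt(len(mm))) if len(mm) > 1 else 0.0
        rows.append({
            "window_start_ns": t0 + w * window_ns,
            "e_elec": float(e[:, 0].mean()),
            "e_vdw": float(e[:, 1].mean()),
            "e_mm": float(mm.mean()),
            "stderr": sem,
            "n_frames": int(sel.sum()),
        })
    return pd.DataFrame(rows)


def per_residue_decomposition(
    trajectory: Trajectory,
    system: MolecularSystem,
    charges: ChargeModel,
    membrane_group: Iterable[int],
    window: Optional[slice] = None,
    cutoff: Optional[float] = None,
) -> pd.DataFrame:
    """Window-averaged per-residue ΔE_elec / ΔE_vdw / ΔE_MM vs a membrane group.

    Residue terms sum exactly to the whole-peptide totals because every
    peptide atom belongs to exactly one residue.
    """
    mem = np.asarray(list(membrane_group), int)
    res_atoms = system.peptide_residue_atom_indices()
    frames = range(trajectory.n_frames) if window is None else range(
        *window.indices(trajectory.n_frames)
    )
    frames = list(frames)
    if not frames:
        raise WindowError("empty frame window")
    pep = system.peptide_indices
    acc = np.zeros((len(res_atoms), 2))
    for f in frames:
        elec, vdw = _pair_terms(trajectory.coords[f], charges, pep, mem, cutoff)
        by_atom = {int(i): (e, v) for i, e, v in zip(pep, elec, vdw)}
        for r, idx in enumerate(res_atoms):
            acc[r, 0] += sum(by_atom[int(i)][0] for i in idx)
            acc[r, 1] += sum(by_atom[int(i)][1] for i in idx)
    acc /= len(frames)
    df = pd.DataFrame({
        "residue": [rid for rid, _ in system.peptide_residues],
        "residue_name": [rn for _, rn in system.peptide_residues],
        "e_elec": acc[:, 0],
        "e_vdw": acc[:, 1],
    })
    df["e_mm"] = df["e_elec"] + df["e_vdw"]
    return df
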