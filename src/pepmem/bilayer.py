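"""Bilayer-phase observables: area per lipid, acyl-chain order parameters,
mass-density profiles and bilayer thickness.

The deuterium order parameter for each tail carbon is
S_CD = ⟨(3cos²θ − 1)/2⟩ over all C–H bond vectors, lipids and frames,
with θ measured against the +z bilayer normal; cos²θ is used, so the
lower leaflet needs no flipping and both leaflets are pooled.  Standard
errors are computed over lipids, not frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np

from .core import (
    DomainError,
    MidplaneError,
    MolecularSystem,
    ObservableSeries,
    TopologyError,
    Trajectory,
    center_of_mass,
)

__all__ = [
    "DensityProfile",
    "OrderParameterProfile",
    "area_per_lipid",
    "order_parameters",
    "density_profile",
    "bilayer_thickness",
    "thickness_from_profile",
    "midplane_z",
]


@dataclass
class OrderParameterProfile:
    """Per-carbon S_CD mean with a standard error over lipids."""

    carbon_index: np.ndarray  # chain position (2 = carbon closest to glycerol)
    scd: np.ndarray
    stderr: np.ndarray


@dataclass
class DensityProfile:
    """Binned z-profiles (midplane-centered) for one or more atom groups."""

    z_edges: np.ndarray
    values: Dict[str, np.ndarray]
    normalize: str  # "mass" | "per_atom" | "count"

    @property
    def z_mid(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])


def area_per_lipid(trajectory: Trajectory, lipids_per_leaflet: int) -> ObservableSeries:
    """Per-frame in-plane area per lipid, A_L(t) = L_x·L_y / n."""
    if lipids_per_leaflet < 1:
        raise DomainError("lipids_per_leaflet must be ≥ 1")
    values = trajectory.box[:, 0] * trajectory.box[:, 1] / lipids_per_leaflet
    return ObservableSeries(trajectory.times, values, name="area_per_lipid", units="Å²")


def _ch_pairs(system: MolecularSystem) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Tail C–H pairs: (carbon idx, hydrogen idx, chain position, lipid ordinal).

    A hydrogen belongs to a carbon when its name is 'H' + the carbon
    name without the leading element letter (e.g. C2A → H2A1, H2A2).
    """
    c_idx, h_idx, pos, lipid_no = [], [], [], []
    for ln, lip in enumerate(system.lipids):
        names = {str(system.names[i]): int(i) for i in lip.indices}
        for seg in ("S4", "S5"):
            for i in lip.segments.get(seg, ()):  # segments must be assigned
                name = str(system.names[i])
                if not name.startswith("C"):
                    continue
                hs = [names[h] for h in names if h.startswith("H" + name[1:])
                      and len(h) > len(name)]
                if not hs:
                    raise TopologyError(
                        f"tail carbon {name} in lipid {ln} has no attached hydrogen"
                    )
                # chain position: letter suffix A.. → 2..
                k = ord(name[2]) - ord("A") + 2
                for h in hs:
                    c_idx.append(int(i)); h_idx.append(h)
                    pos.append(k); lipid_no.append(ln)
    return (np.asarray(c_idx), np.asarray(h_idx),
            np.asarray(pos), np.asarray(lipid_no))


def order_parameters(trajectory: Trajectory, system: MolecularSystem) -> OrderParameterProfile:
    """Deuterium order parameter S_CD per tail-carbon position.

    Averages (3cos²θ − 1)/2 over every C–H vector, both chains, both
    leaflets and all frames; the standard error is over lipids.
    """
    c_idx, h_idx, pos, lipid_no = _ch_pairs(system)
    if len(c_idx) == 0:
        raise TopologyError("no tail C–H pairs found (are segments assigned?)")
    carbons = np.unique(pos)
    n_lip = lipid_no.max() + 1
    # accumulate per (lipid, carbon) so the stderr can be taken over lipids
    sums = np.zeros((n_lip, len(carbons)))
    counts = np.zeros((n_lip, len(carbons)))
    col = np.searchsorted(carbons, pos)
    for f in range(trajectory.n_frames):
        vec = trajectory.coords[f, h_idx] - trajectory.coords[f, c_idx]
        cos2 = (vec[:, 2] ** 2) / (vec ** 2).sum(axis=1)
        p2 = 1.5 * cos2 - 0.5
        np.add.at(sums, (lipid_no, col), p2)
        np.add.at(counts, (lipid_no, col), 1.0)
    per_lipid = sums / counts
    scd = per_lipid.mean(axis=0)
    stderr = per_lipid.std(axis=0, ddof=1) / np.sqrt(n_lip) if n_lip > 1 else np.zeros_like(scd)
    return OrderParameterProfile(carbons, scd, stderr)


def midplane_z(coords: np.ndarray, system: MolecularSystem) -> float:
    """Bilayer midplane: mean of upper- and lower-leaflet phosphorus COM z."""
    zs = []
    for leaflet in ("upper", "lower"):
        p = system.phosphorus_indices(leaflet)
        if len(p) == 0:
            raise MidplaneError(f"no phosphorus atoms in the {leaflet} leaflet")
        zs.append(center_of_mass(coords, system.masses, p)[2])
    return 0.5 * float(zs[0] + zs[1])


def density_profile(
    trajectory: Trajectory,
    system: MolecularSystem,
    groups: Mapping[str, Iterable[int]],
    bin_width: float = 0.5,
    normalize: str = "mass",
    center_midplane: bool = True,
    z_range: Optional[Tuple[float, float]] = None,
) -> DensityProfile:
    """z-profiles of mass density (amu/Å³), per-atom-normalized density, or raw counts.

    z is measured from the per-frame bilayer midplane (recomputed each
    frame, which removes collective drift).  ``per_atom`` divides each
    group's mass profile by its atom count.
    """
    if bin_width <= 0:
        raise DomainError("bin_width must be > 0")
    if not groups:
        raise DomainError("at least one group is required")
    if normalize not in ("mass", "per_atom", "count"):
        raise DomainError(f"unknown normalize mode {normalize!r}")
    if z_range is None:
        half = trajectory.box[:, 2].max() / 2.0
        z_range = (-half, half)
    n_bins = int(np.ceil((z_range[1] - z_range[0]) / bin_width))
    edges = z_range[0] + bin_width * np.arange(n_bins + 1)
    group_idx = {k: np.asarray(list(v), dtype=int) for k, v in groups.items()}
    hist = {k: np.zeros(n_bins) for k in group_idx}
    slab_area = float(np.mean(trajectory.box[:, 0] * trajectory.box[:, 1]))
    for f in range(trajectory.n_frames):
        origin = midplane_z(trajectory.coords[f], system) if center_midplane else 0.0
        z = trajectory.coords[f, :, 2] - origin
        for k, idx in group_idx.items():
            w = system.masses[idx] if normalize != "count" else None
            h, _ = np.histogram(z[idx], bins=edges, weights=w)
            hist[k] += h
    values: Dict[str, np.ndarray] = {}
    for k, h in hist.items():
        if normalize == "count":
            values[k] = h
        else:
            dens = h / (slab_area * bin_width * trajectory.n_frames)
            if normalize == "per_atom":
                dens = dens / len(group_idx[k])
            values[k] = dens
    return DensityProfile(edges, values, normalize)


def bilayer_thickness(trajectory: Trajectory, system: MolecularSystem) -> ObservableSeries:
    """Per-frame |COM_z(P, upper) − COM_z(P, lower)| (Å)."""
    up = system.phosphorus_indices("upper")
    lo = system.phosphorus_indices("lower")
    if len(up) == 0 or len(lo) == 0:
        raise MidplaneError("bilayer thickness requires phosphorus in both leaflets")
    vals = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        zu = center_of_mass(trajectory.coords[f], system.masses, up)[2]
        zl = center_of_mass(trajectory.coords[f], system.masses, lo)[2]
        vals[f] = abs(zu - zl)
    return ObservableSeries(trajectory.times, vals, name="bilayer_thickness", units="Å")


def _peak_position(z_mid: np.ndarray, values: np.ndarray) -> float:
    """Maximum-density bin center; a flat maximal plateau → its midpoint."""
    vmax = values.max()
    at_max = np.flatnonzero(values == vmax)
    runs = np.split(at_max, np.flatnonzero(np.diff(at_max) > 1) + 1)
    longest = max(runs, key=len)
    return float(z_mid[longest].mean())


def thickness_from_profile(profile: DensityProfile, group: str = "P") -> float:
    """Thickness as the separation of the two phosphorus density peaks."""
    z = profile.z_mid
    v = profile.values[group]
    upper = z > 0
    if not upper.any() or upper.all():
        raise MidplaneError("profile does not straddle the midplane")
    z_up = _peak_position(z[upper], v[upper])
    z_lo = _peak_position(z[~upper], v[~upper])
    return abs(z_up - z_lo)
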