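"""Structure and trajectory I/O.

Structures are standard PDB (ATOM/HETATM); trajectories are multi-model
PDB (MODEL/ENDMDL) or XYZ with a one-line-per-frame box sidecar
(``Lx Ly Lz time``).  PDB parsing and writing are delegated to biotite;
this module layers residue classification, mass inference and the
package's error contract on top.
"""

from __future__ import annotations

import io
import os
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .core import (
    ATOMIC_MASSES,
    DEFAULT_RESIDUE_CLASSES,
    FormatError,
    MolecularSystem,
    ShapeError,
    Trajectory,
)

__all__ = [
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "infer_element",
]

_TWO_LETTER = {"CL", "NA", "MG", "FE", "ZN", "CU", "BR", "CA"}


def infer_element(atom_name: str, residue_name: str) -> str:
    """Infer an element symbol from an atom name, using residue context.

    ``CA`` inside an amino acid is the α-carbon; in an ion residue it is
    calcium.  Names the heuristics cannot resolve raise FormatError
    rather than guessing.
    """
    name = atom_name.strip()
    res = residue_name.strip().upper()
    if not name:
        raise FormatError("empty atom name")
    if name[0].isdigit():  # e.g. 1HB
        name = name.lstrip("0123456789")
    upper = name.upper()
    cls = DEFAULT_RESIDUE_CLASSES.get(res)
    if cls == "ion" and upper[:2] in _TWO_LETTER:
        return upper[:2].capitalize()
    if upper[:2] in _TWO_LETTER and upper[:2] not in {"CA"} and cls is None:
        raise FormatError(
            f"ambiguous element for atom {atom_name!r} in residue {residue_name!r}"
        )
    first = upper[0]
    if first in {"H", "C", "N", "O", "S", "P"}:
        return first
    raise FormatError(
        f"cannot infer element for atom {atom_name!r} in residue {residue_name!r}"
    )


def _masses_from_elements(elements: Sequence[str]) -> np.ndarray:
    out = np.empty(len(elements))
    for i, el in enumerate(elements):
        key = str(el).strip().upper()
        if key not in ATOMIC_MASSES:
            raise FormatError(f"no standard atomic weight for element {el!r}")
        out[i] = ATOMIC_MASSES[key]
    return out


def _atom_array_from_file(path: str, model: Optional[int]) -> struc.AtomArray:
    try:
        pdb = PDBFile.read(path)
        arr = pdb.get_structure(model=model)
    except Exception as exc:  # biotite raises a mix of exception types
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    return arr


def read_structure(
    path: str,
    residue_classes: Optional[Mapping[str, str]] = None,
    masses: Optional[Sequence[float]] = None,
) -> MolecularSystem:
    """Read a PDB file into a :class:`MolecularSystem`.

    Masses are inferred from elements (standard atomic weights) unless
    ``masses`` overrides them; the peptide/lipid/ion/water partition is
    inferred from residue names via ``residue_classes``.
    """
    arr = _atom_array_from_file(path, model=1)
    elements = []
    for el, name, res in zip(arr.element, arr.atom_name, arr.res_name):
        el = str(el).strip()
        elements.append(el.capitalize() if el else infer_element(name, res))
    m = _masses_from_elements(elements) if masses is None else np.asarray(masses, float)
    return MolecularSystem(
        names=[str(n) for n in arr.atom_name],
        residue_names=[str(r) for r in arr.res_name],
        residue_indices=arr.res_id.astype(int),
        chain_ids=[str(c) for c in arr.chain_id],
        elements=elements,
        masses=m,
        coords=arr.coord,
        residue_classes=residue_classes,
    )


def _to_atom_array(system: MolecularSystem, coords: np.ndarray, box: Optional[np.ndarray]) -> struc.AtomArray:
    n = system.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32).reshape(n, 3)
    arr.atom_name = system.names.astype(str)
    arr.res_name = system.residue_names.astype(str)
    arr.res_id = system.residue_indices
    arr.chain_id = system.chain_ids.astype(str)
    arr.element = np.array([str(e).upper() for e in system.elements])
    arr.hetero = np.array(
        [cls in ("ion", "water", "lipid") for cls in system.atom_classes]
    )
    if box is not None:
        arr.box = np.diag(np.asarray(box, dtype=float))
    return arr


def write_structure(path: str, system: MolecularSystem, box: Optional[np.ndarray] = None) -> None:
    """Write a MolecularSystem as a single-model PDB file."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(system, system.coords, box))
    pdb.write(path)


def write_trajectory(path: str, system: MolecularSystem, trajectory: Trajectory) -> None:
    """Write a Trajectory as a multi-model PDB (MODEL/ENDMDL)."""
    stack = struc.stack(
        [_to_atom_array(system, trajectory.coords[f], trajectory.box[f]) for f in range(trajectory.n_frames)]
    )
    stack.box = np.stack([np.diag(b) for b in trajectory.box])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)


def _check_model_atom_counts(path: str) -> None:
    """Pre-scan MODEL blocks so a truncated frame is reported by index."""
    counts = []
    current = None
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                current = 0
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:
                    current = 0
                current += 1
            elif rec.startswith("ENDMDL"):
                counts.append(current or 0)
                current = None
    if current:  # trailing model without ENDMDL
        counts.append(current)
    if counts and len(set(counts)) > 1:
        ref = counts[0]
        for f, c in enumerate(counts):
            if c != ref:
                raise ShapeError(
                    f"frame {f} has {c} atoms, expected {ref} (truncated model?)"
                )


def read_trajectory(
    path: str,
    system: MolecularSystem,
    dt_ns: float = 1.0,
    box: Optional[Sequence[float]] = None,
) -> Trajectory:
    """Read a multi-model PDB trajectory.

    Frame times are ``dt_ns × frame_index``.  Boxes come from CRYST1; if
    the file has none, a constant ``box`` must be supplied.
    """
    _check_model_atom_counts(path)
    try:
        pdb = PDBFile.read(path)
        stack = pdb.get_structure(model=None)
    except Exception as exc:
        raise FormatError(f"cannot parse PDB trajectory {path}: {exc}") from exc
    if stack.array_length() != system.n_atoms:
        raise ShapeError(
            f"trajectory has {stack.array_length()} atoms but the system has "
            f"{system.n_atoms}"
        )
    f = stack.stack_depth()
    if stack.box is not None:
        boxes = np.stack([np.diag(stack.box[i]) for i in range(f)])
    elif box is not None:
        boxes = np.tile(np.asarray(box, dtype=float), (f, 1))
    else:
        raise FormatError(
            f"{path}: no CRYST1 box in file and no constant box supplied"
        )
    times = dt_ns * np.arange(f)
    return Trajectory(stack.coord.astype(float), boxes, times)


# ---------------------------------------------------------------------------
# XYZ + box sidecar
# ---------------------------------------------------------------------------

def write_xyz_trajectory(path: str, system: MolecularSystem, trajectory: Trajectory) -> None:
    """Write an XYZ trajectory plus a ``<path>.box`` sidecar (Lx Ly Lz time)."""
    with open(path, "w") as fh:
        for f in range(trajectory.n_frames):
            fh.write(f"{system.n_atoms}\n")
            fh.write(f"frame {f} t={trajectory.times[f]:.6f} ns\n")
            for el, xyz in zip(system.elements, trajectory.coords[f]):
                fh.write(f"{el} {xyz[0]:.4f} {xyz[1]:.4f} {xyz[2]:.4f}\n")
    with open(path + ".box", "w") as fh:
        for f in range(trajectory.n_frames):
            lx, ly, lz = trajectory.box[f]
            fh.write(f"{lx:.4f} {ly:.4f} {lz:.4f} {trajectory.times[f]:.6f}\n")


def read_xyz_trajectory(path: str, system: MolecularSystem) -> Trajectory:
    """Read an XYZ trajectory with its ``<path>.box`` sidecar."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"{path} line {i + 1}: expected atom count") from exc
        if n != system.n_atoms:
            raise ShapeError(
                f"frame {frame_no} has {n} atoms, expected {system.n_atoms}"
            )
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ShapeError(f"frame {frame_no} truncated: {len(block)} of {n} atoms")
        coords = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        frames.append(coords)
        i += 2 + n
        frame_no += 1
    sidecar = path + ".box"
    if not os.path.exists(sidecar):
        raise FormatError(f"missing box sidecar {sidecar}")
    data = np.loadtxt(sidecar, ndmin=2)
    if data.shape[0] != len(frames):
        raise ShapeError(
            f"box sidecar has {data.shape[0]} lines for {len(frames)} frames"
        )
    return Trajectory(np.stack(frames), data[:, :3], data[:, 3])
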