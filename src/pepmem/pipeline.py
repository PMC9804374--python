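"""Config-driven end-to-end driver: generate → analyze → report.

A :class:`RunConfig` collects every tunable of the analysis modules
(cutoffs, windows, bin widths, the seed) and validates unknown keys
before any computation.  ``run_generate`` writes a synthetic system +
trajectory + truth manifest; ``run_analyze`` runs the enabled analyses
and writes one TSV per result plus a JSON summary; ``run_report``
renders a human-readable summary from the bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import bilayer as bilayer_obs
from . import energetics, interactions, landscape, peptide as peptide_obs
from . import synth
from .core import DomainError, MolecularSystem, Trajectory
from .pdbio import read_structure, read_trajectory, write_structure, write_trajectory
from .tabular import file_sha256, write_tsv

log = logging.getLogger("pepmem")

__all__ = ["RunConfig", "run_generate", "run_analyze", "run_report"]


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    outdir: str = "pepmem_out"
    seed: int = 0
    # generator
    n_frames: int = 50
    dt_ns: float = 1.0
    lipids_per_leaflet: int = 77
    Zp: float = 17.0
    box_xy: Sequence[float] = (74.88, 74.37)
    box_z: float = 124.39
    head_z_sigma: float = 1.5
    chain_length: int = 13
    target_SCD: Optional[Sequence[float]] = None
    sequence: str = synth.AB42_SEQUENCE
    conformation: str = "extended"
    com_z: float = 25.0
    cu_bound: bool = False
    noise_sigma: float = 0.0
    n_ca: int = 80
    n_cl: Optional[int] = None
    ion_placement: str = "bulk"
    # analysis
    tau_eq_ns: float = 0.0
    contact_cutoff: float = 6.5
    lipid_segments: Sequence[str] = ("S1", "S2", "S3", "S4")
    d0: float = 4.5
    sb_formed_cutoff: float = 5.0
    hb_dist: float = 3.5
    hb_angle: float = 135.0
    com_contact_cutoff: float = 8.0
    density_bin_width: float = 0.5
    density_normalize: str = "per_atom"
    insertion_bin_width: float = 0.5
    surface_band: float = 6.5
    probe_radius: float = 1.4
    sasa_points: int = 960
    energy_window_ns: float = 10.0
    energy_cutoff: Optional[float] = None
    membrane_group: str = "S2"
    fes_temperature: float = 300.0
    fes_bins: int = 50
    cluster_cutoff: float = 4.0
    cluster_top_k: int = 10
    analyses: Sequence[str] = (
        "bilayer", "peptide", "interactions", "energetics", "landscape"
    )
    keep_going: bool = False

    @classmethod
    def from_dict(cls, data: Dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise DomainError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def generator_specs(self):
        bspec = synth.BilayerSpec(
            lipids_per_leaflet=self.lipids_per_leaflet, Zp=self.Zp,
            box_xy=tuple(self.box_xy), box_z=self.box_z,
            head_z_sigma=self.head_z_sigma, chain_length=self.chain_length,
            target_SCD=self.target_SCD,
        )
        pspec = synth.PeptideSpec(
            sequence=self.sequence, conformation=self.conformation,
            com_z_path=np.full(self.n_frames, self.com_z),
            cu_bound=self.cu_bound, noise_sigma=self.noise_sigma,
        )
        ispec = synth.IonSpec(n_ca=self.n_ca, n_cl=self.n_cl,
                              placement=self.ion_placement)
        return bspec, pspec, ispec


def run_generate(config: RunConfig) -> Dict[str, str]:
    """Generate a synthetic system/trajectory/manifest and write them to disk."""
    bspec, pspec, ispec = config.generator_specs()
    system, traj, manifest = synth.generate_trajectory(
        bspec, pspec, ispec, n_frames=config.n_frames, seed=config.seed,
        dt_ns=config.dt_ns, surface_band=config.surface_band,
    )
    gen_dir = os.path.join(config.outdir, "generated")
    os.makedirs(gen_dir, exist_ok=True)
    paths = {
        "structure": os.path.join(gen_dir, "system.pdb"),
        "trajectory": os.path.join(gen_dir, "trajectory.pdb"),
        "manifest": os.path.join(gen_dir, "manifest.json"),
    }
    write_structure(paths["structure"], system, box=traj.box[0])
    write_trajectory(paths["trajectory"], system, traj)
    manifest.to_json(paths["manifest"])
    log.info("generated %d frames, %d atoms", traj.n_frames, system.n_atoms)
    return paths


def _load_inputs(config: RunConfig):
    gen_dir = os.path.join(config.outdir, "generated")
    system = read_structure(os.path.join(gen_dir, "system.pdb"))
    from .core import assign_lipid_segments
    if system.lipids:
        assign_lipid_segments(system)
    traj = read_trajectory(os.path.join(gen_dir, "trajectory.pdb"), system,
                           dt_ns=config.dt_ns)
    return system, traj


def run_analyze(
    config: RunConfig,
    system: Optional[MolecularSystem] = None,
    trajectory: Optional[Trajectory] = None,
) -> Dict[str, Any]:
    """Run every enabled analysis; write TSVs and a JSON summary.

    Analyses fail fast by default; with ``keep_going`` a failure is
    recorded in the summary and the remaining analyses still run.
    """
    if system is None or trajectory is None:
        system, trajectory = _load_inputs(config)
    ana_dir = os.path.join(config.outdir, "analysis")
    os.makedirs(ana_dir, exist_ok=True)
    if config.tau_eq_ns > 0:
        idx = peptide_obs.equilibration_window(trajectory.times, config.tau_eq_ns)
        window = list(idx)
        traj_w = Trajectory(trajectory.coords[idx], trajectory.box[idx],
                            trajectory.times[idx])
    else:
        window = None
        traj_w = trajectory
    summary: Dict[str, Any] = {"seed": config.seed, "errors": {}, "files": {}}

    def emit(name: str, frame: pd.DataFrame, **meta) -> None:
        path = os.path.join(ana_dir, name + ".tsv")
        summary["files"][name] = write_tsv(path, frame, meta)

    def section(name: str, fn) -> None:
        if name not in config.analyses:
            return
        try:
            fn()
        except Exception as exc:
            if not config.keep_going:
                raise type(exc)(f"[{name}] {exc}") from exc
            log.error("[%s] failed: %s", name, exc)
            summary["errors"][name] = str(exc)

    def do_bilayer() -> None:
        from .core import MidplaneError
        if not system.lipids:
            raise MidplaneError("input system contains no bilayer lipids")
        apl = bilayer_obs.area_per_lipid(traj_w, config.lipids_per_leaflet)
        emit("area_per_lipid", pd.DataFrame(
            {"frame": np.arange(traj_w.n_frames), "time_ns": apl.times,
             "A_L": apl.values}))
        summary["area_per_lipid_mean"] = apl.mean
        scd = bilayer_obs.order_parameters(traj_w, system)
        emit("scd_profile", pd.DataFrame(
            {"carbon": scd.carbon_index, "scd": scd.scd, "stderr": scd.stderr}))
        thick = bilayer_obs.bilayer_thickness(traj_w, system)
        summary["bilayer_thickness_mean"] = thick.mean
        groups = {
            "P": system.phosphorus_indices(),
            **{sp: idx for sp, idx in system.ion_indices.items()},
            "peptide": system.peptide_indices,
        }
        groups = {k: v for k, v in groups.items() if len(v)}
        prof = bilayer_obs.density_profile(
            traj_w, system, groups, bin_width=config.density_bin_width,
            normalize=config.density_normalize)
        emit("density_profile", pd.DataFrame(
            {"z_mid": prof.z_mid, **{k: v for k, v in prof.values.items()}}))

    def do_peptide() -> None:
        pep = system.peptide_indices
        masses = system.masses[pep]
        ref = traj_w.coords[0, pep]
        rows = []
        for f in range(traj_w.n_frames):
            xyz = traj_w.coords[f, pep]
            rows.append({
                "frame": f, "time_ns": traj_w.times[f],
                "rmsd": peptide_obs.rmsd(ref, xyz, masses),
                "rg": peptide_obs.radius_of_gyration(xyz, masses),
            })
        series = pd.DataFrame(rows)
        sasa_df = peptide_obs.sasa(
            traj_w.coords[-1], system, pep,
            probe_radius=config.probe_radius, n_points=config.sasa_points)
        series["sasa_total"] = np.nan
        series.loc[series.index[-1], "sasa_total"] = sasa_df["sasa"].sum()
        emit("series", series)
        emit("sasa", sasa_df)
        ca = [system.find_atom(rid, "CA") for rid, _ in system.peptide_residues]
        r = peptide_obs.rmsf(traj_w, ca)
        emit("rmsf", pd.DataFrame(
            {"residue": [rid for rid, _ in system.peptide_residues], "rmsf": r}))
        codes = []
        for f in range(traj_w.n_frames):
            phi, psi = peptide_obs.compute_phi_psi(system, traj_w.coords[f])
            codes.append(peptide_obs.assign_ss_from_dihedrals(phi, psi))
        content = peptide_obs.ss_aggregate(codes)
        tbl = content.percent.copy()
        tbl.insert(0, "class", tbl.index)
        emit("ss_content", tbl.reset_index(drop=True))
        summary["ss_content"] = {
            c: dict(content.percent.loc[c].round(3)) for c in content.percent.index
        }
        summary["rg_mean"] = float(series["rg"].mean())
        summary["rmsd_mean"] = float(series["rmsd"].mean())

    def do_interactions() -> None:
        cm = interactions.residue_contact_map(
            traj_w, system, cutoff=config.contact_cutoff)
        emit("contact_map", cm.to_frame())
        sb = interactions.salt_bridges(traj_w, system, d0=config.d0)
        emit("salt_bridges", sb.table)
        summary["salt_bridge_pairs"] = int(len(sb.table))
        summary["salt_bridge_mean_count"] = sb.counts.mean
        hb, hb_counts = interactions.hydrogen_bonds(
            traj_w, system, d_cut=config.hb_dist, angle_cut=config.hb_angle)
        emit("hbonds", hb)
        summary["hbond_mean_count"] = hb_counts.mean
        if system.lipids:
            pl = interactions.peptide_lipid_contacts(
                traj_w, system, cutoff=config.contact_cutoff,
                segments=tuple(config.lipid_segments))
            emit("peptide_lipid_contacts", pl.reset_index())
            prof = interactions.insertion_profile(
                traj_w, system, bin_width=config.insertion_bin_width,
                surface_band=config.surface_band)
            emit("insertion", prof.to_frame())
            summary["insertion_classes"] = {
                str(r): c for r, c in zip(prof.residues, prof.classification)
            }
            mem = np.concatenate([lip.indices for lip in system.lipids])
            dist, frac = interactions.com_distance_series(
                traj_w, system, system.peptide_indices, mem,
                contact_cutoff=config.com_contact_cutoff)
            emit("com_distance", pd.DataFrame(
                {"time_ns": dist.times, "distance": dist.values}))
            summary["peptide_bilayer_contact_fraction"] = frac

    def do_energetics() -> None:
        charges = energetics.default_charge_model(system)
        mem = np.concatenate(system.segment_atom_indices(config.membrane_group))
        span = traj_w.times[-1] - traj_w.times[0]
        window_ns = min(config.energy_window_ns, span) if span > 0 else config.energy_window_ns
        win = energetics.windowed_binding_series(
            traj_w, charges, system.peptide_indices, mem,
            window_ns=window_ns, cutoff=config.energy_cutoff)
        emit("energy_windows", win)
        per_res = energetics.per_residue_decomposition(
            traj_w, system, charges, mem, cutoff=config.energy_cutoff)
        emit("energy_per_residue", per_res)
        summary["energy_mm_mean"] = float(win["e_mm"].mean())

    def do_landscape() -> None:
        pep = system.peptide_indices
        masses = system.masses[pep]
        ref = traj_w.coords[0, pep]
        rg = np.array([peptide_obs.radius_of_gyration(traj_w.coords[f, pep], masses)
                       for f in range(traj_w.n_frames)])
        rm = np.array([peptide_obs.rmsd(ref, traj_w.coords[f, pep], masses)
                       for f in range(traj_w.n_frames)])
        fes = landscape.fes_2d(rg, rm, T=config.fes_temperature,
                               bins=config.fes_bins)
        occ = np.isfinite(fes.G)
        ii, jj = np.nonzero(occ)
        emit("fes", pd.DataFrame({
            "rg_mid": fes.rg_mid[ii], "rmsd_mid": fes.rmsd_mid[jj],
            "G": fes.G[ii, jj]}))
        minima = landscape.find_minima(fes)
        emit("fes_minima", minima)
        ca = [system.find_atom(rid, "CA") for rid, _ in system.peptide_residues]
        cl = landscape.cluster_conformers(
            traj_w, ca, cutoff=config.cluster_cutoff, top_k=config.cluster_top_k)
        emit("clusters", pd.DataFrame(
            {"frame": np.arange(traj_w.n_frames), "cluster": cl.assignments}))
        emit("cluster_summary", cl.top_k(config.cluster_top_k))
        summary["n_clusters"] = cl.n_clusters
        summary["fes_minima"] = minima.drop(
            columns=["bin_i", "bin_j"]).to_dict("records")

    section("bilayer", do_bilayer)
    section("peptide", do_peptide)
    section("interactions", do_interactions)
    section("energetics", do_energetics)
    section("landscape", do_landscape)

    # composition / charge bookkeeping
    total_charge = float(system.charges.sum())
    summary["composition"] = {
        "peptide_residues": len(system.peptide_residues),
        "lipids": len(system.lipids),
        "ions": {sp: int(len(idx)) for sp, idx in system.ion_indices.items()},
        "total_formal_charge": total_charge,
    }
    with open(os.path.join(ana_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    return summary


def run_report(config: RunConfig) -> str:
    """Render a markdown report from an analysis bundle."""
    ana_dir = os.path.join(config.outdir, "analysis")
    with open(os.path.join(ana_dir, "summary.json")) as fh:
        summary = json.load(fh)
    lines = ["# pepmem analysis report", ""]
    comp = summary.get("composition", {})
    ions = comp.get("ions", {})
    ion_str = " + ".join(f"{n} {sp}" for sp, n in ions.items()) or "no ions"
    lines.append(
        f"Composition: {comp.get('peptide_residues', 0)}-residue peptide + "
        f"{comp.get('lipids', 0)} lipids + {ion_str}; total formal charge "
        f"{comp.get('total_formal_charge', float('nan')):+.1f} e"
    )
    lines.append("")
    for key, label, unit in (
        ("area_per_lipid_mean", "Area per lipid", "Å²"),
        ("bilayer_thickness_mean", "Bilayer thickness", "Å"),
        ("rg_mean", "Mean radius of gyration", "Å"),
        ("rmsd_mean", "Mean RMSD", "Å"),
        ("salt_bridge_pairs", "Candidate salt-bridge pairs", ""),
        ("hbond_mean_count", "Mean H-bond count", ""),
        ("energy_mm_mean", "Mean peptide–membrane ΔE_MM", "kcal/mol"),
        ("n_clusters", "Conformer clusters", ""),
    ):
        if key in summary:
            v = summary[key]
            vtxt = f"{v:.3f}" if isinstance(v, float) else str(v)
            lines.append(f"- {label}: {vtxt} {unit}".rstrip())
        else:
            lines.append(f"- {label}: not computed")
    if "ss_content" in summary:
        lines += ["", "## Secondary-structure content (%)", ""]
        df = pd.DataFrame(summary["ss_content"]).T
        lines.append(df.to_string())
    # checksum verification
    stale = []
    for name, digest in summary.get("files", {}).items():
        path = os.path.join(ana_dir, name + ".tsv")
        if os.path.exists(path) and file_sha256(path) != digest:
            stale.append(name)
    if stale:
        lines += ["", f"WARNING: checksum mismatch for: {', '.join(stale)}"]
    report = "\n".join(lines) + "\n"
    rep_dir = os.path.join(config.outdir, "report")
    os.makedirs(rep_dir, exist_ok=True)
    with open(os.path.join(rep_dir, "report.md"), "w") as fh:
        fh.write(report)
    return report
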