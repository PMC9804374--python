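# Methods

## Scope and conventions

`pepmem` analyzes peptide–membrane trajectories: a structure (PDB), a
trajectory (multi-model PDB or XYZ with an `Lx Ly Lz time` box
sidecar), and optionally per-frame DSSP-style secondary-structure
strings. Coordinates are in Å, times in ns, masses in amu, charges in
e; residues are numbered from 1 (Asp1…Ala42 for the default amyloid-β
peptide). Boxes are orthorhombic, and molecules are assumed whole: no
minimum-image reconstruction is applied inside center-of-mass (COM)
arithmetic. `flag_wrapping_artifacts` reports any atom whose nearest
intra-molecule neighbour is farther than 5 Å, the usual signature of a
molecule split across a periodic boundary. The literature never states
whether peptide–membrane COM distances use wrapped or unwrapped
coordinates; requiring whole molecules makes the choice explicit.

Residue classification (peptide / lipid / ion / water) is a plain
editable dictionary keyed on residue names; element inference falls
back from the PDB element column to atom-name heuristics that use
residue context (`CA` in an amino acid is a carbon, in an ion residue
it is calcium) and raise rather than guess when neither resolves.

## The synthetic generator

The generator is geometry plus exactly specified statistics — no
physics. It exists so that every downstream estimator can be checked
against a planted truth.

* **Bilayer.** Two leaflets of coarse DMPC-like lipids (default 77 per
  leaflet) on an xy grid (8 Å spacing; over-filling the grid is a
  packing error). Each lipid has realistically named atoms — choline
  N4/C15 (segment S1), phosphate P/O13/O14 (S2), glycerol CG1–3 (S3),
  and two 13-carbon tails C2A…/C3A… with two hydrogens per carbon
  (S4/S5) — so segment rules and order-parameter analysis both apply
  to it unchanged. Heads are built exactly at ±Zp (default 17 Å);
  every frame each lipid receives a rigid z-displacement drawn from
  N(0, `head_z_sigma` = 1.5 Å), emulating head-group thermal motion,
  so the per-frame leaflet phosphorus COM is ~N(±Zp, σ/√77).
* **Order parameters.** C–H orientations are resampled each frame from
  a two-point mixture over the tilt θ ∈ {0°, 90°} with
  P(θ = 0) = (2·S + 1)/3, which makes ⟨(3cos²θ − 1)/2⟩ equal the
  per-carbon target S exactly. A Boltzmann cone distribution would be
  more physical; the mixture is chosen because its expectation is
  exactly solvable, so calibration tests have closed-form targets. The
  default per-carbon profile declines linearly from 0.20 to 0.05,
  qualitatively like a fluid saturated chain.
* **Peptide.** Backbones are built by sequential ideal-geometry
  placement from per-residue (φ, ψ) presets (`extended`,
  `helix_C_term`, `hairpin_17_33`), then rotated onto principal axes so
  the chain lies in the xy plane; side chains are reduced to the atoms
  the analyses need (Cβ plus Lys NZ, Arg NH1/NH2, Asp CG, Glu CD). The
  whole peptide is translated each frame so its COM z follows
  `com_z_path` (default constant 25 Å, i.e. sitting above the upper
  leaflet); optional per-residue z-offsets, planted salt-bridge
  distance schedules, planted hydrogen bonds, and per-frame Gaussian
  jitter (`noise_sigma`) overlay that.
* **Ions.** Default 80 Ca²⁺ with Cl⁻ chosen by exact neutralization
  (n_Cl = q_peptide + 2·n_Ca, giving 157 for the free peptide and 159
  Cu-bound). The stated experimental Ca²⁺ concentrations are mutually
  inconsistent with these counts, so counts are taken literally and no
  concentration→count conversion is attempted. Placements: `bulk`
  (uniform outside |z| > Zp + 8 Å), `interfacial` (±(Zp + 2 Å)), or
  `bridging`, which stretches each charged side-chain representative
  atom to 3 Å above its nearest upper-leaflet phosphorus and pins a
  Ca²⁺ near the midpoint — a purely geometric construction (ions may
  nearly coincide) that realizes the calcium-bridge motif for
  energetic sign tests.
* **Cu-bound variant.** `cu_bound` appends a Cu²⁺ pseudo-atom near the
  N-terminal coordination site and changes the sequence-level formal
  charge from −3 to −1. The sources describe this as the metal's +2
  offset by an N-terminal deprotonation, but the printed net charges
  (−3 free, −1 bound) and Cl⁻ counts (157/159) are only mutually
  consistent with a net +2 change; the printed values govern.
* **Truth manifest.** Records exactly what the sampler used: Zp, A_L,
  the per-carbon S_CD targets, per-residue insertion depths and
  classes, residue pairs within 6.5 Å, planted salt bridges and
  hydrogen-bond triples, surface-contact residues, the peptide net
  charge and the seed. Geometric truths are taken from the noiseless
  frame-0 construction, never re-estimated from the emitted
  trajectory. All randomness flows from one integer seed through a
  single generator; identical specs and seed give byte-identical
  output.

What the generator does **not** emulate: thermodynamically realistic
bilayers (no undulations, no area fluctuations — the box is constant,
so area per lipid has zero variance by construction), water, realistic
side-chain rotamers, or force-field energetics. Passing recovery tests
therefore demonstrates estimator correctness, not that real MD data
would yield any particular value.

## Analysis choices

* **Area per lipid** is `L_x·L_y / n` per frame. The experimental-scale
  value (~62 Å²) arises from barostat-equilibrated boxes; with the
  generator's fixed default box the value is 72.32 Å² and serves only
  as a consistency check.
* **S_CD** pools both chains and both leaflets (cos²θ makes the leaflet
  flip automatic); the standard error is over lipids, not frames, to
  avoid autocorrelation assumptions.
* **Density profiles** default to 0.5 Å bins with the midplane (mean of
  the two leaflet phosphorus COM z) recomputed per frame, which removes
  collective drift. `per_atom` normalization divides each group's mass
  profile by its atom count. Peak positions use the maximum-density
  bin center, with a flat maximal plateau resolved to its midpoint.
* **Thickness** is |COM_z(P, upper) − COM_z(P, lower)| per frame; a
  density-peak-separation variant is provided and agrees within one bin
  width on synthetic data.
* **RMSD/RMSF** use least-squares superposition (weighted
  Kabsch via quaternion alignment) after COM removal; RMSF can skip
  alignment for closed-form checks.
* **SASA** is Shrake–Rupley sphere sampling (default 960 points, probe
  1.4 Å, element vdW radii) rather than the LCPO approximation used by
  some MD toolchains: LCPO's overlap coefficients are force-field
  specific, while sphere sampling is parameter-free at equal probe
  radius. Exactly coincident atoms are collapsed before sampling so
  duplicated positions cannot double-count surface.
* **Secondary structure** is consumed as DSSP-style strings; classes
  are BS ← {E, B}, H ← {H, G, I}, T ← {T}, RC ← {S, C} (isolated
  bridges counted as sheet, bends as coil — the conservative reading of
  the four-class convention). Standard errors are across replicas when
  several are supplied, otherwise from five contiguous time blocks. A
  deliberately approximate dihedral-window assigner (helix
  φ ∈ [−100, −30], ψ ∈ [−80, −5]; strand φ ∈ [−180, −105],
  ψ ∈ [105, 180]; else coil) is included for self-contained tests; it
  ignores hydrogen-bond topology entirely.
* **Contacts** use strict `<` for the 6.5 Å residue–residue rule and
  `≤` for the peptide–lipid rule, following the wording of each
  criterion; equality is a measure-zero concern. Sequence-separation
  classes partition s ≥ 6 as short 6–11, medium 12–23, long ≥ 24 (the
  boundary 24 assigned long so the classes tile). Peptide–lipid
  contacts default to segments S1–S4, matching the stated analysis
  convention even though five segments exist; S5 is available by flag
  since the omission may be a typo. A Cα-based contact mode is
  provided alongside the default COM mode.
* **Salt bridges** use one representative atom per charged group; Arg
  has two Nη atoms and the minimum over NH1/NH2 is used (and
  recorded). Occupancy is over all 3 × 6 = 18 candidate pairs for the
  default sequence; a separate distance-series operation applies the
  5 Å "formed" criterion used for individual pair analyses.
* **Hydrogen bonds**: donors are N/O atoms with a hydrogen within
  1.25 Å in the first frame; acceptors are N/O; a bond requires
  X–Y < 3.5 Å and the X–H···Y angle at H strictly greater than 135°.
* **Insertion**: per-residue histograms of |z − midplane|; modal depth
  below Zp → inserted, within `surface_band` (default 6.5 Å, matching
  the contact cutoff) above Zp → surface, beyond → detached.
* **Energetics** computes only inter-group gas-phase terms:
  ΔE_elec = Σ k_e q_i q_j / r_ij (k_e = 332.0637 Å·kcal/mol/e²) and
  Lennard-Jones ΔE_vdw with Lorentz–Berthelot combining; no periodic
  images; optional distance cutoff (default none); pairs closer than
  0.1 Å are a singularity error. The default charge model is a
  pedagogical surrogate (formal charges on representative atoms,
  zwitterionic P⁻/N4⁺ headgroup, uniform σ = 3.5 Å, ε = 0.1 kcal/mol),
  not a force field; outputs are named ΔE because the solvation and
  entropy terms of a true binding free energy are out of scope. The
  membrane group defaults to the phosphate segment S2 only —
  whether headgroup N and glycerol atoms should be included is
  genuinely open, so it is configurable. Windowed averages use
  non-overlapping 10 ns windows; frame-level standard errors carry no
  autocorrelation correction.
* **Free-energy surfaces** bin (Rg, RMSD) into 50 × 50 cells over the
  observed range padded 5% (binning is unstated in the source
  methodology); empty bins carry a +∞ sentinel and are never
  interpolated; the modal bin has G = 0 exactly. Basins are assigned
  by discrete steepest descent on the 8-neighborhood; plateau ties go
  to the lower-G neighbour, then the lexicographically smaller bin.
  Basin populations are one defensible boundary definition among
  several — published basin populations depend on an unstated choice
  here.
* **Clustering**: the usual "K-clustering with a distance cutoff" is
  ambiguous between k-means and hierarchical clustering, but a 4.0 Å
  cutoff only types as hierarchical/ε clustering, so average linkage on
  the pairwise superposition-RMSD matrix cut at the cutoff is the
  default (k-means with a fixed seed is available). Clusters are
  relabelled by population; representatives are medoids.
* **Equilibration**: averages default to frames with t ≥ τ_eq
  (200 ns convention); τ_eq = 0 analyzes everything.

## Problem sizes in tests

The test suite and acceptance checks use a mixture of full-size
generator runs (154 lipids, 42 residues) for contract checks and small
systems (4–16 lipids/leaflet, ≤ 30 frames, 10-residue fragments) where
brute-force oracles are exercised; calibration checks use 200 frames ×
154 lipids, where the binomial standard error of the order-parameter
estimate is well under the ±0.02 tolerance. These sizes are the
package's chosen verification scale; they complete in seconds.

## Known limitations

* The generator's trajectories have no dynamics — frames are
  independent draws around a static geometry — so autocorrelation-aware
  estimators cannot be validated here.
* The dihedral secondary-structure assigner is a labelled
  approximation; quantitative SS content on real data should come from
  a hydrogen-bond-based assigner.
* The default charge model supports sign- and additivity-level
  reasoning only; per-residue energies on real systems require real
  force-field parameters supplied as a user table.
* Binary trajectory formats (DCD/XTC) are out of scope; convert to
  multi-model PDB or XYZ first.
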