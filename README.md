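# lipidobs

Trajectory observables for membrane–peptide molecular-dynamics systems —
built for studying how cationic antimicrobial peptides (AMPs) perturb a
multi-component Gram-positive lipid bilayer, and verifiable end to end on
synthetic trajectories with analytic ground truth.

## Who it is for

Researchers analysing all-atom MD simulations of peptide–bilayer systems
who need the standard battery of membrane observables as a reproducible,
tested pipeline rather than a pile of one-off scripts:

- **Energetics** — short-range Coulomb/Lennard-Jones interaction energy
  decomposed by peptide residue × lipid species, with net, per-molecule
  normalized and percentage contributions, and block-averaged errors.
- **Hydrogen bonds** — geometric (distance + angle) detection, residue ×
  species count tables with marginals.
- **Profiles** — number/charge/electron density along the bilayer normal,
  electrostatic potential ψ(z) from the 1D Poisson equation, P–P bilayer
  thickness, 2D density maps.
- **Lateral order** — leaflet assignment, distance-threshold lipid
  clustering (NC and its normalized form NNC), RDF/NRDF, CH order
  parameters S_CD.
- **Dynamics** — leaflet-resolved mean-square displacement and lateral
  diffusion coefficients D_L via the Einstein relation.
- **Shape** — gyration tensor, radius of gyration and relative shape
  anisotropy κ² distributions for the peptides.

Every observable has a matching generator in `lipidobs.synthetic` that
plants a known answer (true D, true C–H tilt angle, planted cluster count,
analytic capacitor potential, exact κ²), so each stage is tested against an
oracle instead of against itself.

## The statistics, in standard notation

- Pair energies: `E_C = f q_i q_j / r` with `f = 138.935458 kJ mol⁻¹ nm e⁻²`
  and `E_LJ = 4ε[(σ/r)¹² − (σ/r)⁶]`, truncated at a cutoff (default 1.2 nm)
  under the minimum-image convention; Lorentz–Berthelot combining.
- Electrostatic potential: `ψ(z) = −(1/ε₀) ∫_{z₀}^{z} dz′ ∫_{z₀}^{z′} ρ(z″) dz″`
  with ρ the charge density and ψ(z₀)=0 at the water-slab reference.
- CH order parameter: `S_CD = |⟨(3 cos²θ − 1)/2⟩|`, θ the angle between a
  C–H bond and the bilayer normal.
- Cluster statistic: NC = time-averaged count of single-linkage connected
  components at a 0.35 nm contact threshold; NNC = NC / N_species.
- Lateral diffusion: `MSD(τ) = ⟨|r(t+τ) − r(t)|²⟩ = 4 D_L τ` in the linear
  regime (2 lateral dimensions).
- Relative shape anisotropy: with gyration-tensor eigenvalues
  λ₁ ≥ λ₂ ≥ λ₃ and Rg² = λ₁+λ₂+λ₃,
  `κ² = 1 − 3(λ₁λ₂ + λ₂λ₃ + λ₃λ₁)/(λ₁+λ₂+λ₃)²`
  (1 = linear chain, 0.25 = symmetric planar, 0 = fully symmetric).

Uncertainties everywhere are block-averaging standard errors (default 5
blocks). Units are GROMACS conventions: nm, ps, kJ/mol, e, amu; D_L is
reported in cm²/s.

## Worked example

Generate a Brownian bilayer whose true lateral diffusion coefficient is
5×10⁻⁷ cm²/s (22 single-site MAIPG lipids per leaflet, 200 frames at
100 ps), then recover D_L and the cluster statistics:

```sh
lipidobs generate brownian --seed 7 --out-prefix walk
lipidobs msd --traj walk.gro --topo walk.topology.json --species MAIPG --out msd.tsv
cat msd.D.json
```

```json
{
  "species": "MAIPG",
  "D_L_cm2_s": 4.785449479563138e-07,
  "stderr_cm2_s": 3.0253430199248478e-09,
  "fit_window_ps": [1590.0, 12720.0],
  "r_squared": 0.9956228511493336
}
```

The Einstein-relation fit over the 10–80 % lag window recovers
D_L = 4.79×10⁻⁷ cm²/s, within 5 % of the planted 5×10⁻⁷ cm²/s truth
(r² ≈ 0.996 confirms the diffusive, linear regime).

```sh
lipidobs cluster --traj walk.gro --topo walk.topology.json --species MAIPG --out cl.tsv
cat cl.tsv
```

```
species	NC	NC_err	NNC	N
MAIPG	21.005	0.266857	0.954773	22
```

Freely diffusing lipids are almost all isolated at the 0.35 nm threshold:
on average 21.0 of the 22 upper-leaflet lipids form their own cluster, so
NNC ≈ 0.95, near its upper bound of 1 (a single blob would give 1/22).

The same stages run from a config file:

```sh
lipidobs run --config analysis.yaml     # writes TSVs + manifest.json
```

## File formats

**Trajectories** are multi-frame GRO (fixed-column, 3-decimal nm, `t=`
time headers) or multi-MODEL PDB; boxes must be orthorhombic.

**Topologies** are a JSON sidecar:

```json
{"version": 1,
 "atoms": [{"atom_id": 0, "name": "P", "atomic_number": 15,
            "residue_name": "MAIPG", "residue_index": 1, "molecule_id": 1,
            "species": "MAIPG", "charge": -1.0, "lj_sigma": 0.35,
            "lj_epsilon": 0.5, "mass": 30.97, "leaflet": "upper",
            "bonded_to": null}],
 "chain_map": {"MAIPG": {"SN1": {"carbons": ["C11"],
                                  "hydrogens": {"C11": ["H11A", "H11B"]}}}}}
```

`species` is one of the nine membrane lipids (AIPE, AIPG, DPPE, DPPG,
MAIPE, MAIPG, PAIPE, PAIPG, PAICL) or PEPTIDE / WATER / ION; `bonded_to`
optionally pins a hydrogen to its donor heavy atom; `chain_map` names the
acyl-chain carbons and their hydrogens for the order-parameter stage.

**Selections** use a small grammar:
`field == VALUE` terms joined by `and` / `or` (with parentheses), where
field is `species`, `residue_name`, `residue_index`, `name` or `leaflet` —
e.g. `"species == MAIPG and leaflet == upper"`.
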