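# Methods

This note records the models and conventions behind each observable, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerically delicate choices.

## Scope and design

The package analyses existing trajectories; it never integrates equations
of motion. Coordinates travel as multi-frame GRO / multi-MODEL PDB with
orthorhombic boxes only (triclinic cells are rejected with a clear error),
and all per-atom metadata — partial charge, LJ σ/ε, mass, atomic number,
residue and species labels, optional leaflet and hydrogen-bond parentage —
lives in a JSON sidecar. Decoupling the topology from any MD engine's
force-field dialect keeps the analysis reusable across engines; the cost
is that the user (or the synthetic generators) must produce the sidecar.
Units are GROMACS conventions throughout: nm, ps, kJ/mol, e, amu.

The default analysis window is the full trajectory. Production workflows
that discard equilibration (for instance analysing only the second half of
a microsecond run) express that through `slice_time`/config, not through
hard-coded defaults.

## Uncertainties

All time averages carry block-averaging errors: the frame series is split
into `n_blocks` contiguous blocks (default 5; the trailing remainder goes
to the last block) and the standard error of the block means is reported.
For uncorrelated data this reduces to the ordinary SEM as the block count
approaches the sample count; for correlated MD series 5 blocks is a
conservative, conventional choice. Series shorter than the block count
are refused rather than silently under-blocked.

## Interaction energies

Pairwise Coulomb (`f·q_iq_j/r`, `f = 138.935458 kJ mol⁻¹ nm e⁻²`) and
Lennard-Jones (`4ε[(σ/r)¹²−(σ/r)⁶]`) terms are summed over
peptide-atom/lipid-atom pairs within a 1.2 nm cutoff under the minimum
image, binned into (residue, lipid-species) cells per frame, then
time-averaged. Decisions:

- **Short-range truncation only, no mesh electrostatics.** A per-pair
  decomposition of PME is ill-defined; group-wise energy reports from MD
  engines are likewise short-range terms. Absolute values therefore carry
  a truncation semantic and are meant for *comparisons* (between residues,
  species, or systems), not as total electrostatic energies.
- **Lorentz–Berthelot combining** (arithmetic σ, geometric ε) by default,
  geometric–geometric by flag, since the topology stores per-atom
  parameters.
- **No intramolecular exclusions**: the two groups are disjoint molecules
  by construction (the reference selection is removed from the partner
  group), so 1-4 exclusion lists never apply.
- The neighbour search uses a periodic KD-tree; an all-pairs path
  (`method="brute"`) exists solely so tests can assert the two agree to
  1e-8 kJ/mol.
- No dispersion correction is applied.

The contribution arithmetic — net share = 100·(species column sum)/(grand
sum), normalized = net/(molecules of the species), percentage share of the
electrostatic component, fold changes between systems — is plain
arithmetic on the matrices and is tested against published worked
examples digit for digit.

## Hydrogen bonds

Geometric criteria: donor–acceptor distance ≤ 0.35 nm and H–D–A angle
≤ 30°, both inclusive, both exposed as flags — these are the de-facto
standard values, and the source analyses never state theirs, so the
defaults are documented as ours rather than asserted as anyone else's.
Donors are N*/O* heavy atoms with at least one bonded hydrogen; acceptors
are N*/O* atoms. Hydrogen parentage comes from an explicit `bonded_to`
field when the topology carries one, else from proximity (nearest same-
molecule N/O within 0.12 nm). Each (donor, hydrogen, acceptor) triplet
counts once per frame, so a bidentate arginine contact contributes two
triplets — consistent with how residue-level count tables treat such
contacts. Water-mediated bridges are not counted.

## Density profiles, potential, thickness

Profiles are histograms along z in a membrane-centred frame (z measured
from the per-frame mass-weighted centre of all lipid atoms; box centre
when no lipids exist, e.g. for calibration fixtures). Default bin width
0.05 nm. Weights: 1, partial charge, atomic number (optionally minus the
partial charge — the electron-count convention is not standardized, so
integer Z is the default), or mass. Per-frame bin volumes absorb box
fluctuations.

ψ(z) integrates the binned charge density twice with cumulative
trapezoids from the reference z₀ (conventionally the water-slab midpoint)
and is shifted so ψ(z₀)=0; the unit conversion is
e/nm → V via e/(nm·ε₀) = 18.0948 V. The parallel-plate fixture provides
the analytic check: two discretized sheets of ±σ at gap d must produce a
drop σd/ε₀ (1.809 V for σ = 0.1 e/nm², d = 1 nm), and the error must
shrink monotonically as bins halve — binning is the only discretization
knob.

Bilayer thickness is the distance between the two leaflet peaks of the
phosphate (electron-)density, each refined by 3-point parabolic
interpolation so the estimate beats the bin resolution. Each side of the
membrane centre must carry a genuine peak (≥ 5 % of the global maximum)
or the input is rejected; profiles are not symmetrized before peak
reading.

## Clustering, RDF, order parameters

Clustering is single-linkage: lipids of one species join iff *any*
interatomic distance is within the threshold (default 0.35 nm), computed
per species within the upper leaflet (headgroup-only contact available by
flag). Components come from a sparse graph; the test oracle is an
independent union–find. NNC divides the time-averaged component count by
the species count *in the analysed leaflet* — the normalization the
statistic needs to be comparable across species of very different
abundance; a whole-membrane denominator is available by flag since the
convention is genuinely ambiguous in the literature.

RDF normalizes pair-distance histograms by the ideal-gas shell count —
spherical shells in 3d (default), annuli for the lateral-2d mode (the
dimensionality convention also varies between studies, hence the flag).
NRDF divides g(r) by the molecule count of the target species. Self-pairs
are excluded; r_max beyond half the smallest box edge is refused.

S_CD averages (3cos²θ−1)/2 over bonded hydrogens and molecules per frame,
block-averages over frames, and takes the modulus of the grand mean (the
experimental convention). The chain map (which carbons form SN1/SN2 and
which hydrogens bond to each) comes from the topology; a carbon without a
recorded hydrogen is an error, not a silent skip. The ordered-chain
generator plants every C–H bond at an exact polar angle with random
azimuth, making |(3cos²θ−1)/2| the exact expectation at every carbon.

## MSD and diffusion

The MSD uses every frame as a time origin (FFT-accelerated, exactly equal
to the O(n²) double loop), averaged over the molecules of a species in a
leaflet, lateral (x,y) by default. Coordinates are unwrapped
frame-to-frame; a wrapped step approaching half a box edge aborts the
analysis since unwrapping is then ambiguous. The centre-of-mass drift of
the analysed molecule set is removed per frame so collective leaflet flow
does not masquerade as diffusion. Leaflet membership is frozen at frame 0
(no flip-flop tracking).

D_L comes from a least-squares fit of MSD(τ) = 2·dims·D·τ over the
10–80 % lag window: short lags are noise-dominated, the longest lags have
few origins. The fit's r² is reported so non-diffusive (e.g. ballistic)
inputs are visible. Conversion: 1 nm²/ps = 10⁻² cm²/s.

## Shape

The gyration tensor is mass-weighted by default (unweighted by flag);
molecules are made whole across the periodic boundary (nearest image to
the first atom) before evaluation. κ² uses the standard invariant form
`1 − 3(λ₁λ₂+λ₂λ₃+λ₃λ₁)/(λ₁+λ₂+λ₃)²`, which reproduces the three analytic
anchors exactly: 1 (line), 0.25 (symmetric planar), 0 (three equal
eigenvalues). Eigenvalues are clipped at 0 against roundoff; a
degenerate, all-coincident point set raises rather than returning 0/0.
κ² densities are histogrammed on [0,1] and normalized to unit integral.

## Synthetic generators: what they emulate and what they don't

Each generator is a pure function of (parameters, seed); random streams
are per-molecule substreams of the master seed, so enlarging a system
never reshuffles existing molecules. The bundled bilayer composition is
the nine-species Gram-positive model membrane (AIPE 11, AIPG 27, DPPE 3,
DPPG 7, MAIPE 9, MAIPG 22, PAIPE 4, PAIPG 9, PAICL 8 per leaflet, with
formal charges 0/−1/−2), 100 lipids per leaflet.

The generators plant *statistical structure*, not physics: single-site
lipids doing ideal 2D Brownian motion at fixed z (default D = 5×10⁻⁷
cm²/s, 100 ps frames — typical of lipid lateral diffusion and of MD
output cadence), rigid chains at exact tilt angles, geometrically
separated clusters, point-charge capacitor plates, rigid shape fixtures.
They contain no excluded volume, no interleaflet coupling, no peptide
adsorption dynamics, no water structure and no force field. Passing the
oracle suites therefore demonstrates that the *estimators* are correct
and unbiased under their own assumptions — it does not validate any
force-field physics, and observables on real trajectories inherit all the
caveats of the simulation that produced them.

Desk-scale problem sizes were chosen so the full suite runs in seconds
while keeping estimator noise well below the asserted tolerances: the
diffusion-recovery check uses 5 seeds × 2000 frames × 200 lipids, the
clustering oracle ≤ 50 lipids (where brute force is exact and cheap), the
energetics oracle ~200 atoms, the RDF sanity check 500 points × 12
frames.

## Known limitations

- Orthorhombic boxes only; no velocities/forces; no TPR/engine topologies.
- Truncated short-range energies are not comparable to mesh-summed
  totals in absolute terms.
- Published trajectory-dependent headline values (absolute kJ/mol
  energies, the 0.68 V potential peak, 3.66 nm thickness, per-species
  NNC/D_L curves) require the original microsecond trajectories, which
  are not deposited; this package reproduces the printed *arithmetic* and
  the analytic anchors, and verifies every estimator against planted
  ground truth instead.
- H-bond lifetimes/kinetics, anomalous-diffusion exponents, Voronoi
  clustering and dielectric profiles are out of scope.
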