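# Methods

## The torsional reduction

The molecules are modelled as rigid-geometry chains: bond lengths and angles
are frozen at standard values (C-C 1.53 Å, Cβ-Sγ 1.81 Å, S-S 2.05 Å, N-Cα
1.458 Å, Cα-C′ 1.525 Å, peptide C-N 1.329 Å; tetrahedral-like angles,
C-S-S 103.8°), and the only degrees of freedom are the rotatable dihedrals.
Cartesian coordinates are reconstructed from internal coordinates by
sequential NeRF placement (atom 0 at the origin, atom 1 on +x, atom 2 in the
xy-plane); every observable is internal, so the seeding convention is
immaterial. Dihedrals follow the IUPAC sign convention and are reported on
[0°, 360°), which makes the closed state of a C-C-S-S dihedral the single
interval [130°, 230°]; signed (-180°, 180°] representations are provided for
interoperability (`geometry.to_signed`), and survey tables carry both.

Three builtin models of increasing complexity:

| model | atoms | torsions | pulled atoms | Cα pair |
|---|---|---|---|---|
| DEDS | 6 (C-C-S-S-C-C) | χ1, χ3, χ2 | terminal C | = pulled |
| cystine | 8 (N-Cα-Cβ-Sγ-Sγ-Cβ-Cα-C′) | 2 side-chain + χ1, χ3, χ2 | N and C′ termini | the two Cα |
| polypeptide-path | 14 | 9 (backbone ψ/φ-like, side chains, χ1, χ3, χ2) | terminal backbone atoms | the two Cys Cα |

The polypeptide-path model is the force-bearing path of an
Ile-Cys-(7 residues)-Cys-Gln disulfide loop. Once a loop is closed by an S-S
bridge, tension short-circuits through the bridge and the intervening loop
residues carry no force, so they are omitted; this keeps the sampler
desk-scale and avoids ring-closure constraints. It is an acknowledged
approximation: the omitted residues would add entropy but not change which
path bears the tension. Peptide ω dihedrals are frozen trans.

## Torsional potentials

Each torsion type carries a three-term Fourier series
`U(φ) = Σₙ ½Vₙ(1 + cos(nφ - γₙ))`, n = 1..3, shipped in the editable file
`src/dscape/data/torsion_params.yaml`:

* **C-C-S-S** (χ1/χ2): near-degenerate trans (0.0 kJ/mol at 180°) and gauche
  (≈0.3 kJ/mol at ±60°) wells with 2.5-4.6 kJ/mol barriers. Two gauche wells
  vs one trans well make open conformers entropically dominant at zero force,
  while the trans (closed) well gives the longest chain extension - the
  mechanism by which force stabilizes closed/closed.
* **C-S-S-C** (χ3): minima near ±90° (the unstrained disulfide), trans
  barrier ≈ 21.5 kJ/mol, cis barrier ≈ 38.5 kJ/mol - the literature scale for
  S-S torsion. The V1 asymmetry displaces the exact minima to ≈ ±98°.
* side-chain and backbone types: soft threefold staggered profiles.

These are effective OPLS-style parameters for a rigid, solvent-free torsional
model, chosen once on the physical grounds above; no claim is made that they
reproduce any particular force field's coefficients.

## Isotensional sampling and the exact oracle

A constant collinear force F adds the mechanical work term `-F·R` to the
energy, with R the distance between the pulled atoms (units: pN and Å;
1 pN·Å = 0.06022 kJ/mol, k_B = 0.0083145 kJ/(mol·K)). Sampling is
single-dihedral-update Metropolis: a randomly chosen dihedral is perturbed by
a wrapped Gaussian step (default width 30°, acceptance ≈ 50-70% across the
force range), default burn-in 10% of steps, thinning 10. Runs are
deterministic given a seed; ladder seeds derive from a master seed and the
force value through `numpy.random.SeedSequence`, so a repeated force
reproduces the identical row.

For models with ≤ 3 torsions, `quadrature_reference` evaluates the Boltzmann
expectations exactly by midpoint quadrature on the periodic grid (default 120
points/dihedral; doubling the grid moves ⟨R⟩ by < 10⁻³ Å). Energies are
shifted by their grid minimum before exponentiation to avoid underflow.
Joint open/closed probabilities weight each grid cell by its exact overlap
with the closed band, so band edges that fall inside a cell do not bias the
result. The sampler is validated against this oracle to within 3 Monte-Carlo
standard errors; standard errors everywhere use batch means over 20 batches,
which is robust to the chain's autocorrelation.

## Landscapes

(χ1, χ2) probability surfaces are periodic 2D histograms (default 72 bins
per axis, i.e. 5° resolution; the values are per-bin probabilities, not
densities per square degree). Boltzmann inversion `G = -k_B T ln P` is
min-shifted so the deepest bin is zero; unsampled bins are flagged rather
than assigned infinite energy, because finite sampling cannot distinguish a
true zero from an unvisited bin (plots clamp them at the maximum sampled
free energy + 5 kJ/mol). The χ3 summary statistic is the mean absolute
deviation from the nearest unstrained minimum (±90°), measuring the
force-induced strain of the central S-S torsion.

## PDB survey

Parsing is gemmi-backed, preceded by a line-level sanity pass that rejects
truncated ATOM/HETMAT records with the offending line number. First model
only for multi-model files; alternate locations resolve to the
highest-occupancy conformer, ties broken by altloc order. Disulfides are the
union of SSBOND declarations and geometric Sγ-Sγ contacts (default cutoff
2.5 Å - generous around the 2.05 Å covalent bond for low-resolution
structures); pairs missing Cα/Cβ/Sγ are excluded with a warning, and
measured bridges with S-S length outside [1.8, 2.5] Å are dropped from
survey tables. The pair is ordered by (chain, residue number): the first
residue supplies χ1, the second χ2. The closed band is inclusive at both
endpoints - the boundary has measure zero in real data and inclusivity makes
tests deterministic. Protein-class labels (TDi, DO, inter/intrachain Ig, ...)
are user-supplied metadata; only the inter- vs intrachain distinction is
derived automatically from chain identifiers.

## Ruler and Bell model

The ruler interpolates (force, mean Cα-Cα distance) calibration points with
a shape-preserving monotone piecewise cubic (PCHIP) - deliberately not a
parametric polymer-elasticity fit, since the response saturates nonlinearly
as the torsional chain approaches full extension. Calibration requires ≥ 3
forces including 0; an adjacent pair whose distance *drops* by more than its
combined 3 SE aborts calibration, while smaller (noise-level) violations are
repaired by isotonic regression plus a strict-increase nudge far below the
statistical resolution. Inversion is Brent root-finding to 0.1 pN;
uncertainty propagates as local calibration SE divided by local slope.
Distances below the zero-force mean report 0 pN with a
"compressive/unstrained" flag; distances beyond the maximal calibrated
extension raise. Rulers are calibrated per model; the observation that
different models fall on a common stress-strain curve is a *result* one can
check, not an input assumption.

Bell's law `k(F)/k0 = exp(F·Δx / k_B T)` requires the length parameter Δx
explicitly (no default); for Δx in the plausible 0.3-0.6 Å range, 100 pN
gives a 2-5× rate enhancement - the "severalfold at 0.1 nN" consistency band
the tests assert.

## Synthetic data

The generator emulates the statistical structure of crystal-structure
disulfide surveys without downloads. Class tables are wrapped-Gaussian
mixtures in (χ1, χ2) - wrapped Gaussians rather than von Mises because the
two are indistinguishable at the ≤ 30° spreads used: intrachain-Ig-like is a
single component at (180°, 180°) with 25° spread (n = 927); the
interchain-Ig-like (n = 69), TDi-like (n = 40) and DO-like (n = 27) classes
are equal-weight mixtures over open-region centers (±60°/±85°-type gauche
combinations). The class sizes mirror the four crystal-structure data sets
this survey design is modelled on. Cα-Cα distances are the rigid
cystine-fragment geometry at the drawn dihedrals plus 0.15 Å Gaussian noise.
The closed/closed probability of each mixture has a closed form (Gaussian
band masses per axis, summed over ±360° images), against which the empirical
fractions are tested at 3 binomial SD.

Fragment PDB files are written with five-decimal coordinates (centred so
every |coordinate| < 10 Å keeps the 8-column field width) because
three-decimal coordinates limit dihedral round-trips to ≈ 5×10⁻³ °, short of
the 10⁻³ ° recovery the writer guarantees. What the generator does *not*
emulate: real fold context (burial, solvent accessibility), experimental
coordinate error correlated with resolution, class-dependent χ3 coupling, or
non-Gaussian tails. Passing tests therefore demonstrate the pipeline's
correctness and sensitivity, not field-realism of any particular class.

## Problem sizes and determinism

Default study conditions: T = 300 K; 2×10⁶ MC steps per force for DEDS and
cystine and 4×10⁶ for the 9-torsion polypeptide path (a few seconds each
with the numba kernels); quadrature oracle grids of 90-144 points/dihedral.
The acceptance script re-runs these conditions end-to-end from a single
`--seed`. Property tests use shorter chains (5×10⁴-10⁶ steps) with
statistical tolerances stated in units of their own standard errors.

## Known limitations

* No solvent, no bond-length/angle flexibility, no metadynamics: absolute
  free-energy scales and the precise force at which closed/closed takes over
  are model-dependent; the monotone trends, symmetries and limiting states
  are the robust content.
* The quadrature oracle is restricted to ≤ 3 torsions (grid blow-up), so the
  cystine and polypeptide models are validated only through properties and
  cross-model ordering.
* Single-dihedral Metropolis mixes slowly across the high cis barrier of χ3
  at large forces; the shipped step width and chain lengths were sized so
  that batch-means errors remain honest (verified against the oracle).
* PDB format only (no mmCIF in this iteration); cystine protonation/termini
  chemistry is idealized (neutral blocked ends represented only by the
  backbone heavy atoms on the force path).
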