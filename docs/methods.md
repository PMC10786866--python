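# Methods

This note documents the models, conventions, parameter defaults, and design
choices behind each analysis stage, what the synthetic generator does and
does not emulate, and the known limitations.

## Coordinate and symmetry conventions

Structures keep the author's residue numbering (chain, sequence number,
insertion code) with no renumbering, since published discussions of specific
residues use author numbers.  Orthogonalization follows the standard PDB
convention (a along x, b in the xy-plane); fractionalization is the inverse
of that matrix and is cross-checked against gemmi in the test suite.  A
blank alternate-location identifier coexisting with lettered ones in a
residue is treated as common to all conformers (PDB convention).  Space-group
operators are taken from gemmi's tables; a model without a real unit cell is
rejected at read time because every symmetry-aware stage needs one.

Density maps are resampled to a canonical X,Y,Z axis order covering exactly
one unit cell at read time, regardless of the axis permutation and start
offsets the writing program used; grids wrap periodically.  σ-scaling is the
map convention used for 2Fo-Fc maps: `(ρ − mean)/rms` over the grid, which
makes all density comparisons invariant to affine rescalings of the raw map.
Interpolation is trilinear by default (deterministic, exact for per-axis
linear fields); a tricubic spline mode is available by flag.  The default
was chosen for determinism and speed; CC-based comparisons are insensitive
to the kernel at the 10° angular sampling used downstream.

## Volumes

Unit-cell volume uses the general triclinic closed form, which reduces to
`a·b·c` for orthorhombic cells; percent changes are reported to one decimal,
matching how such tables are normally printed.

Protein molecular volume is a probe-excluded grid method defined entirely by
this package (deliberately *not* a re-implementation of any closed-source
volume program): voxels inside any van der Waals sphere, plus voxels that a
probe-dilated flood fill from the bounding-box boundary cannot reach
(interior cavities and inter-atomic interstices smaller than the probe),
times the voxel volume.  Defaults: 0.3 Å grid, 1.4 Å probe (the water-probe
convention), radii C 1.70 / N 1.55 / O 1.52 / S 1.80 / H 1.10 Å with
hydrogens counted only when modeled.  Waters and hetero atoms are excluded
by default (a flag includes waters; published values for the system this
package was built around were reported insensitive to that choice).
Because this is a different algorithm from published per-structure volume
numbers, absolute values are validated by closed-form and convergence
properties (single-sphere volume to 5 %, disjoint additivity to 1 %,
cavity capture against a 0.1 Å brute-force oracle to 3 %, grid convergence
|V(0.4) − V(0.2)|/V < 3 %), while *percent-change arithmetic* on published
volumes is checked exactly.

Welch's t statistic and the Welch–Satterthwaite degrees of freedom are
computed from their explicit formulas, with scipy supplying only the t
distribution; `scipy.stats.ttest_ind(equal_var=False)` serves as an
independent oracle in tests, and a 1000-replicate equal-mean simulation
checks the empirical type-I error rate at α = 0.05.

## Ordered solvent

A water's match distance is the minimum Euclidean distance to any water of
the reference set over all space-group operators and all 27 neighboring
lattice translations (shell 1 is exhaustive because the 2 Å threshold is far
smaller than any cell edge).  A water is unique when that distance exceeds
the threshold for *every* reference structure.  Since condition-matched
crystals are isomorphous but differ by a few percent in cell dimensions, two
frame reconciliations are provided and both should be consulted for real
data: the default identifies the lattices (waters compared as fractional
coordinates re-orthogonalized in each reference's cell), and an alternative
superposes the query onto the reference via shared Cα atoms first.  Waters
with altlocs count as distinct positions.

## Backbone displacement

Superposition is a least-squares rigid fit (Kabsch, SVD) over shared Cα
atoms with the proper-rotation constraint, validated against an independent
quaternion-eigenvalue implementation to 1e-8 Å.  Displacement profiles
default to global superposition over all shared residues — with an option to
exclude ranges (e.g. a deliberately shifted loop) from the fit — and a
crystal-frame mode for strictly isomorphous comparisons; real analyses
should report both when the choice is not obvious.  With alternate
conformations the default policy pairs matching altloc letters and emits one
row per pair, falling back to the highest-occupancy conformer.  RMSF across
a structure set is the per-residue root-mean-square deviation of Cα from the
mean position after superposing everything to the first structure; for a
pair it equals half the pairwise Cα distance, which the tests assert.

## Ringer χ1 sampling

For each residue with a γ heavy atom (branch priority CG > OG/SG >
CG1/OG1), the γ atom is rotated about the Cα→Cβ axis so the N–Cα–Cβ–γ
torsion takes each value in {0°, 10°, …, 350°}, preserving the model's own
Cβ–γ bond length and Cα–Cβ–γ angle (ideal fallback 1.52 Å / 114° when the γ
atom is missing).  The 10° step is the original Ringer convention;
step, interpolation, and scaling are all configurable.  Models are first
collapsed to a single conformer per residue (highest occupancy, or an
explicit altloc letter to analyze each state of a dual loop), with
occupancies reset to 1 and every choice recorded.  Curves are compared by
Pearson CC over the 36 paired samples; flat curves have undefined CC and are
excluded from counts but listed.  The changed-residue threshold CC < 0.5
follows the convention of multi-condition Ringer comparisons; excluded
residue ranges (flexible loops) are removed from the census.  Only χ1 is
sampled.  Peak detection reports circular local maxima above 0.3 σ,
dominant first.

## Rotamers

χ angles use the standard per-type torsion atom quadruples and the IUPAC
sign convention (verified against gemmi's dihedral).  χ1 classes are
p = [0°, 120°), t = [120°, 240°), m = [240°, 360°).  Full names come from
the nearest mode in a shipped nominal-mode table (version `perturbxtal-1`):
idealized staggered modes (p 62°, t 180°, m −65°) for aliphatic χs, crossed
with curated terminal-angle modes for sp2-terminal types (Asp/Asn/Glu/Gln,
aromatics).  Nearest is by summed wrapped angular distance; if the winning
mode still leaves any χ more than 40° away the conformer is an OUTLIER.
This table is compact and fully reproducible rather than a copy of a
statistical rotamer library, so censuses against models refined with other
software may differ by a few residues near bin boundaries — synthetic
ground-truth recovery is exact and is the primary test surface.  The census
counts a residue as changed when no conformer name on one side matches any
on the other (conservative any-match policy); a primary-conformer policy is
available, and residues with multiple distinct rotamers *within* one model
are reported separately.

## Torsion-space embedding

Backbone (φ, ψ) and side-chain (χ1–χ4) torsions are extracted per structure
(highest-occupancy conformer; φ/ψ masked at chain breaks, detected by a
C–N distance over 2 Å).  Torsions missing in any structure are dropped for
all (complete-case mask) — imputation would invent signal.  Each angle
becomes a (sin θ, cos θ) pair, removing the ±180° branch cut; features are
mean-centered and decomposed by SVD.  Component signs are fixed by making
each component's largest-magnitude loading positive, so output is
deterministic and independent of input order.  With n structures at most
n − 1 components are informative.  An optional per-torsion-type weight
vector (default uniform) lets backbone and side-chain contributions be
re-balanced.  This stage is a PCA of circular torsion features intended to
reproduce qualitative ensemble geometry (cluster memberships, perturbation
directions), not the coordinates of any specific published embedding tool.

## Synthetic data

The generator emulates the minimal crystal system the pipeline needs: a
15-residue α-helical peptide (φ = −57°, ψ = −47°) of Ser/Cys/Thr/Val/Leu/Met
built from ideal internal coordinates with assigned χ1 per residue, placed
in a 34 × 38 × 46 Å P2₁2₁2₁ cell with every symmetry contact ≥ 2 Å, plus 20
ordered waters ≥ 2.4 Å from the protein, each other, and all symmetry
images.  Atoms carry a uniform B of 30 Å².  The map model sums, over all
space-group images with periodic wrapping, one isotropic Gaussian per atom
with variance σ² = B/(8π²) + (h/2)² (h = grid spacing; the second term is an
anti-aliasing smoothing) and amplitude proportional to the electron count
(C 6, N 7, O 8, S 16 — no form factors).  Optional seeded white noise is
scaled to a fraction of the noiseless map's rms.  The default grid is 0.3 Å,
which resolves the atomic widths at B = 30 Å².

Perturbations mirror the effect classes seen in temperature/pressure
comparisons: χ1 rotamer flips (side chain rotated rigidly about Cα→Cβ),
rigid loop translations of stated magnitude, water displacements above and
below the 2 Å threshold, B inflation, and dual-conformer loops emitted as
altlocs A/B at stated occupancies.  Every perturbation records ground truth
with per-stage expected-detection flags; sub-rotameric χ1 nudges (< 40°) are
not expected to change a rotamer name or decorrelate a Ringer curve and are
flagged accordingly.  Move directions are retried until symmetry-aware
clearance holds, so a planted move cannot accidentally land beside an image
of another water and confound the uniqueness analysis.  The default seed
20240112 fully determines the output.

What the generator does *not* emulate: diffraction physics (form factors,
Fourier truncation ripple, phase error), refinement artifacts, anisotropic
displacement, realistic solvent networks, or crystal-to-crystal
non-isomorphism.  Passing recovery tests therefore demonstrates the
correctness of the analysis logic — symmetry handling, geometry,
thresholds, bookkeeping — not robustness to real experimental noise, which
is bounded instead by the configurable map-noise level (recovery is exact
across 20 seeds at 0.05 σ noise, and at 0.1 σ in the unit tests).

## Numerical choices and degenerate inputs

Floating output in reports is formatted to 6 significant digits so re-runs
are byte-identical.  Constant (zero-rms) maps make σ-scaling undefined and
are rejected explicitly.  Degenerate cell angles (non-positive-definite
metric) raise rather than returning NaN.  Collinear torsion quadruples
raise.  Welch's test refuses zero-variance groups by name.  Ties in
highest-occupancy conformer selection break toward the alphabetically first
altloc.  Percent changes round half-even to one decimal via Python's
`round`.

## Problem sizes

The test suite and the acceptance script run entirely on the synthetic
system: ~123-atom crystals, ~1.6 M-voxel maps, 20-seed recovery sweeps,
1000-replicate Welch calibration, 300–400 k-point Monte-Carlo volume
oracles.  These sizes were chosen to exercise every code path with
comfortable statistical margins while keeping a full run in tens of
seconds on one CPU.

## Known limitations

- Deposited-model comparisons (water-uniqueness counts, rotamer censuses,
  altloc separations for specific accessions) require the coordinate files
  to be present locally; the package does not download.
- Anisotropic B-factors are treated as isotropic equivalents; hydrogens are
  used only if present.
- Only χ1 is Ringer-sampled; multi-χ sampling is out of scope.
- Structure-factor-to-map synthesis is out of scope: maps are consumed
  precomputed or synthesized by the generator.
- The rotamer mode table is nominal, not statistical; OUTLIER rates on real
  models will exceed those of library-based validators.
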