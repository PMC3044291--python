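# Methods

## Model

A ligand-defined binding site is carved from a protein–ligand complex as
all receptor heavy atoms within a cutoff of the ligand envelope: the union
of spheres of radius 6 Å (default), one per ligand atom, inclusive at the
boundary.  Waters are always excluded; monoatomic metal ions are excluded
by default (`include_metals` re-admits them); other HET groups (cofactors)
count as receptor.  Hydrogens are dropped on parsing — X-ray PDB entries
generally lack them — and donor/acceptor character is encoded on heavy
atoms by the typing table.

Each site atom carries a 7-component property vector: hydrogen-bond donor,
acceptor, lipophilicity, size, electronegativity, charge, and sp2
(aromatic/planar) character.  The shipped table
(`src/apfbss/data/typing_table.tsv`) keys on (residue, atom name) for
backbone atoms and the functional side-chain atoms of the 20 standard amino
acids, with an element-based fallback for everything else (aliphatic C →
lipophilic, O → acceptor, N → donor+acceptor, …).  Size scales with a
van-der-Waals radius class relative to carbon; electronegativity is a
Pauling-like scale offset so carbon is 0; formal charges are spread over
the equivalent atoms of the charged group (e.g. −0.5 per carboxylate
oxygen).  The table is plain text and overridable; the exact magnitudes
are a calibration choice, and only relative magnitudes across components
matter because component weights are separately configurable.

The template site's properties are projected into continuous fields by
isotropic Gaussians, φ_k(x) = Σ_j P_k(j) exp(−|x−r_j|²/w²), with a single
global kernel width w = 1.0 Å by default — comparable to hydrogen-bond
localization and to the grid resolution.  The probe's pseudo-energy is the
negative weighted overlap E_APF = −Σ_k w_k Σ_i P_k(i) φ_k(g·r_i); all
seven component weights default to 1.  Signed components (charge,
electronegativity) can contribute positive terms for mismatched atoms;
they are deliberately not clamped, so unlike-charge overlap is penalized.

## Superposition search

The probe is rigid: six pose variables, a Cartesian offset of the probe
centroid plus three Euler angles (extrinsic x-y-z) about that centroid.
Cartesian translation is used instead of polar coordinates for the centre
position — an equivalent 3-DOF parameterization whose gradients are
simpler and free of the polar singularity.  Euler angles are re-derived
from the rotation matrix after each accepted move to keep them in
[−π, π] and away from accumulating gimbal drift.

The global optimizer is pseudo-Brownian Monte-Carlo: Gaussian increments
on all six variables (σ = 1.0 Å translation, 0.25 rad rotation — about one
grid cell per move), then bounded local minimization (L-BFGS-B with the
analytic gradient, 100 iterations max), then Metropolis acceptance on the
minimized energy.  The effective temperature is expressed directly in
pseudo-energy units as kT_eff = 10 (a physical temperature is meaningless
for a unitless score; reading E_APF as kcal/mol, 10 corresponds to roughly
5000 K).  Every grid energy/gradient evaluation — including those inside
line searches — counts toward the 10,000-evaluation budget; when the
budget runs out mid-minimization the best evaluated point is returned, so
the reported evaluation count never exceeds the budget.  A single MC run
per pair is the default; per-pair seeds make runs reproducible
bit-for-bit.

## Grid numerics

Fields are sampled on a regular lattice (0.5 Å default spacing) covering
the template's bounding box plus a margin of 3 kernel widths, beyond which
the Gaussians are negligible; probe atoms outside the lattice contribute 0
rather than erroring, since MC moves can carry the probe off-grid
transiently.  A node budget (default 4×10⁷) guards against accidental
huge lattices.

Grid evaluation uses separable Catmull-Rom cubic interpolation by default.
Trilinear interpolation (available as `order="linear"`) systematically
undershoots the sharp Gaussian peaks that dominate the overlap sum: its
error is O(h²) with mean sag ≈ (h²/12)·∇²φ, about 10% of the self-energy
at 0.5 Å spacing and w = 1 Å.  Catmull-Rom interpolates the nodes exactly,
reproduces quadratics (error O(h³); measured ≤ 1.5% at 0.5 Å, ≤ 0.1% at
0.25 Å), and is C¹, so the analytic pose gradients are continuous across
cell boundaries.  The pose gradient is exact through the interpolant and
the Euler parameterization (verified against central differences to
≤ 10⁻⁴ relative).

Because even cubic interpolation biases the location of minima by a small
fraction of a cell, the best pose found on the grid is *polished* at the
end of the search: a short L-BFGS descent on the exact Gaussian double sum
(analytic gradient, quadratic cost in atom counts), after which the
reported E_APF is the direct-sum energy at the polished pose.  The polish
is a local refinement outside the 10,000-grid-evaluation budget; it
removes interpolation bias from both the reported energy (identity
self-superposition then agrees with the exact self-energy to ~10⁻⁷
relative) and the recovered transform (self-recovery RMSD drops from
~10⁻² to ~10⁻⁴ Å).  It can be disabled (`final_polish=False`).

## Similarity and clustering

Self-similarities S_APF(A,A) are computed from the exact identity-pose
direct-sum energy — deterministic, no sampling noise — so the
identical-pair distance is exactly zero.  The cross term E(A,B) is the
mean of the two directed MC optima (each site once as template): the
protocol is inherently directional, a distance must be symmetric, and
averaging is the minimal fix.  The tanh normalization uses the published
empirical constants E₀ = −250, Δ₀ = 100, with the argument oriented as
(E₀ − E_APF) so that similar pairs score near +1 and D_APF satisfies its
contract (zero for identical pairs, positive and increasing with
dissimilarity); the opposite orientation is available behind a flag.
Tiny negative distances from tanh saturation plus MC noise are floored at
0 and logged.

UPGMA is implemented in-package because the tree contract requires a
specific deterministic tie-break (lexicographically smallest representative
label pair) and merge heights equal to half the merge distance; it is
cross-checked in the tests against SciPy's average-linkage implementation
(exact agreement on heights and cophenetic structure) and reproduces
ultrametric inputs exactly.

## Synthetic sites

The generator emulates what the method needs from a pocket — a spatially
packed cloud of atoms with heterogeneous pharmacophoric composition — not
protein geometry.  Defaults: 30 heavy atoms, 7 Å bounding radius, ≥ 1.5 Å
pairwise separation (protein-like heavy-atom packing), property vectors
drawn from five archetypes (donor-rich, acceptor-rich, lipophilic,
charged, aromatic) mirroring the typing table, with ±10% per-atom scale
variation.  `jitter` is calibrated so the rms atom displacement magnitude
equals the stated value (per-coordinate σ = jitter/√3).  Perturbed copies
carry their exact ground-truth rigid transform.  Fixture files embed a
dummy HET group placed to cover the site within the carve radius, so the
ligand-selection and carving path is exercised unchanged.

What synthetic sites do *not* model: backbone connectivity and secondary
structure, realistic residue composition statistics, correlated side-chain
placement, alternative conformers, or crystallographic noise.  Passing the
recovery and clustering tests therefore demonstrates the correctness and
calibration of the machinery (carving, fields, search, scoring,
clustering), not performance on the real pocketome; real-structure
validation requires downloading PDB complexes and running the same CLI on
them.  One consequence of desk-scale sites: with ~30 atoms the self-energy
(≈ −70) sits in the saturated tail of the tanh at E₀ = −250, so D_APF
values are compressed (order 10⁻²–10⁻¹) relative to what full-size pockets
produce; orderings and cluster structure are unaffected.

## Problem sizes and tolerances

The shipped checks use sizes chosen to exercise the full default protocol
(10,000 evaluations, 0.5 Å grids) while keeping a laptop-scale footprint:
20 seeds for recovery tests, 5-member families (10 sites, 45 pairs, 2
directed runs each) for cluster recovery, 50 random 6×6 matrices for the
UPGMA oracle, 10⁵ trials for Metropolis calibration.  The reproduction
script (`scripts/acceptance.py`) uses 10 recovery seeds and 4-member
families so a complete from-scratch rerun stays under ten minutes.  Numerical
tolerances: grid/direct agreement 5% at 0.5 Å (halving required at
0.25 Å), gradient check 10⁻⁴ relative at step 10⁻⁶, pose round-trips and
rotation orthonormality 10⁻⁹, UPGMA oracle agreement 10⁻⁹.  Degenerate
inputs are errors, not silent defaults: empty sites, empty carves,
duplicate labels, sub-cycle evaluation budgets, non-positive widths or
spacings all raise with a message naming the remedy.

## Known limitations

- Rigid-body superposition only; no side-chain or torsional flexibility.
- A single global kernel width for all seven components.
- Ligand selection needs a bound ligand; apo pockets are out of scope.
- The cross-energy symmetrization (mean of two directed optima) is a
  pragmatic choice; directed energies typically agree to well under 10%,
  but the mean is not itself the optimum of any single superposition.
- E₀ and Δ₀ are taken as published constants; they were fitted to a large
  curated site collection and are not re-derived here.
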