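# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, and what the synthetic fixtures do and do not
establish.

## The two-bead representation

Each residue carries a Cα bead (radius 1.8 Å, centred on the Cα atom)
and, for every residue but glycine, a Cβ bead centred on the centroid of
the side-chain atoms *including* Cα, with a residue-dependent radius.
Derived geometry: θᵢ is the Cα(i−1)–Cα(i)–Cβ(i) bend angle (defined for
i ≥ 2, non-glycine), φᵢ the backbone torsion over Cα(i−1..i+2) (defined
for 2 ≤ i ≤ N−2, 1-based). Ingestion reads single-model PDB files
(first chain unless named, altloc 'A'), maps common nonstandard
residues to parents, errors on a missing Cα and records chain breaks
(Cα–Cα > 4.5 Å) as provenance warnings. A tabular TSV round-trip format
(index, residue, Cα xyz, Cβ xyz, radius) is lossless.

### Residue parameter table

`data/residue_params.tsv` is versioned and overridable by path:

- **b, r, θ₀** — curated template-scale values (bond length to the
  side-chain centroid, radius of gyration of the side chain about that
  centroid with proportionality constant 1.0, near-tetrahedral
  equilibrium bend of 2.10 rad, 1.95 for proline). No primary source
  prints these; they are package constants.
- **h** — Kyte–Doolittle hydropathy shifted +4.5 so all values are
  non-negative; h doubles as the like-pair LJ well depth εᵢᵢ, with
  εᵢⱼ = √(εᵢᵢεⱼⱼ) for unlike pairs and a single backbone ε = 1.0 for Cα
  beads. The polarity index is derived, not stored:
  p = (h_max − h_min) − h. A side effect of the non-negative shift is
  that arginine (h = 0) has a vanishing LJ well depth; its packing is
  then felt only through the beads it collides with.
- **helix_k** — the Pace–Scholtz helix propensity scale affinely
  *inverted* (K = 3.26 − P) so that strong helix formers are stiffest
  toward helical geometry; this is the physically sensible orientation
  for a force constant.
- **beta_k** — a beta-propensity ranking (Kim–Berg-style ordering)
  affinely mapped onto the same numeric range [0.10, 3.26]. The exact
  published Kim–Berg numbers are not available offline; only the
  ordering is encoded, and the map is documented in the file header.
- **q** — formal charges: D,E = −1; K,R = +1; histidine neutral.

### Solvent exposure

Per-residue exposure uses a neighbour-vector approximation: unit
vectors from the residue's interaction centre (Cβ; Cα for glycine) to
every other residue's centre within 10 Å, weighted 1 inside 3.3 Å and
ramping linearly to 0 at the cutoff. The normalised resultant magnitude
NV ∈ [0,1] is the exposure signal — isotropic surroundings cancel,
one-sided surroundings do not. A plain resultant cannot distinguish
"surrounded" from "two opposite neighbours": an extended chain would
read as buried. The burial implied by a small resultant is therefore
damped by neighbour density, exposure = 1 − (1 − NV)·min(1, W/W_ref),
with W the neighbour weight sum and W_ref = 6.0 the typical interior
weight sum of a compact domain at this bead density (~190 Å³/residue).
All constants live in `PhysicsConstants` and are overridable. This
measure is a declared approximation: it is deterministic, rigid-motion
invariant and monotone under one-sided crowding, but it is not a true
solvent-accessible area; values near the burial threshold (0.25) should
not be over-interpreted.

## Physics-based scoring

Folding is the weighted seven-term sum V(s,c) (bend, LJ, helix, beta,
ion, solv, SS), binding the three-term inter-molecular sum
w'_LJ·V'_LJ + w'_ion·V'_ion − w_Δsolv·V_Δsolv, both lower-is-better.
Implementation choices:

- The bend term is the printed pair of half-K sums, so interior angles
  count twice, the second occurrence against the *preceding* residue's
  equilibrium; terms whose angle is undefined (glycine, chain ends)
  are skipped.
- LJ runs over all bead pairs except same-residue pairs and bonded
  Cα–Cα neighbours (unspecified in any source; excluding them removes
  constant bonded-term noise). σᵢⱼ is the sum of the bead radii.
- The beta term works in degrees (the equilibrium is printed as 210°)
  with differences wrapped to (−180°, 180°]; the bend term works in
  radians.
- The ionic term uses centre-to-centre Cβ distances and gates on both
  members being buried (< 0.25 exposure); in binding, burial is judged
  in the complex frame.
- Every folding term evaluates a `Measurements` bundle — flat arrays of
  angles, torsions, helix 1–3/1–4 distances, bead-pair distances,
  exposures, cysteine distances. Native structures and decoys share one
  code path.

## Specificity and decoys

Z_fold = (⟨G⟩ − G_nat)/σ(G) with median location and
(median − first quartile) dispersal, quartiles by linear interpolation
(type 7) — the Z values depend on that convention. Robust estimators
are used everywhere because threaded random sequences and shuffled
geometries produce long right tails of steric-clash scores; only the
low-score flank matters for fold stability.

Random-energy-model decoys:

- **Geometry decoys** (physics) permute each measurement class of the
  native bundle independently: θ, φ, r₁₃, r₁₄, LJ pair distances,
  charged-pair distances, per-residue exposure, cysteine distances.
  Exposures are permuted, not recomputed — a shuffled-measurement decoy
  has no coordinates. A decoy stores a seed, not permutations, and
  regenerates them per class length, so one fixed decoy set can score
  sequences whose glycine content changes the bead count.
- **Contact decoys** (informational) redraw the native number of
  contacts uniformly among pairs with sequence separation > 4.
- **Random sequences** are i.i.d. uniform over the 20 letters and are
  threaded before scoring.

During sampling and evolution the dispersal is frozen at its starting
value, so S_gap ∝ Z_fold and only G_nat and the decoy medians move.
For the informational model the native conformation's contact map is
reused for every candidate sequence by default (E(s,c) depends on c
only through its map); a `rethread` switch rebuilds the map from a
fresh threading when the small Cβ shifts matter.

## Threading

Sequences are placed on a fixed backbone by setting each Cβ at its
tabulated bond length and equilibrium bend angle, leaving the azimuth
about the local backbone axis as the single refined degree of freedom.
Initial azimuths point away from the local chain axis (the centroid of
a ±4-residue backbone window); refinement is Metropolis MCMC on the
placed beads' pairwise LJ energy (Gaussian azimuth proposals, σ = 0.3
rad, T = 0.1 LJ units, 50 sweeps by default), tracking the best state
seen, followed by a deterministic greedy sweep over a 60-point azimuth
grid that escapes local minima the walk can get stuck in. Backbones are
never adjusted; results are bitwise reproducible per seed. Defaults
thread a 100-residue chain in well under a second; tests use reduced
settings (5 sweeps, 24-point grid).

## Weight parameterisation

Weights live in the open box (0,1)⁷ (folding) or (0,1)³ (binding). The
reference set is cached as raw per-term scores — native + 1000 geometry
decoys + 1000 threaded random sequences (defaults) — so evaluating Z
for a candidate weight vector is one matrix-vector product. Before
optimisation each term column is affinely mapped onto [0,1] over all
states including the native row ("equal range" across terms);
zero-range columns are left untouched with a warning. The chain accepts
uphill moves always and downhill moves with probability exp(ΔZ/T),
T = 0.1, 100 000 attempted moves by default; proposals perturb every
coordinate with Gaussian(mean 0.1, variance 0.1) — a *biased* random
walk, reproduced as printed, with a mean-zero switch — and proposals
leaving the box are rejected outright (reflection would bias the
boundary given the positive proposal mean). The largest-Z state seen is
returned. One known consequence of the biased proposals: weights that
do not affect Z (e.g. a zero-range term) drift upward rather than
staying put.

## Sequence sampling and landscape tools

Metropolis chains over single-residue substitutions accept on S_gap
with the same exponential rule. Default temperatures: informational
10 (high) / 0.1 (low), physics 50 / 1.5; a bisection harness transfers
temperatures between scorers by matching acceptance frequencies.
Divergence from the fixed start sequence can be capped as a fraction of
differing positions; the proposal kernel is uniform position × uniform
different letter (not specified anywhere; declared here). Stable optima
are collected by pooling replicate low-temperature chains thinned to
every 4th unique sample, final 100 kept per chain. Sammon projection
minimises the standard stress by L-BFGS from a seeded random start
(duplicates share coordinates); information content is
log₂20 − Shannon entropy per column, no small-sample correction by
default.

## Evolution

Haploid Wright–Fisher populations of protein-coding genes: per-base
mutation with P(transition) = R/(R+1) for ratio R = 2, translation by
the standard code, fitness by the three-level truncation rule frozen
against the starting sequence, resampling proportional to fitness at
constant size. Premature stops are lethal (a truncated protein cannot
meet the fold threshold). Scores are cached per protein sequence, so
synonymous genotypes never rescore; checkpoints carry the population
and RNG state and restarts are bitwise. The printed decoy-ligand
sequences (informational IWMTIYMIIIT, physics RLPTIYICITG) are threaded
through the native ligand conformation; both are 11-mers, so fixtures
use an 11-residue peptide ligand, and any other length requires an
explicit decoy sequence. Defaults follow the full-scale protocol
(N = 1000, 200 000 generations, μ = 10⁻⁵/bp); tests and the acceptance
script run the reduced scale (N = 100, ≤ 2000 generations, μ = 10⁻⁴)
with the physics scorer.

Simulations start from a sampled S_gap optimum (a low-temperature chain
from the designed sequence), not from the designed sequence itself —
otherwise early adaptive substitutions dominate the divergence and
contaminate dN/dS with positive selection.

## Analyses

- **Site classes**: binding = any inter-molecular Cβ contact < 4.5 Å;
  core = non-binding with exposure < 0.25 (computed on the unbound
  protein); surface = rest. Binding overrides burial.
- **dN/dS (PBL)**: sites classed by degeneracy with counts averaged
  over the two sequences; per-codon differences averaged over all
  minimal substitution pathways (stop-crossing pathways excluded when
  avoidable), each step contributing half to the site class of its
  source and half to its target codon — this makes the estimator
  exactly symmetric. Per-class K2P correction, with the transition (A)
  and transversion (B) components allowed to saturate independently;
  dS = (L₂A₂ + L₄A₄)/(L₂+L₄) + B₄, dN = A₀ + (L₀B₀ + L₂B₂)/(L₀+L₂).
  An undefined or zero dS reports the ratio as undefined, never
  infinity.
- **Hydrophobicity partition** uses the positive-hydropathy set
  {A,V,L,I,M,F,W,C}, overridable, since published tables never
  enumerate one.
- **Rate heterogeneity** compares, on per-site substitution counts
  across replicate lineages, (a) one-rate Poisson, (b) a 4-category
  discrete-gamma Poisson mixture (category rates are the means of
  equal-probability gamma slices, unit mean), and (c) one rate plus an
  invariant class, by maximum likelihood with AIC weights (AICc/BIC
  selectable). Counts rather than a phylogenetic likelihood: the
  replicate design is star-shaped, so there is no tree to integrate
  over. An all-identical alignment reports equal-rates support 1 by
  convention.

## Synthetic fixtures: what a green test establishes

Fixtures replace downloaded structures entirely: ideal helix (1–3
spacing solved to 5.5 Å), ideal sheet (constant 210° torsion), random
coil, a compact two-domain fold (two touching confined self-avoiding
walks at ~190 Å³/residue, hydrophobic letters designed into the
occluded positions, small-side-chain hydrophobic cycle so a single
azimuthal degree of freedom can always relax the packing), and a
helix+peptide toy complex. The fold generator rejection-samples
deterministically over sub-seeds until the conformation threads without
steric strain (net-attractive LJ), has a non-trivial contact map and
some genuinely buried residues; a peptide can be docked against any
fold surface by a deterministic principal-axis scan. All-atom emission
writes minimal PDB files (CA plus two pseudo side-chain atoms whose
centroid with CA reproduces the Cβ centre) that round-trip through
coarse-graining.

These fixtures exercise every code path and the full workflow, but they
are 20–40 residue toys with designed sequences: green tests establish
the correctness of the formulas, estimators and samplers, and the
*direction* of the evolutionary signatures (Z > 0 for designed folds,
dN/dS < 1 under truncation selection, core no faster than surface) —
not the magnitudes reported for real proteins, which depend on real
structures (e.g. the SH2-domain complex) and full-scale simulation.

## Numerical notes and limitations

- Angle wrap-around is centralised; torsions live in (−π, π], beta
  differences in (−180°, 180°].
- LJ raises on exactly coincident beads rather than returning inf.
- Geometry decoys can pair a short distance with a large σ, producing
  huge clash scores; this is intended (it is why the robust estimators
  exist) but means means/variances of decoy scores are meaningless.
- The contact matrix shipped is a synthetic hydrophobic-attraction
  stand-in, not a published statistical potential; any 20×20 symmetric
  matrix file can be swapped in.
- No rotamer libraries, hydrogen bonding, multi-chain assemblies beyond
  two-body complexes, recombination, or demography.
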