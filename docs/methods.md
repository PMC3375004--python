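# Methods

`micromr` is a compact, fully testable implementation of template-based
crystallographic structure determination: prepare a search model from a
homolog and an alignment, place it against observed amplitudes, improve the
phases by density modification, and rebuild the model against the resulting
map under a joint geometry/density score until the R value converges.  This
note records the models, conventions, defaults and deliberate simplifications.

## Coordinate model and conventions

Coordinates are orthogonal Å; crystallographic symmetry acts in fractional
coordinates through the cell orthogonalization matrix (PDB convention).
Built-in space groups are P1, P2₁ and P2₁2₁2₁ (operator lists taken from
gemmi's tables; identity and closure are asserted in tests); other groups
can be supplied as explicit operator lists.  PDB I/O goes through gemmi;
alternate locations collapse to the highest-occupancy conformer (ties by
altloc letter), insertion codes are rejected.  Superposition is Kabsch
least squares over atoms paired by (chain, residue number, atom name);
degenerate (collinear) point sets are rejected.

## Structure factors, scaling and maps

Two independent routes compute F(h) = Σ_sym Σ_atoms f_elem(s) · occ ·
exp(−B s²/4) · exp(2πi h·(Rx+t)), with s = 1/d and four-Gaussian IT92 form
factors for C, N, O and S:

* **direct summation** — exact within float tolerance, used as the oracle;
* **FFT sampling** — Gaussian atomic density sampled on a grid of spacing
  d_min/3 per axis, Fourier transformed, and unblurred in reciprocal space.
  Sampling adds an artificial B of up to ~80 Å² (removed exactly after the
  FFT) so that the sharpest density component is wide on the grid; atoms are
  rasterized to 1e-8 relative density.  On the standard fixture the two
  routes agree to amplitude R ~ 1e-7.

Overall scaling fits k and B minimizing Σ(|F_obs| − k e^{−Bs²/4}|F_calc|)²
on the work set (scalar B optimized by bounded search, k closed-form); R is
reported separately on work and free sets.  Free flags are a seeded random
5% subset.  Maps are plain Fourier syntheses (Fc, Fo or 2Fo−Fc with
calculated phases; no sigma-A weighting — a deliberate fidelity limit, since
the likelihood-weighted map coefficients of production programs are out of
scope here).  Maps are mean-zero by construction (F(000) excluded) and the
map/model fit score is the occupancy-weighted trilinear map value per
residue on a standardized map.

## Template preparation

Alignments are paired FASTA (target first, `-` gaps); template columns are
counted in ungapped template positions in file order.  Editing keeps aligned
residues, renames and renumbers them to the target, and prunes side chains
to the atoms shared by the two residue types' topologies (main chain always
kept, CB kept unless the target is glycine); the shared-atom rule is the
"mixed" editing convention and is checked exhaustively against the packaged
topology table for all 400 residue-type pairs.  Unaligned target positions
are recorded as gaps for loop building.  Copy-number hypotheses come from
the Matthews relation (1.23 Da/Å³; solvent fraction within [0.20, 0.80],
ordered by closeness to 0.50) using the full sequence mass; when the
hypothesized copy number is a multiple of the template's own assembly size,
the multimer is offered as a search model alongside the monomer.

## Molecular replacement

The search target is the Pearson correlation between F_obs² and |F_calc|²
of the (fixed + shifted search) model — the classical correlation
translation function; a likelihood target is deliberately not implemented.
Orientations are scanned on a uniform zyz Euler grid (default 15°, polar
redundancy removed; tests and the pipeline default to 30° as their
problem-size choice), translations on a fractional grid (default 1/8,
guarded at 64³ points).  Copies are placed sequentially, each joining the
fixed set.  In polar directions amplitudes are invariant under origin
shifts — in P1 with nothing fixed the translation function is constant —
so ranking breaks score ties (to 1e-9) lexicographically toward the
smallest offset; test fixtures therefore place the true pose at the origin,
which in P1 is a free choice of origin, not a constraint.  Candidate
solutions from different search models and hypotheses are re-ranked under
one common criterion: the same squared-amplitude correlation after a shared
B-factor inflation (default 20 Å², the stand-in for a fixed assumed
template-error level; with zero inflation the rescored value reproduces the
search score).

## Density modification

Classical solvent flattening with phase recombination: the solvent region
starts as all grid points farther than 4 Å from a model atom and is trimmed
or grown by density-value ranking to exactly the requested solvent
fraction; flattening sets it to its mean; if NCS operators are present the
density in a 5 Å-sphere union around one copy is averaged over all copies
(cubic-spline interpolation; identity operators are no-ops) and written
back to every copy's region.  New phases are those of w·F_mod + (1−w)·F_start
with w = 0.5; amplitudes are always reset to |F_obs|, so work and free
reflections are treated identically (phase-only modification).  Five cycles
by default; an oscillating solvent mask stops the loop early.  NCS
operators are detected from chain pairs agreeing at ≥ 90% of shared residue
numbers whose CA superposition rmsd is ≤ 2 Å.  Multi-model maps are
averaged pointwise after standardization, unweighted.

## Rebuilding

The rebuilder trades a physical-plausibility surrogate against density fit:

    score = w_dens · density − w_geom · (bond_dev + angle_dev/50 + clash
                                         + 2·rama_outliers)

with bond/angle rms deviations from ideal values, a count of non-bonded
contacts under 2.4 Å (pairs within the same or adjacent residues excluded),
and the fraction of residues outside broad allowed (φ, ψ) regions.  This
surrogate replaces a full molecular-mechanics force field; it preserves the
geometry-vs-density trade-off the pipeline exercises but has no
electrostatics, solvation or hydrogen bonding, which is the main fidelity
limit of the package.  Both weights default to 1.0: at that balance the
ideal-geometry true model outscores distorted high-density conformations
(at w_dens = 2 the score can reward collapsing atoms onto density maxima).
Inside the Monte-Carlo rebuilder the density term is averaged over the
*target* length, counting unbuilt residues as zero, so that building a
well-fitting loop raises the score; the reported score uses the plain
per-residue mean.

Fragment proposals replace the φ/ψ/ω torsions of a 3- or 9-residue window
with an entry from a deterministic synthetic torsion library (canonical
helix/strand/polyproline-II/turn values plus seeded jitter, ~140 entries of
both lengths) and rebuild the window with ideal geometry by NeRF chain
extension.  Internal windows are closed onto the downstream anchor by cyclic
coordinate descent over the window torsions (closure rmsd ≤ 0.5 Å required);
windows at segment C-termini are free ends.  Each window needs an upstream
anchor residue, so the first residue of a segment is only ever moved by
refinement; N-terminal extensions are likewise not proposed (a known
limitation).  Gaps of up to 8 residues get loop proposals built and closed
the same way, with residue types from the target sequence.  Acceptance is
Metropolis at temperature 0.05 score units; trajectories are seeded
(seed + trajectory index) and bitwise reproducible.  Defaults are 20
trajectories of 300 steps — a deliberate scale-down from the thousands of
candidate models a production run would build; the pipeline defaults scale
further to 6 × 150 as its own end-to-end problem size, and tests state
their sizes explicitly.

With multiple NCS copies, one reference copy is rebuilt and the best result
is replicated through the operators, giving exact ("idealized") NCS.

## Real-space refinement

Refinement is residual-based least squares: each round computes the
band-limited model density on the map grid (same Gaussian model as the
structure-factor route, restricted to the map's own frequency support),
forms the least-squares residual map R = map − k·ρ_model, and moves all
atoms by L-BFGS-B (max 0.5 Å per atom per round) on a smooth objective
combining the profile-blurred residual field with harmonic bond/angle and
soft-clash restraints; the residual is then recomputed.  Because R vanishes
identically when the map is the model's own synthesis, such a model is an
exact fixed point — naive peak-pulling (interpolating the raw map at atom
centers) is biased by ~0.2 Å at 2.5 Å resolution by series termination and
was rejected for that reason.  Rounds stop when the residual sum of squares
stops shrinking; the returned model is the best-residual snapshot and never
scores below the input under the combined score.

## Autobuild loop and pipeline

One autobuild cycle: structure factors → k/B scaling and R → 2Fo−Fc map →
density modification → Monte-Carlo rebuilding restricted to windows
covering the worst-fitting 20% of residues → real-space refinement →
pruning of residues fitting worse than (mean − 2 sd).  The loop stops when
|ΔR_work| < 0.005, after three consecutive R increases, or at the cycle cap,
and returns the lowest-R_work model with its density-modified map.  The
entry state is itself a candidate in that selection, so autobuilding can
never lose an already-good model; this also makes a true-model start a
one-cycle fixed point.

The pipeline chains the six stages — template editing; optional
geometry-only pre-refinement (density weight zero against an uninformative
map, emulating structure idealization without crystallographic data; on the
ideal-geometry synthetic templates this stage is close to a no-op and the
package demonstrates only that such templates score no worse afterwards);
molecular replacement over the hypothesis list with common-criterion
rescoring and a fixed-model retry when fewer copies than hypothesized are
placed; then refinement/density modification, rebuilding with map averaging
over the four best candidates, and autobuilding — iterating the last three
stages up to three times until R_work stops changing.  Candidates surviving
to autobuilding default to the top 2.  All randomness derives from the one
config seed through fixed per-stage offsets; identical config and seed give
bitwise-identical histories.  Chains that cannot be assigned to the target
sequence (all-UNK) are discarded before rebuilding.

## Synthetic fixtures: what they do and do not show

`synthetic` builds ideal-geometry helical and helix-turn-helix chains
(turn torsions chosen, per seed, as the most compact clash-free variant of
~300 candidates), places them in a cell padded 3 Å beyond the bounding box
(scaled by copy and symmetry count; the resulting solvent fractions of
~0.6 sit inside the Matthews window used for copy-number enumeration),
simulates amplitudes as |F_calc|·(1+ε) with ε ~ N(0, noise) and 5% free
flags, perturbs templates by low-frequency torsion modulation rescaled to a
target main-chain rmsd (±10%), and derives homolog sequences by exact
substitution counts plus 0–2 short deletions.  The standard fixture —
30-residue helix-turn-helix, P1, one copy, d_min 2.5 Å, 5% amplitude noise,
1.5 Å perturbation, 30% identity — builds in seconds and drives the
end-to-end tests; its parameters sit in the resolution/identity regime
where template-based phasing is genuinely marginal.

What passing tests show: the pipeline's information flow is correct — exact
inputs are fixed points, known poses are recovered, phase improvement and
density-guided rebuilding move models toward the truth under controlled
perturbations.  What they do not show: performance on real data.  The toy
crystals have no side chains beyond CB, no bulk solvent, no measurement
model beyond relative Gaussian noise, no anisotropy or twinning, perfect
isotropic B factors and tiny unit cells; scores, radii and convergence
thresholds would all need revisiting at realistic scale.

## Key defaults

| parameter | value | where |
|---|---|---|
| map grid spacing | d_min/3 per axis | structure factors, maps |
| free-reflection fraction | 0.05 | `assign_free_flags` |
| rotation / translation grid | 15° (tests: 30°) / 1/8 | MR search |
| rescoring B inflation | 20 Å² | `rescore_solutions` |
| solvent mask radius / recombination weight | 4 Å / 0.5 | density modification |
| NCS region radius / max operator rmsd | 5 Å / 2 Å | NCS averaging |
| MC trajectories × steps | 20 × 300 (pipeline: 6 × 150) | rebuilder |
| MC temperature / max loop length | 0.05 / 8 residues | rebuilder |
| clash distance / closure rmsd | 2.4 Å / 0.5 Å | geometry, CCD |
| R convergence tolerance | 0.005 | autobuild, outer loop |
| autobuild / outer cycle caps | 4–5 / 3 | pipeline |
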