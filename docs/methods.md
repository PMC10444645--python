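# Methods

`clashfix` implements three connected pieces: a piecewise-Gaussian van der
Waals (vdW) repulsion pair term, a proxy-reference-datum scheme for fitting
its parameters with clash-driven iterative reweighting, and the
Molprobity-style geometry-validation protocol used to judge the outcome.
Because the term is meant to correct a *deficiency* of an energy model, the
package also ships a deliberately deficient surrogate energy model and
synthetic structure generators, so the pathology and its cure can be
reproduced end to end on a desktop in minutes.

## The repulsion pair term

For one unordered element pair with parameters `a` (amplitude, kcal/mol),
`b` (width, 1/A^2) and `c` (switch distance, A):

    E(r) = a * exp(-b * (c - r)^2)   for r > c
    E(r) = a                         for r <= c

The term is continuous and once-differentiable at `r = c`, non-negative,
and monotone non-increasing in `r`, so its force (−dE/dr) is everywhere
repulsive and vanishes identically inside the plateau. With `b` of order
1 /A^2 it is numerically zero a few Angstroms past `c`; the default
evaluation cutoff of 12 A truncates nothing of consequence. The energy is
summed over non-bonded atom pairs, excluding 1-2 and 1-3 neighbors (1-4
pairs are included; near-bonded geometry is the bonded terms' business,
but 1-4 distances are genuinely non-bonded degrees of freedom). The term
is realized as an additive pair energy rather than inside any
quantum-chemical core-core scaling product; only the shape of the
resulting force matters for the clash mechanism, and the precise
functional embedding is immaterial at the force scales involved.

Two properties of the plateau deserve emphasis because they drive every
design decision downstream:

* the term repels *approaching* pairs — it has zero force inside `c`, so
  it can prevent a pair from entering the clash zone but cannot expel a
  pair that already sits there;
* at contact it raises the energy by `a` without any force, so binding
  energetics of genuinely bound pairs (hydrogen bonds sit well inside
  `c`) are shifted but not distorted.

## The surrogate energy model

The baseline model (`surrogate.SurrogateModel`) is a minimal
molecular-mechanics caricature: harmonic bonds and 1-3 angles (reference
values captured from a structure's own idealized geometry), Gaussian
attraction wells between configured element pairs, and a soft-core
`s / r^4` short-range term. Torsions are deliberately unrestrained — the
softest degrees of freedom of real chains — so non-bonded forces decide
side-chain and backbone rotations, exactly where clashes form and resolve.

Attraction wells model *inter-fragment* non-covalent stabilization: they
act only between atoms of different residues and beyond 1-4 bond
separation, the same convention dispersion/H-bond corrections use. The
pathological configuration used throughout the tests
(`synthdata.pathological_model`) has a single O···H well of depth
1.2 kcal/mol at an optimum of 2.0 A (width 2.0 /A^2). That optimum lies
0.57 A inside the O/H vdW contact distance (1.40 + 1.17 A), i.e. beyond
the 0.4 A clash threshold, so a model with this well *and no long-range
repulsion* pulls hydrogens onto carbonyl oxygens during optimization and
drags neighboring pairs into clashes. This reproduces, in miniature, the
failure mode of semiempirical methods whose stabilizing non-covalent
terms are not balanced by any vdW repulsion.

The geometry optimizer is a limited-memory BFGS (history 10) with Armijo
backtracking (factor 0.5, parameter 1e-4), a per-atom step cap
(default 0.1-0.2 A, which also keeps steps from tunneling through the
thin repulsion barrier), curvature-filtered updates, and a reset to
steepest descent when a line search fails with stale curvature. The
stopping rule is stall-based: iteration ends when the best energy has not
improved by more than the tolerance over a 60-cycle window. Trajectories
of accepted steps are monotone non-increasing by construction and
bit-for-bit reproducible for identical inputs.

## Proxy reference data and weights

A single diatomic repulsion cannot be isolated from ordinary experimental
data, so each parameterized pair gets a *proxy*: two rigid small molecules
placed twice — once far apart (50 A) and once with one designated atom of
each molecule at the pair's vdW contact distance, oriented so the
designated pair is strictly the nearest cross-molecule contact (audited:
every other cross pair must be at least 0.5 A further; violations raise
an error naming the offending pair). The energy difference
`E(contact) − E(separated)` then reads out essentially one pair term.

The rigid library (H2, N2, HNC, CO2, NH3, H2O, H2S; standard experimental
bond lengths and angles) covers the six canonical clash pairs
(H-H, C-H, C-O, O-H, N-O, S-O) plus five extensions (N-H, C-C, C-N, O-O,
N-N) needed to cover every contact type the toy chains produce. N2 serves
as the axial nitrogen contact: ammonia's hydrogen umbrella spreads
laterally enough to violate the 0.5 A nearest-pair margin at the N···C
contact distance.

Weights make residuals dimensionless and encode priorities:
heats of formation 1, hydrogen bonds 10, interaction energies 10, clash
proxies 30 initially, raised as needed to at most 100 /(kcal/mol). The
training builder (`synthdata.make_training_set`) assembles clash proxies
with a +2.5 kcal/mol contact target alongside hydrogen-bond-like anchor
data (attractive O···H placements referenced to the repulsion-free model,
which punish repulsion leakage into binding energetics) and weakly
weighted far anchors in the 3.3-4.5 A decay region whose only role is to
pin the switch distance and width — one proxy per pair leaves (b, c)
underdetermined, and in a full parameterization that ambiguity is resolved
by the bulk of conventional data; the far anchors play that part here.
The contact target of 2.5 kcal/mol sits at the scale conventionally used
for repulsive reference points (a couple of kcal/mol above the separated
monomers); the fitted amplitude lands near `target + well depth at
contact` because the proxy difference includes the surrogate's own
attraction.

## Fitting and the clash-driven reweighting loop

The objective is a weighted sum of squares,
`sum_d (w_d (pred_d − ref_d))^2`, minimized simultaneously over all
(a, b, c) triples with a bounded derivative-free Powell search. Because
payload geometries never move during a fit, predictions decompose into a
repulsion-free baseline plus pair-term sums over fixed distances; these
are precomputed once (`paramfit._FeatureTable`), making objective
evaluations vectorized and cheap. Default bounds keep `a >= 0`, `b` and
`c` positive; the toy-chain studies use `b` in [0.5, 2.0] and `c` in
[1.5, 4.2] so the term keeps a vdW-scale onset.

The reweighting loop alternates: fit parameters → optimize every test
structure under the fitted model → detect clashes → raise (x1.5, capped
at 100) the weights of the clash-proxy data matching the worst distinct
clashing element pairs (5 per cycle) → repeat, warm-starting each refit
from the previous estimate. It stops when the average clashscore reaches
the target (default 5, the order of a well-validated structure), when the
cycle budget is exhausted, or when every matched proxy weight is already
at the ceiling (no lever left). Clash pair types with no matching proxy
datum are recorded as uncovered and the loop continues. Weights never
decrease and never exceed the ceiling.

On the frozen study conditions (two 6-residue chains, perturbation
sigma 0.03 A, seeds 0-1), optimization without the repulsion term yields
average clashscores near 170; the loop's first fit (weights 30) cures
only part of the pathology, and the weight escalation drives the fitted
amplitudes up until re-optimized chains score in the 10-35 range — a
reduction of 5-20x across seeds, qualitatively matching the published
behavior of the corrected method (clashscores dropping to a small
fraction of their uncorrected values).

## Validation protocol

* **Clashes** — candidate pairs are non-bonded pairs excluding 1-2/1-3
  neighbors and, by default, donor-H/acceptor pairs satisfying a
  hydrogen-bond criterion (H bonded to N/O/S; H···acceptor <= 2.5 A;
  donor-H···acceptor angle >= 120 degrees). A pair clashes iff the sum of
  its vdW radii exceeds its distance by at least 0.4 A (closed bound).
  The clashscore is clashes per 1000 atoms, hydrogens included. Radii
  follow the small-probe contact lineage (C 1.75, N 1.55, O 1.40, S 1.80,
  H 1.17, polar H 1.00 A).
* **Backbone RMSD** — matched N/CA/C atoms (by chain, residue number,
  insertion code, name; waters excluded) after optimal proper-rotation
  superposition (Kabsch via SVD with determinant correction).
* **Volume** — grid occupancy of the union of probe-augmented vdW spheres
  (probe 1.4 A, default spacing 0.3 A). This is a plain
  solvent-accessible-surface volume; absolute values are not comparable
  to any specific solvation model's cavity volume, so only relative
  changes are meaningful.
* **H-bond survey** — every O-bound H to acceptor-O distance in
  [1.5, 2.5] A, binned at 0.1 A, plus a flag for acceptors receiving both
  hydrogens of one water (an oxygen bearing exactly two hydrogens).
* **Geometry outliers** — residue-internal bonds/angles compared against
  an idealized reference dictionary (backbone/alanine fragment values,
  plus the His ND1-CE1 and Arg NE-CZ bonds; tolerances 0.025 A and
  4 degrees).
* **Survey statistics** — plain mean, count-weighted mean
  (`sum n_i v_i / sum n_i`) and excess kurtosis (`m4/m2^2 − 3`) over
  labeled tables. Transcriptions of the published 21-protein survey
  (clashscores, backbone RMSDs, volumes) and the interaction-energy
  benchmark summary ship as package data; the published summary rows are
  *recomputed* from the per-protein/per-set rows, never stored.

## Synthetic structures

`make_toy_chain` builds an extended poly-alanine chain
(phi, psi = −139, 135; idealized internal geometry shared with the
outlier reference dictionary, so clean chains have zero outliers and zero
clashes by construction). Clashes are planted by moving a carbon-bound
hydrogen onto a backbone oxygen at an exact vdW overlap, choosing the
placement direction on a deterministic spherical lattice so no third atom
is grazed and the H-C bond stretches by at most 0.75 A; the construction
ledger lists exactly the planted pairs, giving the clash detector an
exact cross-check. `make_survey_set` samples rigid dimers across
attractive wells and places repulsive points at a true interaction energy
of +2 kcal/mol by bisection on the inner wall, adding seeded Gaussian
noise to form references. All generators are pure functions of their
arguments, seed included.

What the synthetic data do *not* emulate: real residue diversity,
electrostatics and charge transfer, solvation, experimental coordinate
error, and the size and heterogeneity of real training sets. Passing the
end-to-end tests demonstrates that the fitting-and-reweighting machinery
cures the modeled pathology; it does not by itself certify accuracy on
real proteins.

## Numerical choices and degenerate inputs

Distance comparisons use closed intervals everywhere (a pair exactly at a
cutoff or threshold is included). Neighbor enumeration uses a k-d tree
with a post-filter so boundary behavior equals exhaustive enumeration.
Altloc handling keeps the highest-occupancy conformer (first on ties).
Element symbols are title-cased; deuterium is treated as hydrogen.
Covalent radii are a published single-bond consensus table; topology
inference bonds pairs within 1.15x the radius sum, with explicit ADD/DEL
edits applied afterwards for structures whose clashes masquerade as
covalent bonds. Fits are deterministic; `seed` arguments exist for
interface uniformity and provenance logging wherever no randomness is
actually drawn.

## Known limitations

* The pair term cannot repair a clash that already exists in the starting
  geometry (zero force inside the plateau); the protocol prevents clash
  *formation* during optimization from sensible starts.
* One proxy per pair cannot identify (b, c); auxiliary decay-region data
  (or, in a full parameterization, the bulk of the training set) must pin
  them.
* The surrogate's collapse dynamics on long chains are chaotic enough
  that per-run clashscores vary between local minima; the frozen study
  conditions use short chains, where outcomes are reproducible.
* Absolute SAS volumes depend on the radius set and grid spacing; only
  differences under a fixed protocol are meaningful.
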