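# Methods

This note documents the models and numerical choices behind
`butenolide_scout`, in the order the pipeline runs them.

## Sequence similarity network and exclusivity calibration

Every pair of input proteins is scored by Smith–Waterman local alignment
with BLOSUM62 and affine gap penalties (open 11, extend 1), the common
defaults of protein search tools. Raw scores S are converted to bits with
the standard gapped Karlin–Altschul form S′ = (λS − ln K)/ln 2 using
λ = 0.267, K = 0.041, and to E-values as E = m·n·2^(−S′), where m is the
query length and n the effective database size. Because the network is a
self-contained all-vs-all comparison rather than a database search, n is
defined as the total residue count of the input set. For an undirected
edge, m is taken from the lexicographically smaller sequence id so the edge
E-value is symmetric and deterministic; raw and bit scores are symmetric by
construction. E-values are computed in log space and clamped at the
smallest positive double, so extreme bit scores never underflow to an
exact zero.

An SSN at threshold t contains the edge (i, j) iff E(i, j) ≤ t, which makes
edge sets nested across thresholds. "Mutually exclusive co-localization"
means no connected component contains two distinct family labels; a family
occupying several pure components is still exclusive. The calibration scans
a descending decade grid (1e-10 … 1e-120 by default) from permissive to
strict and returns the first exclusive threshold — the most permissive one,
which separates families while keeping each family maximally connected. If
even the strictest grid value mixes labels (e.g. two families assigned to
near-identical sequences whose pair E-value beats the whole grid), the
search reports no threshold. The shipped default cutoff for mining is
1e-70. Full-length sequences are networked; no domain trimming is applied.

## Genomic-context rule

A putative butenolide receptor is a TetR_N-family gene whose neighborhood
contains (a) a cytochrome P450 gene (PF00067) and (b) at least one
acyl-CoA dehydrogenase/oxidase gene (PF00441, PF08028, or PF01756). The
neighborhood is the ±5 genes around the receptor in gene-rank order
(configurable); ranks rather than base pairs make the rule robust to
intergenic length variation. Both clauses may be satisfied by the same
neighbor, strand is ignored, and enlarging the window can only add
neighbors, so a true verdict never flips to false under a larger window.
Strand-agnostic matching is a deliberate choice — requiring co-orientation
is stricter than the rule needs and is left configurable in principle via
the rule object. Domain assignment is annotation-driven: Pfam accessions
come from GenBank qualifiers or a sidecar locus→Pfam TSV, and the receptor
family is the literal tag `TetR_N` in that table, so the core rule runs
with no profile-HMM scanner in the loop.

## Conservation scoring and structure painting

Column conservation is gap-penalized normalized Shannon entropy:
score = (1 − H/ln 20)·(1 − g), with H the entropy of the amino-acid
frequencies in the column (gaps excluded from H) and g the gap fraction.
All-gap columns score 0 by convention. The metric is bounded in [0, 1],
invariant to row order, and never decreased by adding a duplicate
sequence. It is deliberately unweighted — no phylogenetic down-weighting —
so absolute values are comparable only within one alignment; rank order is
the meaningful output. The alignment itself is an input: MSA construction
heuristics are out of scope.

Scores map through a designated reference record (first record by default)
to 1-based residue numbers and are painted into the B-factor field of a
PDB structure as score×100, with −1 marking unmapped residues. Mapping is
by residue-number identity with an optional constant offset; no
re-alignment is attempted.

## Domain-shift quantification

Cα traces are paired by residue number (unmatched residues dropped). The
holo structure is superposed onto the apo structure using ligand-binding
domain (LBD) pairs only, via the Kabsch SVD solution with a sign flip of
the smallest singular direction to enforce a proper rotation; clouds whose
cross-covariance has rank < 2 (collinear points) are rejected. The rigid
rotation mapping the apo DNA-binding domain (DBD) onto the LBD-aligned holo
DBD is then fitted the same way, and its angle, arccos((trace − 1)/2)
clamped to [0°, 180°], is the reported shift. Note the arccos form is
√ε-conditioned near identity, so "zero shift" computes to ~1e-6 degrees in
double precision.

Domain boundaries are configuration, defaulting to DBD = residues 1–65 and
LBD = 66–end, an N-terminal split typical of TetR-family receptors; exact
helix boundaries for a particular structure should be supplied by the user.

## One-site ITC model and fit

Totals after injection i (cumulative injected volume v) use the
displaced-volume correction for an overfilled cell:
Mt = M0·(1 − v/2V0)/(1 + v/2V0) and Xt = X0·(v/V0)/(1 + v/2V0) — the
injected moles over the displacement-corrected effective volume. Variants
of the syringe-side correction differ across instrument software; since
simulation and fitting share one model, parameter recovery is insensitive
to the variant. The complex concentration is the smaller root of
c² − c(nMt + Xt + Kd) + nMt·Xt = 0, evaluated in the cancellation-safe form
2nMtXt/(b + √(b² − 4nMtXt)). Cumulative heat is Q = c·V0·ΔH and the
differential heat adds the expelled-aliquot term (dV/V0)(Qi + Qi−1)/2,
normalized per mole of injectant.

The fit runs trust-region least squares over (n, ln Kd, ΔH) — the log
scale enforces Kd > 0 — with the first injection excluded (a small
pre-injection whose heat is corrupted by syringe-tip diffusion).
Initialization: n from the molar ratio at the steepest heat change, ΔH
from the mean of the first three post-excluded heats, Kd from a Wiseman
c ≈ 10 prior. A curve whose final heats have not decayed below half the
initial plateau never crossed its equivalence point and is rejected as
degenerate rather than fitted. Standard errors come from the Gauss–Newton
curvature at the optimum, with the ln Kd error delta-mapped back to Kd.
Derived quantities: ΔG = RT·ln(Kd/1 M) (R = 1.987 cal mol⁻¹ K⁻¹, reported
in kcal/mol) and ΔS = (ΔH − ΔG)/T in cal mol⁻¹ K⁻¹.

The reference protocol (`PAPER_PROTOCOL`) is a VP-ITC titration: 1.8 mL
cell at 8 µM macromolecule, 80 µM ligand syringe, 35 injections (2 µL then
34 × 7 µL), 298.15 K. With Kd = 42.5 nM this gives Wiseman c ≈ 188, a
sharply sigmoidal isotherm whose inflection sits at molar ratio ≈ n.
Stoichiometry is always fitted as a free parameter, never pinned to 1.

## Synthetic data

The generators define the study conditions for all tests; every generator
is seeded and deterministic.

* **Families**: a random ancestor is mutated (substitutions only, no
  indels) to family founders at the between-family identity target, then to
  members at the within-family target; the per-branch substitution rate
  corrects for chance coincidence (~1/20) at doubly-mutated positions.
  Defaults: 3 families × 5 members, length 200, 90% within / 30% between —
  well-separated families typical of receptor clades. Because there are no
  indels, the outputs are trivially alignable and double as MSAs. Real
  families have indels, domain architecture variation and phylogenetic
  structure; passing tests show threshold calibration works when families
  are separable, not that any fixed cutoff transfers to arbitrary data.
* **Genomes**: one contig per plan with 3 true operons and 4 decoys by
  default, each decoy violating exactly one rule clause (anchor-only,
  alternative-only, no-receptor, or partners pushed beyond the window);
  cassettes are separated by window+1 filler genes so neighborhoods never
  bleed together, with intergenic gaps of 50–300 bp and ~900 bp genes. The
  nucleotide sequence is random filler; only the feature table matters.
* **Structures**: two compact random-walk Cα clusters (residues 1–65 and
  66–220, ~1.5 Å steps); the holo copy rotates the first cluster about a
  random axis through the hinge (centroid of the boundary residue pair),
  optionally adding Gaussian coordinate noise. A planted 0° angle yields a
  bit-identical copy.
* **MSAs**: per column, a majority residue is drawn with the probability
  (found by root-finding on the 20-letter mixture entropy) that makes the
  expected score equal the target; remaining mass is uniform over the
  other 19 residues; no gaps by default.
* **Isotherms**: the one-site model plus i.i.d. Gaussian noise on the
  normalized heats; the default 0.2 kcal/mol reflects a few percent of the
  ~−10 kcal/mol plateau, typical of a clean VP-ITC run. Real baselines
  drift and early-injection artifacts are not modeled beyond excluding the
  first injection.

## Problem sizes

Default test and acceptance problem sizes are chosen so the whole suite
runs in seconds on one core while keeping estimates stable: 100 fitted
replicates for the titration experiment, 20 genome seeds for the
context-rule precision/recall check, 30 sequences of length 200 for the
exclusivity calibration, 10-point clouds against 10,000 random rotations
for the superposition oracle.

## Known limitations

* E-values are internally consistent but not interchangeable with those of
  any specific search engine; only the relative ordering and the
  calibration procedure carry over.
* Exclusivity treats a family split across pure components as exclusive;
  callers who require single-component families should check the
  per-family component counts (the calibration tests do).
* The domain-shift measurement assumes both domains are internally rigid;
  it reports a single rotation, not a hinge axis or per-residue
  deformation.
* The ITC fitter covers the single-site model only; multi-site,
  sequential, and competitive schemes are out of scope.
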