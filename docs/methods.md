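# Methods

## Model

An equivariant evolutionary model is specified by a permutation group
`G ≤ S4` on the alphabet `{A,C,G,T}` (digits 0–3, order A < C < G < T). A
tree distribution under the model is

    p_{x1…xn} = Σ_{interior assignments} Π_{x_root} · Π_e A^e[x_parent, x_child]

with a root vector Π fixed by every permutation matrix `P_g` of the group and
edge matrices satisfying `P_g A P_g^{-1} = A`. "Stochastic" means entries of
Π and every matrix row sum to one (non-negativity is not imposed — the
algebraic setting). A phylogenetic mixture is a weighted sum of such tensors
over arbitrary trees and parameters under one model; for the five groups the
set of mixtures is the linear space `L^G` of G-invariant tensors.

Key consequences implemented and tested here:

- `dim L^G` = number of G-orbits on length-n words, computed two independent
  ways (conjugacy-class/character sum and printed closed forms) and
  cross-checked against explicit orbit enumeration.
- `L^G` is cut out by the nested minimal equation system described below.
- Every orbit tensor `τ{X}_G = Σ_g gX` lies on a tree point when some letter
  has a trivial stabiliser (K81, SSM, GMM); for K80 and JC69 every letter has
  a stabiliser of order ≥ 2 and the construction is rejected.

## The equation generator

Equations accumulate along the chain SSM → K81 → K80 → JC69; each stage adds
`p_X = p_{gX}` for one canonical representative X of every orbit newly merged
at that stage:

- **SSM**: g = (AT)(CG), X over all words with first letter in {A,C}
  (2^(2n−1) equations).
- **K81**: g = (AC)(GT), X with first letter A (4^(n−1) equations). The
  stage's permutation is (AC)(GT), the transversal of the SSM subgroup inside
  the K81 group; using (AT)(CG) here would duplicate the SSM layer, and the
  published worked equations for three taxa (pAAA=pCCC, …) confirm (AC)(GT).
- **K80**: g = (AG), X with first letter A, X outside {A,G}^n ∪ {C,T}^n, and
  the first {C,T}-letter of X being C (2^(2n−3) − 2^(n−2) equations). The
  domain restriction matters: for X inside {A,G}^n ∪ {C,T}^n the image (AG)X
  already lies in the K81-orbit of X, so such equations would be redundant —
  this is validated by the exact rank check.
- **JC69**: (a) g = (AT) for words over {A,C} starting with A and containing
  a C (2^(n−1) − 1 equations); (b) g = (AC) *and* g = (AT) for each word with
  ≥ 3 distinct letters whose letters in order of first appearance read
  A, C, G (then T if present). The first-appearance condition picks exactly
  one representative per orbit; both the "form A^l C^m …" and "a G precedes
  any T" conditions require l, m ≥ 1, as the counts force.

Verification is exact and dual-route:

- **Soundness**: each equation's two words must lie in a common G-orbit —
  equivalently, every orbit-indicator tensor of the group annihilates the
  equation. Violations are reported, not raised.
- **Completeness/independence**: each equation is a ±1 difference of two
  coordinates, so the system is the incidence system of a graph on the 4^n
  coordinates and its rank over Q is `Σ_components (size − 1)`, computed
  exactly by union–find. The tests additionally cross-check this rank against
  dense exact rational elimination (sympy) at small n. The system is accepted
  when rank = 4^n − dim L^G.

One caveat documented rather than hidden: the published worked K80 equations
for three taxa include three lines (pAAG=pGAA, pAGA=pGAG, pAGG=pGAA) whose
left words lie inside {A,G}^3; pAAG=pGAA is actually violated by the K80
orbit indicator of {AAG,CCT,GGA,TTC}. The generator follows the selection
rule above (which passes the rank check); the golden tests pin the three
published K80 equations that are consistent with it, plus the full verified
6-equation layer.

## Orbit tensors on trees

For K81, SSM and GMM the package realizes `τ{Y}_G` exactly: leaves carrying
equal letters of Y join a node per distinct letter, each joined to the root;
pendant edges carry the identity, the edge above the letter-z node carries
the 0/1 matrix with ones at `(h·x0, h·z)` for h ∈ G, and the root vector is
the indicator of the orbit of a trivial-stabiliser letter x0. With the
*stochastic* root vector (1/c on the orbit) the same construction yields
`τ/c`; since the parametrization is linear in the root vector and the
parameter space is a cone, the indicator scaling is used so that the output
equals `τ{Y}_G` on the nose, which is what the exact oracle tests assert for
every word up to length 4 and seeded words at length 5. Degenerate
single-letter words produce a single interior node and are handled.

## Sampling and the synthetic-data generator

`sample_params` draws, per edge, a random row-stochastic matrix
`0.5·I + 0.5·R` with rows of R ~ Dirichlet(1,1,1,1) — the identity weight
keeps matrices diagonally dominant, as in a substitution process over
moderate divergence, and guarantees strictly positive entries — and projects
it onto the model by group averaging `(1/|G|) Σ_g P_g A P_g^{-1}`, which
preserves row sums. Root vectors: the uniform distribution for the
letter-transitive groups (JC69/K80/K81 — the only invariant choice), one free
parameter for SSM (A/T content drawn uniformly in (0.1, 0.9) total), a
Dirichlet(5,…) draw for GMM. The per-draw free-parameter dimension (computed
group-theoretically as orbits on letter pairs minus orbits on letters, per
edge, plus letter orbits minus one at the root) reproduces the
identifiability parameter counts s(n) on trivalent trees for all five models.

`simulate_alignment` samples site columns i.i.d. from the mixture tensor
(multinomial via a seeded generator) and writes 60-column-wrapped FASTA.
What this emulates: exchangeable sites from an exact equivariant mixture.
What it does not: rate heterogeneity beyond the mixture itself, indels,
alignment error, or any violation of the equivariance symmetry — so passing
tests show correctness of the linear-algebraic machinery on data that truly
follow the model class, not robustness of model selection on real genomic
alignments.

All simulation sizes in the default test run are desk-scale choices: 100
seeded draws per model at n = 4–5 for membership, 10^3–10^5 sites for the
simulator/scorer loop, n ≤ 6 for the exact dimension/rank cross-validation.

## Scoring

Alignments are read column-wise; any column containing a character outside
A/C/G/T (after uppercasing, with U mapped to T) is discarded whole and
tallied — fractional attribution of IUPAC codes would break the exactness of
the counts. Record i maps to leaf i in file order (a flag switches to
name-sorted order). Scores per model: max single-equation residual,
root-sum-square of residuals, and distance to the orbit-mean projection
(which is the orthogonal projection onto `L^G`, since orbit indicators are an
orthogonal basis of the space). The spaces are nested, so projection
distances are non-decreasing from GMM to JC69 on any input — reported and
tested. No p-values, bootstrap or information criteria are produced: the
statistical calibration of residuals is deliberately out of scope, and the
report says so to prevent misuse.

## Identifiability

`h0(model, n) = dim(D_M)/(s(n)+1)` is kept as an exact `Fraction`; the
integer threshold is `⌈h0⌉` (the printed jump from 5/2 to 3 for JC69 on four
taxa fixes this reading). The module reports *non*-identifiability only —
nothing is claimed below the threshold, where the question is open in
general. The complementary positive bound for GMM mixtures on a single
trivalent topology is exposed as an informational record carrying **both**
readings of its ambiguously rendered bound (4^(⌈n/4⌉−1) versus 4^(⌈n/4⌉)−1)
with an ambiguity flag; it never feeds the threshold.

## Numerical choices

- Exact path (stdlib `Fraction`, object-dtype arrays) for every mathematical
  identity: equation verification, orbit-tensor realization, dimension
  arithmetic, h0. Float path (tolerance 1e-10 unless stated) for simulation
  and scoring.
- The tensor parametrization has two implementations — a pruning-style
  dynamic program over subtrees and a literal sum over interior-state
  assignments — which must agree exactly (rational path) or to 1e-12 (float
  path); both accept either dtype.
- Re-rooting uses the Bayes reversal `A' = D(π_u)^{-1} A^T D(π_v)` with node
  marginals π, valid for any Markov process on a tree; it requires strictly
  positive marginals (guaranteed by the sampler's positive matrices) and is
  tested by tensor equality to 1e-10, the strong observable form of
  root-position independence.
- Trees are stored rooted (the parametrization needs directions); parsers
  reject duplicate labels and non-root degree-2 nodes; generated topologies
  root at the interior node adjacent to leaf 1. Topology enumeration inserts
  leaf k into every edge of every (k−1)-leaf shape, giving each of the
  (2n−5)!! labeled trivalent topologies exactly once.
- Equation emission on the command line is capped at n = 8 by default
  (65536 coordinates; output size dominates beyond), overridable with
  `--force`.
- The scorer evaluates the full equation system (cheap at n ≤ 8); restricting
  to equations touching observed patterns is a pure performance optimization
  left unimplemented.

## Known limitations

- Only the five named groups are exposed; the internals are generic over an
  element set, but minimal equation systems for other equivariant groups are
  not established and are not attempted.
- No continuous-time (rate matrix / branch length) parametrization; edges
  carry discrete transition matrices.
- No tree reconstruction, no hypothesis-test calibration, and no nonlinear
  (tree-specific) invariants — including the tree-specific *linear*
  invariants that exist for JC69 and K80 beyond the mixture-space equations.
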