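# phylinv

Linear invariants, exact dimensions and identifiability bounds for
phylogenetic mixtures under the five classical **equivariant** nucleotide
substitution models: Jukes–Cantor (JC69), Kimura 2- and 3-parameter (K80,
K81), the strand symmetric model (SSM) and the general Markov model (GMM).

## The problem and who this is for

A Markov process on a rooted tree with root distribution Π and one 4×4
transition matrix per edge induces a joint distribution
`p = (p_{x1…xn})` over the 4^n site patterns observed at the `n` leaves.
Each of the five models is *equivariant*: it is determined by a permutation
group `G ≤ S4` acting on `{A,C,G,T}` (S4 for JC69; ⟨(ACGT),(AG)⟩ for K80;
⟨(AC)(GT),(AG)(CT)⟩ for K81; ⟨(AT)(CG)⟩ for SSM; the trivial group for GMM),
and its transition matrices are exactly those commuting with every
permutation matrix of `G`.

The central fact the package implements: the set `D_M` of *phylogenetic
mixtures* — arbitrary linear/convex combinations of tree distributions under
one model, over **any** trees and parameters — is a linear space, equal to the
space `L^G` of G-invariant tensors. It is cut out by simple coordinate
equalities `p_X = p_{gX}`, and its dimension is the number of G-orbits on
length-n words,

    dim L^G = (1/|G|) · Σ_{g∈G} χ(g)^n ,   χ(g) = #letters fixed by g.

This gives users in molecular evolution three practical tools:

1. **Minimal equation systems.** A nested, minimal, linearly independent
   system `E_M` of invariants for each model and any `n` (the SSM layer is a
   prefix of K81's, K81's of K80's, K80's of JC69's), verified exactly over
   the rationals (soundness + rank = codimension).
2. **Model-fit scoring.** Empirical pattern frequencies from an alignment can
   be scored against each model space by pure linear algebra — the
   model-selection use of these invariants — with no tree search and no
   assumption on the number of mixture classes.
3. **Identifiability bounds.** With `s(n)` free parameters per trivalent tree,
   an h-class mixture has at most `h·s(n) + h − 1` degrees of freedom, so for

       h ≥ h0(n) = dim(D_M) / (s(n) + 1)

   the tree topologies and/or continuous parameters of h-mixtures are **not**
   identifiable (e.g. h ≥ 4 for K81 on 4 taxa; h ≥ 3 for JC69 on 4 taxa).

The package also contains a seeded simulator for equivariant tree models and
mixtures (used throughout the tests as the fixture generator), the orbit
tensors `τ{X}_G` together with the explicit two-level-tree construction that
realizes them when some letter has a trivial stabiliser (K81, SSM, GMM — and
a clean error for K80/JC69, where it is impossible), and an exact
Bayes-reversal re-rooting transport.

## Worked example

Library:

```python
>>> import phylinv as pv
>>> pv.dimension_closed_form("JC69", 3)          # dim L^JC69, n = 3
5
>>> eqs = pv.equations("JC69", 3)                # nested minimal system
>>> len(eqs), eqs.layer_counts()
(59, {'SSM': 32, 'K81': 16, 'K80': 6, 'JC69': 5})
>>> [e.as_text for e in eqs.layer("JC69")]
['pAAC=pTTC', 'pACA=pTCT', 'pACC=pTCC', 'pACG=pCAG', 'pACG=pTCG']
>>> rep = pv.verify_equation_set(eqs)            # exact rational verification
>>> rep.sound, rep.complete, rep.rank            # rank 59 = 64 - dim
(True, True, 59)
>>> pv.h0("JC69", 4), pv.mixture_threshold("JC69", 4)
(Fraction(5, 2), 3)
```

Command line (same numbers):

```console
$ phylinv ident --model JC69 --n 4
model: JC69
n: 4
dim_DM: 15
s: 5
h0: 5/2
h0_float: 2.5
threshold: 3
statement: JC69 h-mixtures on 4 taxa are not identifiable for h >= 3; nothing is claimed below
$ phylinv dim --model K80 --n 6
528
```

`dim_DM = 15` is the number of S4-orbits on 4-letter words; `s = 5 = 2n−3`
is the JC69 parameter count on a trivalent quartet tree; their ratio
`15/(5+1) = 5/2` rounds up to the threshold 3: mixtures of three or more
JC69 quartet trees cannot be fully recovered from pattern frequencies.

Simulate a K81 quartet alignment and score it:

```console
$ phylinv simulate --tree "((1,2),(3,4));" --model K81 --sites 20000 --seed 7 --output k81.fasta
$ phylinv fit k81.fasta
model       dim     n_eq    max_resid     l2_resid    proj_dist
GMM         256        0    0.000e+00    0.000e+00    0.000e+00
SSM         128      128    1.750e-03    6.765e-03    4.783e-03
K81          64      192    1.750e-03    8.107e-03    6.110e-03
K80          36      220    2.700e-03    9.135e-03    7.844e-03
JC69         15      241    4.600e-03    1.105e-02    1.209e-02
ranking (best fit first): GMM > SSM > K81 > K80 > JC69
```

For each model the report shows the space dimension, the number of equations
evaluated, the largest single-equation residual `max |p_X − p_Y|`, the
root-sum-square of all residuals, and the Euclidean distance from the
empirical tensor to its orthogonal projection onto the model space. The exact
K81 tensor satisfies the GMM/SSM/K81 systems identically, so those residuals
here are pure multinomial sampling noise (≈ 2·10⁻³ per coordinate at 2·10⁴
sites); moving past K81 down the nesting chain adds genuine violations on
top of the noise. Residuals are geometric, not calibrated test statistics —
see `docs/methods.md`.

## Layout

- `phylinv.wordspace` — alphabet, word indexing, the five groups, orbits,
  stabilisers, characters, conjugacy classes.
- `phylinv.invariants` — dimensions (character and closed forms), the nested
  minimal equation systems, exact verification, orbit-mean projection.
- `phylinv.tree_model` — Newick I/O, topology enumeration, equivariant
  parameter sampling, the tensor parametrization (pruning + brute force),
  mixtures, orbit tensors and their tree realization, re-rooting.
- `phylinv.selection` — FASTA pattern counting, residual scoring, model-fit
  reports, alignment simulation.
- `phylinv.identifiability` — parameter counts, `h0`, thresholds, closed
  forms.
- `phylinv.cli` — `phylinv equations | dim | ident | simulate | fit`.
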