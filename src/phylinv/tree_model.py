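"""Rooted trees, equivariant Markov parameters, tensors and mixtures.

A Markov process on a rooted tree with root distribution ``Pi`` and one 4x4
transition matrix per edge (rows indexed by the parent state) induces the
joint leaf-pattern tensor

    p_{x1...xn} = sum over interior-state assignments of
                  Pi_{x_root} * prod_e A^e[x_parent(e), x_child(e)].

The process evolves under one of the five equivariant models when ``Pi`` is
fixed by the model's group and every edge matrix commutes with each of the
group's permutation matrices.  This module provides Newick I/O (via dendropy),
topology enumeration, seeded sampling of equivariant parameters, the tensor
parametrization (both a literal brute-force sum and a pruning-style dynamic
program), mixtures, orbit tensors ``tau{X}_G``, the explicit two-level-tree
construction realizing every orbit tensor when some letter has trivial
stabiliser, and an exact Bayes-reversal re-rooting transport.

Matrix orientation convention: ``A[i, j]`` is the probability of child state
``j`` given parent state ``i``.  Transition matrices are discrete (no
branch-length/rate-matrix parametrization).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import dendropy
import numpy as np

from .wordspace import (
    ALPHABET,
    MODEL_NAMES,
    Permutation,
    apply,
    model_group,
    orbit,
    stabiliser,
    word_to_index,
)


class NewickError(ValueError):
    """Raised for malformed or invalid Newick input."""


class UnsupportedModelError(ValueError):
    """Raised when an operation requires a letter with trivial stabiliser."""


class Tree:
    """A rooted phylogenetic tree with leaves labeled 1..n.

    Nodes are integers 0..N-1 with node 0 the root; edges are oriented away
    from the root.  Interior nodes of degree 2 (other than the root) are
    rejected on parse but may be produced by explicit constructions.
    """

    def __init__(
        self,
        children: Sequence[Sequence[int]],
        leaf_labels: dict[int, int],
        root: int = 0,
    ):
        self.children = [list(c) for c in children]
        self.leaf_labels = dict(leaf_labels)
        self.root = root
        n_nodes = len(self.children)
        self.parent = [-1] * n_nodes
        for u, kids in enumerate(self.children):
            for v in kids:
                self.parent[v] = u
        labels = sorted(self.leaf_labels.values())
        if labels != list(range(1, len(labels) + 1)):
            raise NewickError(f"leaf labels must be 1..n, got {labels}")
        for v, kids in enumerate(self.children):
            if not kids and v not in self.leaf_labels:
                raise NewickError(f"unlabeled leaf node {v}")
            if kids and v in self.leaf_labels:
                raise NewickError(f"labeled interior node {v}")

    # -- structure ----------------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    def leaves(self) -> list[int]:
        """Leaf nodes ordered by label 1..n."""
        by_label = {lab: v for v, lab in self.leaf_labels.items()}
        return [by_label[i] for i in range(1, self.n_leaves + 1)]

    def interior_nodes(self) -> list[int]:
        return [v for v, kids in enumerate(self.children) if kids]

    def edges(self) -> list[tuple[int, int]]:
        """Directed edges (parent, child), oriented away from the root."""
        return [(u, v) for u, kids in enumerate(self.children) for v in kids]

    def degree(self, v: int) -> int:
        return len(self.children[v]) + (0 if v == self.root else 1)

    @property
    def is_trivalent(self) -> bool:
        """True iff every interior node has degree 3 in the unrooted sense
        (a degree-2 root is suppressed when unrooting)."""
        return all(
            self.degree(v) == 3
            for v in self.interior_nodes()
            if not (v == self.root and self.degree(v) == 2)
        )

    # -- Newick I/O ---------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        """Parse a Newick string; leaf names may be "1".."n" or arbitrary
        names, which are mapped to 1..n in input order."""
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickError(f"malformed Newick {text!r}: {exc}") from exc
        return cls._from_dendropy(dtree, text)

    @classmethod
    def _from_dendropy(cls, dtree: "dendropy.Tree", text: str) -> "Tree":
        dnodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(dnodes)}
        children: list[list[int]] = [[] for _ in dnodes]
        raw_labels: list[tuple[int, str]] = []
        for nd in dnodes:
            i = index[id(nd)]
            kids = nd.child_nodes()
            for c in kids:
                children[i].append(index[id(c)])
            if not kids:
                label = nd.taxon.label if nd.taxon is not None else nd.label
                if label is None:
                    raise NewickError(f"unlabeled leaf in {text!r}")
                raw_labels.append((i, str(label)))
            elif len(kids) == 1:
                raise NewickError(
                    f"degree-2 node (single child) in {text!r}; only the root "
                    "may have degree 2"
                )
        names = [lab for _, lab in raw_labels]
        if len(set(names)) != len(names):
            raise NewickError(f"duplicate leaf labels in {text!r}")
        try:
            numeric = [int(lab) for lab in names]
        except ValueError:
            numeric = None
        if numeric is not None and sorted(numeric) == list(range(1, len(names) + 1)):
            leaf_labels = {node: int(lab) for (node, lab) in raw_labels}
        else:  # map names to 1..n in input order
            leaf_labels = {node: k + 1 for k, (node, _) in enumerate(raw_labels)}
        if len(leaf_labels) < 2:
            raise NewickError(f"need at least 2 leaves, got {len(leaf_labels)}")
        return cls(children, leaf_labels)

    def to_newick(self) -> str:
        def render(v: int) -> str:
            if not self.children[v]:
                return str(self.leaf_labels[v])
            return "(" + ",".join(render(c) for c in self.children[v]) + ")"

        return render(self.root) + ";"

    def __repr__(self) -> str:
        return f"Tree({self.to_newick()!r})"


# -- topology enumeration ----------------------------------------------------


def _adjacency_to_tree(adj: dict[int, set[int]], n: int) -> Tree:
    """Root an unrooted adjacency structure at the interior node adjacent to
    leaf 1 and renumber nodes in preorder."""
    root_old = next(iter(adj[1]))  # leaves carry ids 1..n
    order: list[int] = []
    stack = [(root_old, -1)]
    parent_of: dict[int, int] = {}
    while stack:
        u, pu = stack.pop()
        order.append(u)
        parent_of[u] = pu
        for w in sorted(adj[u], reverse=True):
            if w != pu:
                stack.append((w, u))
    new_id = {old: i for i, old in enumerate(order)}
    children: list[list[int]] = [[] for _ in order]
    leaf_labels: dict[int, int] = {}
    for old in order:
        i = new_id[old]
        for w in sorted(adj[old]):
            if w != parent_of[old]:
                children[i].append(new_id[w])
        if 1 <= old <= n:
            leaf_labels[i] = old
    return Tree(children, leaf_labels)


def trivalent_topologies(n: int) -> list[Tree]:
    """All (2n-5)!! unrooted trivalent topologies on leaves 1..n, each rooted
    at the interior node adjacent to leaf 1."""
    if n < 3:
        raise ValueError("trivalent topologies require n >= 3")
    # leaves are nodes 1..n; interior nodes get ids n+1, n+2, ...
    base: dict[int, set[int]] = {n + 1: {1, 2, 3}}
    for leaf in (1, 2, 3):
        base[leaf] = {n + 1}
    shapes = [(base, n + 2)]
    for leaf in range(4, n + 1):
        grown = []
        for adj, next_id in shapes:
            edges = {
                tuple(sorted((u, v))) for u, nbrs in adj.items() for v in nbrs
            }
            for u, v in sorted(edges):
                new_adj = {k: set(s) for k, s in adj.items()}
                w = next_id
                new_adj[u].discard(v)
                new_adj[v].discard(u)
                new_adj[u].add(w)
                new_adj[v].add(w)
                new_adj[w] = {u, v, leaf}
                new_adj[leaf] = {w}
                grown.append((new_adj, next_id + 1))
        shapes = grown
    return [_adjacency_to_tree(adj, n) for adj, _ in shapes]


def random_trivalent_tree(n: int, rng: np.random.Generator) -> Tree:
    """A uniformly random trivalent topology, by random edge insertion."""
    if n < 3:
        raise ValueError("need n >= 3")
    adj: dict[int, set[int]] = {n + 1: {1, 2, 3}, 1: {n + 1}, 2: {n + 1}, 3: {n + 1}}
    next_id = n + 2
    for leaf in range(4, n + 1):
        edges = sorted({tuple(sorted((u, v))) for u, nb in adj.items() for v in nb})
        u, v = edges[rng.integers(len(edges))]
        w = next_id
        next_id += 1
        adj[u].discard(v)
        adj[v].discard(u)
        adj[u].add(w)
        adj[v].add(w)
        adj[w] = {u, v, leaf}
        adj[leaf] = {w}
    return _adjacency_to_tree(adj, n)


# -- equivariant parameters --------------------------------------------------


@dataclass
class TreeParams:
    """Root vector and per-edge transition matrices for one tree and model.

    ``edge_matrices`` is keyed by the child node of each edge.  ``stochastic``
    records whether the root vector and matrix rows sum to one.
    """

    model: str
    root_vector: np.ndarray
    edge_matrices: dict[int, np.ndarray]
    stochastic: bool = True

    @property
    def exact(self) -> bool:
        return np.asarray(self.root_vector).dtype == object

    def to_json(self, tree: Tree) -> str:
        return json.dumps(
            {
                "model": self.model,
                "stochastic": self.stochastic,
                "tree": tree.to_newick(),
                "root_vector": [float(x) for x in self.root_vector],
                "edge_matrices": {
                    str(child): [[float(x) for x in row] for row in mat]
                    for child, mat in sorted(self.edge_matrices.items())
                },
            },
            indent=2,
        )


def _perm_inverse_indices(g: Permutation) -> np.ndarray:
    return np.asarray(g.inverse().mapping, dtype=np.intp)


def group_average(matrix: np.ndarray, model: str) -> np.ndarray:
    """Project a matrix onto the model's equivariant subspace by averaging
    the conjugates ``P_g A P_g^{-1}`` over the group; preserves row sums."""
    G = model_group(model)
    mat = np.asarray(matrix)
    acc = np.zeros_like(mat, dtype=mat.dtype if mat.dtype == object else float)
    for g in G:
        inv = _perm_inverse_indices(g)
        acc = acc + mat[np.ix_(inv, inv)]
    if mat.dtype == object:
        return acc * Fraction(1, G.order)
    return acc / G.order


def check_equivariance(matrix: np.ndarray, model: str, atol: float = 1e-10) -> bool:
    """True iff conjugation by every group element's permutation matrix fixes
    the matrix (``P_g A P_g^{-1} = A``)."""
    mat = np.asarray(matrix)
    if mat.shape != (4, 4):
        raise ValueError("expected a 4x4 matrix")
    for g in model_group(model):
        inv = _perm_inverse_indices(g)
        conj = mat[np.ix_(inv, inv)]
        if mat.dtype == object:
            if not (conj == mat).all():
                return False
        elif not np.allclose(conj, mat, atol=atol, rtol=0.0):
            return False
    return True


def invariant_root_vector(model: str, rng: np.random.Generator | None = None) -> np.ndarray:
    """A stochastic root vector fixed by the model's group.

    JC69/K80/K81 groups act transitively on letters, so the uniform vector is
    the only choice; SSM has one free parameter (A/T versus C/G content); GMM
    has three.
    """
    if model in ("JC69", "K80", "K81"):
        return np.full(4, 0.25)
    if rng is None:
        rng = np.random.default_rng(0)
    if model == "SSM":
        a = rng.uniform(0.05, 0.45)  # Pi_A = Pi_T = a, Pi_C = Pi_G = 1/2 - a
        return np.array([a, 0.5 - a, 0.5 - a, a])
    return rng.dirichlet(np.full(4, 5.0))  # GMM


def edge_dof(model: str) -> int:
    """Free parameters per stochastic equivariant matrix: the number of group
    orbits on ordered letter pairs minus the number of orbits on letters."""
    G = model_group(model)
    pair_orbits = sum(
        (sum(1 for i in range(4) if g.mapping[i] == i)) ** 2 for g in G
    ) // G.order
    letter_orbits = sum(
        sum(1 for i in range(4) if g.mapping[i] == i) for g in G
    ) // G.order
    return pair_orbits - letter_orbits


def root_dof(model: str) -> int:
    """Free parameters of the stochastic invariant root vector."""
    G = model_group(model)
    letter_orbits = sum(
        sum(1 for i in range(4) if g.mapping[i] == i) for g in G
    ) // G.order
    return letter_orbits - 1


def sample_params(
    model: str,
    tree: Tree,
    seed: int | np.random.Generator | None = None,
    stochastic: bool = True,
) -> TreeParams:
    """Draw random parameters evolving under the model on the given tree.

    Each edge matrix is a random row-stochastic matrix (rows with a mild
    diagonal bias, as in a substitution process) replaced by its group
    average, which preserves row sums and lands in the equivariant subspace.
    For the algebraic (non-stochastic) path the root vector is additionally
    scaled by a random positive factor. Deterministic given the seed.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root_vec = invariant_root_vector(model, rng)
    if not stochastic:
        root_vec = root_vec * rng.uniform(0.5, 2.0)
    mats: dict[int, np.ndarray] = {}
    for _, child in tree.edges():
        raw = 0.5 * np.eye(4) + 0.5 * rng.dirichlet(np.ones(4), size=4)
        mats[child] = group_average(raw, model)
    return TreeParams(
        model=model, root_vector=root_vec, edge_matrices=mats, stochastic=stochastic
    )


# -- parametrization ---------------------------------------------------------


def _validate_params(tree: Tree, params: TreeParams) -> None:
    non_root = {v for v in range(tree.n_nodes) if v != tree.root}
    if set(params.edge_matrices) != non_root:
        raise ValueError(
            "edge matrices do not match the tree: expected one matrix per "
            f"non-root node {sorted(non_root)}, got {sorted(params.edge_matrices)}"
        )
    if len(params.root_vector) != 4:
        raise ValueError("root vector must have 4 entries")


def parametrize(tree: Tree, params: TreeParams, method: str = "pruning") -> np.ndarray:
    """The joint leaf-pattern tensor of a Markov process on the tree.

    ``method="pruning"`` runs a bottom-up dynamic program over subtrees;
    ``method="brute"`` evaluates the literal sum over interior-state
    assignments (exponentially slower; used as an oracle in tests).  Both
    paths accept float or exact-rational (object dtype) parameters.
    """
    _validate_params(tree, params)
    if method == "brute":
        return _parametrize_brute(tree, params)
    if method != "pruning":
        raise ValueError(f"unknown method {method!r}")
    exact = params.exact
    dtype = object if exact else float
    one = Fraction(1) if exact else 1.0

    def subtree(v: int) -> tuple[list[int], np.ndarray]:
        label = tree.leaf_labels.get(v)
        if label is not None:
            eye = np.zeros((4, 4), dtype=dtype)
            for i in range(4):
                eye[i, i] = one
            return [label], eye
        leaves: list[int] = []
        acc = np.full((4, 1), one, dtype=dtype)
        for c in tree.children[v]:
            lc, tc = subtree(c)
            mat = np.asarray(params.edge_matrices[c], dtype=dtype)
            sc = mat @ tc  # (4, 4**len(lc)): pattern likelihoods given parent state
            acc = (acc[:, :, None] * sc[:, None, :]).reshape(4, -1)
            leaves.extend(lc)
        return leaves, acc

    leaves, table = subtree(tree.root)
    pi = np.asarray(params.root_vector, dtype=dtype)
    flat = pi @ table
    n = tree.n_leaves
    order = [leaves.index(lab) for lab in range(1, n + 1)]
    return np.transpose(flat.reshape((4,) * n), order).reshape(-1)


def _parametrize_brute(tree: Tree, params: TreeParams) -> np.ndarray:
    """Literal sum over interior-state assignments (oracle path)."""
    exact = params.exact
    dtype = object if exact else float
    zero = Fraction(0) if exact else 0.0
    interior = tree.interior_nodes()
    leaves = tree.leaves()
    n = tree.n_leaves
    out = np.full(4**n, zero, dtype=dtype)
    pi = params.root_vector
    edges = tree.edges()
    for leaf_states in itertools.product(range(4), repeat=n):
        state = {v: s for v, s in zip(leaves, leaf_states)}
        total = zero
        for int_states in itertools.product(range(4), repeat=len(interior)):
            state.update(zip(interior, int_states))
            term = pi[state[tree.root]]
            for u, v in edges:
                term = term * params.edge_matrices[v][state[u], state[v]]
            total = total + term
        idx = 0
        for s in leaf_states:
            idx = 4 * idx + s
        out[idx] = total
    return out


def tensor_sum(p: np.ndarray):
    """The coordinate sum lambda(p); equals 1 for stochastic parameters."""
    total = p[0] - p[0]
    for x in p:
        total = total + x
    return total


# -- mixtures ----------------------------------------------------------------


@dataclass
class MixtureSpec:
    """A phylogenetic mixture: components (tree, params, weight) under one
    model; stochastic mixtures have weights summing to one."""

    components: list[tuple[Tree, TreeParams, float]]
    stochastic: bool = True

    def __post_init__(self):
        if not self.components:
            raise ValueError("a mixture needs at least one component")
        models = {params.model for _, params, _ in self.components}
        if len(models) != 1:
            raise ValueError(f"mixture components use different models: {models}")
        ns = {tree.n_leaves for tree, _, _ in self.components}
        if len(ns) != 1:
            raise ValueError(f"mixture components have different taxa counts: {ns}")
        if self.stochastic:
            total = sum(w for _, _, w in self.components)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"stochastic mixture weights sum to {total}, not 1")

    @property
    def model(self) -> str:
        return self.components[0][1].model

    @property
    def n(self) -> int:
        return self.components[0][0].n_leaves


def mix(spec: MixtureSpec) -> np.ndarray:
    """The mixture tensor ``sum_i alpha_i * parametrize(T_i, theta_i)``."""
    out = None
    for tree, params, weight in spec.components:
        p = weight * parametrize(tree, params)
        out = p if out is None else out + p
    return out


# -- orbit tensors and their tree realization --------------------------------


def tau_orbit_tensor(word: str, model: str, exact: bool = False) -> np.ndarray:
    """The G-invariant orbit tensor ``tau{X}_G = sum_{g in G} gX``: coordinate
    of Y counts the group elements sending X to Y (the stabiliser size on
    each orbit member, zero elsewhere)."""
    G = model_group(model)
    n = len(word)
    out = np.zeros(4**n, dtype=object if exact else float)
    one = Fraction(1) if exact else 1.0
    for g in G:
        out[word_to_index(apply(g, word))] += one
    return out


def prop13_construction(word: str, model: str) -> tuple[Tree, TreeParams]:
    """Build a two-level tree and equivariant parameters whose tensor equals
    ``tau{word}_G`` exactly.

    Requires a letter with trivial stabiliser, which holds for K81, SSM and
    GMM; for JC69 and K80 every letter has a nontrivial stabiliser and the
    orbit tensor is in general not realizable on any tree, so those models
    are rejected.

    The tree joins the leaves carrying equal letters of the word to one node
    per distinct letter, each joined to the root; pendant edges carry the
    identity matrix, the edge above the node of letter z carries the 0/1
    matrix with ones at ``(h*x0, h*z)`` for h in G, and the root vector is
    the indicator of the orbit of the trivial-stabiliser letter x0 (the
    stochastic vector with 1/c on the orbit, scaled by the orbit size c so
    the output is exactly ``tau`` rather than ``tau/c``; the parametrization
    is linear in the root vector, so either scaling realizes the orbit
    tensor up to a known constant).
    """
    G = model_group(model)
    free_letters = [x for x in ALPHABET if len(stabiliser(x, G)) == 1]
    if not free_letters:
        stabs = {
            x: "{" + ",".join(sorted(g.cycle_text for g in stabiliser(x, G))) + "}"
            for x in ALPHABET
        }
        raise UnsupportedModelError(
            f"model {model} has no letter with trivial stabiliser "
            f"(stabilisers: {stabs}); the orbit tensor of a word is not "
            "realizable on a tree for this model"
        )
    x0 = free_letters[0]
    n = len(word)
    distinct = sorted(set(word), key=ALPHABET.index)
    # node 0 = root; nodes 1..m = one per distinct letter; then the n leaves
    m = len(distinct)
    children: list[list[int]] = [[] for _ in range(1 + m + n)]
    leaf_labels: dict[int, int] = {}
    mats: dict[int, np.ndarray] = {}
    eye = np.zeros((4, 4), dtype=object)
    for i in range(4):
        eye[i, i] = Fraction(1)
    for zi, z in enumerate(distinct):
        vz = 1 + zi
        children[0].append(vz)
        mat = np.full((4, 4), Fraction(0), dtype=object)
        for h in G:
            mat[ALPHABET.index(h(x0)), ALPHABET.index(h(z))] = Fraction(1)
        mats[vz] = mat
        for pos, letter in enumerate(word):
            if letter == z:
                leaf = 1 + m + pos
                children[vz].append(leaf)
                leaf_labels[leaf] = pos + 1
                mats[leaf] = eye.copy()
    tree = Tree(children, leaf_labels)
    x0_orbit = orbit(x0, G)
    root_vec = np.array(
        [Fraction(1) if x in x0_orbit else Fraction(0) for x in ALPHABET],
        dtype=object,
    )
    params = TreeParams(
        model=model, root_vector=root_vec, edge_matrices=mats, stochastic=False
    )
    return tree, params


# -- re-rooting --------------------------------------------------------------


def node_marginals(tree: Tree, params: TreeParams) -> dict[int, np.ndarray]:
    """Marginal state distribution at every node, propagated from the root."""
    pi = {tree.root: np.asarray(params.root_vector)}
    order = [tree.root]
    stack = [tree.root]
    while stack:
        u = stack.pop()
        for v in tree.children[u]:
            pi[v] = np.asarray(params.edge_matrices[v]).T @ pi[u]
            stack.append(v)
            order.append(v)
    return pi


def reroot(tree: Tree, params: TreeParams, new_root: int) -> tuple[Tree, TreeParams]:
    """Transport the process to a different root without changing the joint
    leaf distribution.

    Edges pointing toward the old root are reversed by Bayes' rule: the new
    matrix on a reversed edge u -> v is ``D(pi_u)^{-1} A^T D(pi_v)`` where
    ``pi`` are the node marginals of the original process.  Requires strictly
    positive marginals at the nodes along the path (generic stochastic
    parameters satisfy this).
    """
    _validate_params(tree, params)
    if new_root == tree.root:
        return tree, params
    if not 0 <= new_root < tree.n_nodes:
        raise ValueError(f"no node {new_root}")
    pi = node_marginals(tree, params)
    adj: dict[int, set[int]] = {v: set() for v in range(tree.n_nodes)}
    for u, v in tree.edges():
        adj[u].add(v)
        adj[v].add(u)
    # orient away from the new root
    new_children: list[list[int]] = [[] for _ in range(tree.n_nodes)]
    mats: dict[int, np.ndarray] = {}
    seen = {new_root}
    stack = [new_root]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v in seen:
                continue
            seen.add(v)
            new_children[u].append(v)
            if tree.parent[v] == u:  # orientation unchanged
                mats[v] = params.edge_matrices[v]
            else:  # reversed edge: originally v was the parent of u
                a = np.asarray(params.edge_matrices[u], dtype=float)
                if np.any(np.asarray(pi[u], dtype=float) <= 0):
                    raise ValueError(
                        "re-rooting requires strictly positive node marginals"
                    )
                mats[v] = (a * np.asarray(pi[v], dtype=float)[:, None]).T / np.asarray(
                    pi[u], dtype=float
                )[:, None]
            stack.append(v)
    new_tree = Tree(new_children, tree.leaf_labels, root=new_root)
    new_params = TreeParams(
        model=params.model,
        root_vector=np.asarray(pi[new_root], dtype=float),
        edge_matrices=mats,
        stochastic=params.stochastic,
    )
    return new_tree, new_params
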