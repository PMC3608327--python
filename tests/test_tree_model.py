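"""Trees, equivariant parameters, tensors, mixtures and orbit realization."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from phylinv import (
    MODEL_NAMES,
    MixtureSpec,
    NewickError,
    Tree,
    TreeParams,
    UnsupportedModelError,
    all_words,
    check_equivariance,
    edge_dof,
    equations,
    group_average,
    mix,
    model_group,
    parametrize,
    prop13_construction,
    random_trivalent_tree,
    reroot,
    root_dof,
    sample_params,
    tau_orbit_tensor,
    tensor_sum,
    trivalent_topologies,
    word_to_index,
)


def max_equation_residual(p: np.ndarray, model: str, n: int) -> float:
    eqs = equations(model, n)
    if not len(eqs):
        return 0.0
    pairs = eqs.index_pairs()
    return float(np.abs(p[pairs[:, 0]] - p[pairs[:, 1]]).max())


# -- Newick and topology -----------------------------------------------------


def test_star_tree_parse(star3):
    assert star3.n_leaves == 3
    assert len(star3.interior_nodes()) == 1
    assert star3.to_newick() == "(1,2,3);"


def test_quartet_parse_roundtrip(quartet):
    assert quartet.n_leaves == 4
    assert quartet.is_trivalent
    assert Tree.from_newick(quartet.to_newick()).to_newick() == quartet.to_newick()


def test_named_leaves_map_in_input_order():
    t = Tree.from_newick("((human,chimp),(mouse,rat));")
    assert t.n_leaves == 4
    assert sorted(t.leaf_labels.values()) == [1, 2, 3, 4]


@pytest.mark.parametrize(
    "bad",
    ["((1,2),(3,4);", "((1,2),(1,3));", "(1,(2),3);", "(1;2)", "((1,2));"],
)
def test_invalid_newick_rejected(bad):
    with pytest.raises(NewickError):
        Tree.from_newick(bad)


def test_trivalent_topology_counts():
    """(2n-5)!! unrooted trivalent topologies: 3 on 4 leaves, 15 on 5."""
    quartets = trivalent_topologies(4)
    assert len(quartets) == 3
    assert len(trivalent_topologies(5)) == 15
    assert len({t.to_newick() for t in quartets}) == 3
    assert all(t.is_trivalent for t in quartets)


def test_random_tree_is_valid(rng):
    t = random_trivalent_tree(6, rng)
    assert t.n_leaves == 6 and t.is_trivalent


# -- parameters --------------------------------------------------------------


@pytest.mark.parametrize("model", MODEL_NAMES)
def test_sampled_params_are_equivariant_and_stochastic(model, quartet, rng):
    params = sample_params(model, quartet, rng)
    assert np.isclose(params.root_vector.sum(), 1.0)
    for g in model_group(model):
        inv = [g.inverse().mapping[i] for i in range(4)]
        assert np.allclose(params.root_vector[inv], params.root_vector)
    for mat in params.edge_matrices.values():
        assert np.allclose(mat.sum(axis=1), 1.0)
        assert check_equivariance(mat, model)


def test_jc69_matrices_have_two_value_structure(quartet):
    """Averaging over the full symmetric group forces one diagonal value a and
    one off-diagonal value b with a + 3b = 1."""
    params = sample_params("JC69", quartet, 7)
    for mat in params.edge_matrices.values():
        diag = np.diag(mat)
        off = mat[~np.eye(4, dtype=bool)]
        assert np.allclose(diag, diag[0]) and np.allclose(off, off[0])
        assert np.isclose(diag[0] + 3 * off[0], 1.0)


def test_gmm_average_is_identity_map(rng):
    raw = rng.dirichlet(np.ones(4), size=4)
    assert np.allclose(group_average(raw, "GMM"), raw)


def test_random_dense_matrix_is_not_k81_equivariant(rng):
    assert not check_equivariance(rng.random((4, 4)), "K81")
    assert check_equivariance(np.eye(4), "K81")


def test_sampler_free_parameter_dimensions():
    """Per-edge and root degrees of freedom match the identifiability counts
    (3 per edge for K81, 1 for JC69, 12+3 for GMM, ...)."""
    assert {m: edge_dof(m) for m in MODEL_NAMES} == {
        "GMM": 12, "SSM": 6, "K81": 3, "K80": 2, "JC69": 1,
    }
    assert {m: root_dof(m) for m in MODEL_NAMES} == {
        "GMM": 3, "SSM": 1, "K81": 0, "K80": 0, "JC69": 0,
    }


# -- parametrization ---------------------------------------------------------


def test_star_tree_identity_matrices_copy_root(star3):
    eye = np.eye(4)
    params = TreeParams(
        model="JC69",
        root_vector=np.full(4, 0.25),
        edge_matrices={v: eye.copy() for v in range(1, 4)},
    )
    p = parametrize(star3, params)
    for w in all_words(3):
        expected = 0.25 if len(set(w)) == 1 else 0.0
        assert p[word_to_index(w)] == pytest.approx(expected)


@pytest.mark.parametrize("newick", ["(1,2,3);", "((1,2),(3,4));", "((1,2),3,(4,5));"])
@pytest.mark.parametrize("model", ["JC69", "K81", "GMM"])
def test_pruning_agrees_with_bruteforce(newick, model, rng):
    tree = Tree.from_newick(newick)
    params = sample_params(model, tree, rng)
    p_fast = parametrize(tree, params)
    p_slow = parametrize(tree, params, method="brute")
    assert np.allclose(p_fast, p_slow, atol=1e-12)
    assert p_fast.sum() == pytest.approx(1.0, abs=1e-12)


def test_pruning_agrees_with_bruteforce_exact(star3):
    """The two evaluation strategies agree exactly in rational arithmetic."""
    third = Fraction(1, 3)
    mat = np.full((4, 4), Fraction(1, 6), dtype=object)
    for i in range(4):
        mat[i, i] = Fraction(1, 2)
    params = TreeParams(
        model="JC69",
        root_vector=np.array([Fraction(1, 4)] * 4, dtype=object),
        edge_matrices={v: mat.copy() for v in range(1, 4)},
    )
    p_fast = parametrize(star3, params)
    p_slow = parametrize(star3, params, method="brute")
    assert (p_fast == p_slow).all()
    assert tensor_sum(p_fast) == 1


def test_parametrize_linear_in_root_vector(quartet, rng):
    params = sample_params("SSM", quartet, rng, stochastic=False)
    p = parametrize(quartet, params)
    scaled = TreeParams(
        model=params.model,
        root_vector=3.0 * params.root_vector,
        edge_matrices=params.edge_matrices,
        stochastic=False,
    )
    assert np.allclose(parametrize(quartet, scaled), 3.0 * p)
    assert tensor_sum(scaled.root_vector) == pytest.approx(3 * tensor_sum(params.root_vector))


def test_mismatched_params_rejected(quartet, star3):
    params = sample_params("K81", quartet, 0)
    with pytest.raises(ValueError):
        parametrize(star3, params)


@pytest.mark.parametrize("model", MODEL_NAMES)
def test_tree_tensors_satisfy_model_equations(model, rng):
    """Any equivariant stochastic draw on any tree lies in the model's linear
    mixture space: every generated equation holds to float precision."""
    for n in (3, 4):
        tree = random_trivalent_tree(n, rng)
        params = sample_params(model, tree, rng)
        p = parametrize(tree, params)
        assert max_equation_residual(p, model, n) < 1e-10


def test_contraction_of_identity_interior_edge():
    """Setting an interior edge to the identity reproduces the tensor of the
    contracted star-like tree with the same remaining parameters."""
    # quartet ((1,2),(3,4)): node 1 = cherry (1,2), node 4 = cherry (3,4)
    quartet = Tree(
        children=[[1, 4], [2, 3], [], [], [5, 6], [], []],
        leaf_labels={2: 1, 3: 2, 5: 3, 6: 4},
    )
    params = sample_params("K81", quartet, 42)
    params.edge_matrices[1] = np.eye(4)  # contract the edge above cherry (1,2)
    p = parametrize(quartet, params)
    # contracted tree (1,2,(3,4)): leaves 1,2 hang off the root directly
    star = Tree(
        children=[[1, 2, 3], [], [], [4, 5], [], []],
        leaf_labels={1: 1, 2: 2, 4: 3, 5: 4},
    )
    m = params.edge_matrices
    star_params = TreeParams(
        model="K81",
        root_vector=params.root_vector,
        edge_matrices={1: m[2], 2: m[3], 3: m[4], 4: m[5], 5: m[6]},
    )
    assert np.allclose(parametrize(star, star_params), p, atol=1e-12)


def test_reroot_preserves_tensor(rng):
    """Transporting the process to any other interior root leaves the joint
    leaf distribution unchanged (root-position independence)."""
    for model in ("JC69", "K80", "SSM", "GMM"):
        tree = random_trivalent_tree(5, rng)
        params = sample_params(model, tree, rng)
        p = parametrize(tree, params)
        for v in tree.interior_nodes():
            t2, p2 = reroot(tree, params, v)
            assert np.allclose(parametrize(t2, p2), p, atol=1e-10)
            assert max_equation_residual(parametrize(t2, p2), model, 5) < 1e-10


# -- mixtures ----------------------------------------------------------------


def test_single_component_mixture_equals_parametrize(quartet):
    params = sample_params("K80", quartet, 3)
    spec = MixtureSpec([(quartet, params, 1.0)])
    assert np.array_equal(mix(spec), parametrize(quartet, params))


def test_equal_weight_duplicate_components_collapse(quartet):
    params = sample_params("SSM", quartet, 9)
    spec = MixtureSpec([(quartet, params, 0.5), (quartet, params, 0.5)])
    assert np.allclose(mix(spec), parametrize(quartet, params))


def test_three_topology_k81_mixture_stays_in_space(rng):
    trees = trivalent_topologies(4)
    comps = [(t, sample_params("K81", t, rng), w) for t, w in zip(trees, (0.5, 0.3, 0.2))]
    p = mix(MixtureSpec(comps))
    assert p.sum() == pytest.approx(1.0)
    assert max_equation_residual(p, "K81", 4) < 1e-10


def test_mixture_validation():
    t4 = Tree.from_newick("((1,2),(3,4));")
    t3 = Tree.from_newick("(1,2,3);")
    with pytest.raises(ValueError, match="taxa"):
        MixtureSpec([(t4, sample_params("K81", t4, 0), 0.5),
                     (t3, sample_params("K81", t3, 0), 0.5)])
    with pytest.raises(ValueError, match="sum"):
        MixtureSpec([(t4, sample_params("K81", t4, 0), 0.7),
                     (t4, sample_params("K81", t4, 1), 0.7)])


# -- orbit tensors and their realization -------------------------------------


@pytest.mark.parametrize(
    "word, model, support_value",
    [("AAA", "GMM", 1), ("AAA", "K81", 1), ("AAA", "JC69", 6), ("AAA", "SSM", 1)],
)
def test_tau_orbit_tensor_stabiliser_multiplicity(word, model, support_value):
    tau = tau_orbit_tensor(word, model, exact=True)
    G = model_group(model)
    assert tensor_sum(tau) == G.order
    support = {w for w in all_words(3) if tau[word_to_index(w)] != 0}
    assert all(tau[word_to_index(w)] == support_value for w in support)


def test_tau_tensors_of_distinct_orbits_are_independent():
    """One tau per orbit: supports are disjoint, so they are linearly
    independent and there are exactly dim L^G of them."""
    seen: set[int] = set()
    count = 0
    for w in all_words(3):
        tau = tau_orbit_tensor(w, "K80", exact=True)
        support = frozenset(int(i) for i in np.nonzero(tau != 0)[0])
        if min(support) in seen:
            continue
        assert not (seen & support)
        seen |= support
        count += 1
    assert count == 10  # dim L^K80 at n = 3


@pytest.mark.parametrize("model", ["K81", "SSM", "GMM"])
def test_prop13_realizes_orbit_tensor_exactly(model):
    """For every word up to length 4, the two-level tree construction
    reproduces tau{Y}_G exactly in rational arithmetic (including the
    degenerate single-letter words)."""
    for n in (2, 3, 4):
        for word in all_words(n):
            tree, params = prop13_construction(word, model)
            assert (parametrize(tree, params) == tau_orbit_tensor(word, model, exact=True)).all()


@pytest.mark.parametrize("model", ["K81", "SSM", "GMM"])
def test_prop13_sampled_words_n5(model, rng):
    words5 = ["".join(rng.choice(list("ACGT"), 5)) for _ in range(8)]
    for word in words5:
        tree, params = prop13_construction(word, model)
        assert (parametrize(tree, params) == tau_orbit_tensor(word, model, exact=True)).all()


@pytest.mark.parametrize("model", ["K80", "JC69"])
def test_prop13_rejects_models_without_free_letter(model):
    with pytest.raises(UnsupportedModelError, match="stabiliser"):
        prop13_construction("ACGT", model)
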