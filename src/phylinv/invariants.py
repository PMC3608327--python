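"""Dimensions and minimal linear equation systems of equivariant mixture spaces.

For each of the five models the space of phylogenetic mixtures on ``n`` taxa is
the linear span ``L^G`` of the G-invariant pattern tensors, regardless of tree
topology.  Its dimension equals the number of G-orbits on length-``n`` words
(Burnside / trivial-character multiplicity), and it is cut out by a minimal
system of coordinate equalities ``p_X = p_{gX}`` built in nested stages:

* SSM stage:  g = (AT)(CG), X ranging over all words with first letter A or C;
* K81 stage:  g = (AC)(GT), X ranging over all words with first letter A;
* K80 stage:  g = (AG), X with first letter A, X outside {A,G}^n ∪ {C,T}^n,
  and the first letter of X drawn from {C,T} being a C;
* JC69 stage: g = (AT) for words over {A,C} starting with A and containing a C;
  plus g = (AC) and g = (AT) for each word whose letters in order of first
  appearance read A, C, G (then T if present).

Each stage adds exactly one independent equation per orbit newly merged at
that stage, so the total count equals the codimension ``4**n - dim L^G`` and
the system is minimal.  All verification here is exact (integer/rational).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Sequence

import numpy as np

from .wordspace import (
    ALPHABET,
    MODEL_NAMES,
    Permutation,
    all_words,
    apply,
    character,
    conjugacy_classes,
    model_group,
    orbit_count_burnside,
    word_to_index,
)

# nested chain, smallest space (most equations) last
_LAYER_ORDER = ("SSM", "K81", "K80", "JC69")


def _validate_model(model: str) -> None:
    if model not in MODEL_NAMES:
        raise ValueError(
            f"unknown model {model!r}; valid names are {', '.join(MODEL_NAMES)}"
        )


def dimension_character(model: str, n: int) -> int:
    """dim L^G via conjugacy classes: ``(1/|G|) * sum_i |C_i| * chi(g_i)**n``."""
    _validate_model(model)
    if n < 1:
        raise ValueError("n must be >= 1")
    G = model_group(model)
    total = Fraction(0)
    for rep, size in conjugacy_classes(G):
        total += size * Fraction(character(rep)) ** n
    value = total / G.order
    assert value.denominator == 1
    return int(value)


def dimension_closed_form(model: str, n: int) -> int:
    """dim L^G by the printed closed forms (must match the character route):

    GMM: 4^n;  SSM: 2^(2n-1);  K81: 4^(n-1);  K80: 2^(2n-3) + 2^(n-2);
    JC69: (2^(2n-3) + 1)/3 + 2^(n-2).
    """
    _validate_model(model)
    if n < 1:
        raise ValueError("n must be >= 1")
    two = Fraction(2)
    if model == "GMM":
        value = Fraction(4) ** n
    elif model == "SSM":
        value = two ** (2 * n - 1)
    elif model == "K81":
        value = Fraction(4) ** (n - 1)
    elif model == "K80":
        value = two ** (2 * n - 3) + two ** (n - 2)
    else:  # JC69
        value = (two ** (2 * n - 3) + 1) / 3 + two ** (n - 2)
    assert value.denominator == 1
    return int(value)


@dataclass(frozen=True)
class SpaceInfo:
    """Dimension bookkeeping for one mixture space ``L^G``."""

    model: str
    n: int
    dim: int
    codim: int

    def to_dict(self) -> dict:
        return {"model": self.model, "n": self.n, "dim": self.dim, "codim": self.codim}


def space_info(model: str, n: int) -> SpaceInfo:
    dim = dimension_closed_form(model, n)
    assert dim == dimension_character(model, n)
    return SpaceInfo(model=model, n=n, dim=dim, codim=4**n - dim)


@dataclass(frozen=True)
class WordClass:
    """Membership flags of a word in the special word families:

    ``b0`` — single-letter words; ``ac_gt`` — {A,C}^n ∪ {G,T}^n (and the two
    analogous pair families); ``b2`` — union of the three pair families,
    i.e. words using at most two distinct letters.
    """

    b0: bool
    ac_gt: bool
    ag_ct: bool
    at_cg: bool
    b2: bool


def word_class(word: str) -> WordClass:
    letters = set(word)
    if not letters or not letters <= set(ALPHABET):
        raise ValueError(f"not a word over ACGT: {word!r}")
    ac_gt = letters <= {"A", "C"} or letters <= {"G", "T"}
    ag_ct = letters <= {"A", "G"} or letters <= {"C", "T"}
    at_cg = letters <= {"A", "T"} or letters <= {"C", "G"}
    return WordClass(
        b0=len(letters) == 1,
        ac_gt=ac_gt,
        ag_ct=ag_ct,
        at_cg=at_cg,
        b2=ac_gt or ag_ct or at_cg,
    )


@dataclass(frozen=True)
class Equation:
    """One coordinate equality ``p_left = p_right`` (a +1/-1 row)."""

    left: str
    right: str
    layer: str

    def __post_init__(self):
        if self.left == self.right or len(self.left) != len(self.right):
            raise ValueError(f"invalid equation {self.left} = {self.right}")

    @property
    def as_text(self) -> str:
        return f"p{self.left}=p{self.right}"

    @property
    def left_index(self) -> int:
        return word_to_index(self.left)

    @property
    def right_index(self) -> int:
        return word_to_index(self.right)


@dataclass(frozen=True)
class EquationSet:
    """A minimal independent system of equations for one model and taxa count.

    Stages are nested: the SSM layer is a prefix of K81's system, K81's of
    K80's, and K80's of JC69's; GMM has no equations at all.
    """

    model: str
    n: int
    equations: tuple[Equation, ...]

    @property
    def info(self) -> SpaceInfo:
        return space_info(self.model, self.n)

    def layer_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for eq in self.equations:
            counts[eq.layer] = counts.get(eq.layer, 0) + 1
        return counts

    def layer(self, name: str) -> tuple[Equation, ...]:
        return tuple(eq for eq in self.equations if eq.layer == name)

    def __len__(self) -> int:
        return len(self.equations)

    def __iter__(self):
        return iter(self.equations)

    def index_pairs(self) -> np.ndarray:
        """(m, 2) integer array of (left, right) coordinate indices."""
        return np.array(
            [(eq.left_index, eq.right_index) for eq in self.equations], dtype=np.int64
        ).reshape(-1, 2)

    # -- export -------------------------------------------------------------

    def to_text(self) -> str:
        return "\n".join(eq.as_text for eq in self.equations)

    def to_tsv(self) -> str:
        lines = ["layer\tleft_word\tright_word\tleft_index\tright_index"]
        for eq in self.equations:
            lines.append(
                f"{eq.layer}\t{eq.left}\t{eq.right}\t{eq.left_index}\t{eq.right_index}"
            )
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "space": self.info.to_dict(),
                "n_equations": len(self.equations),
                "equations": [
                    {"layer": eq.layer, "left": eq.left, "right": eq.right}
                    for eq in self.equations
                ],
            },
            indent=2,
        )


def _first_appearance(word: str) -> str:
    seen: list[str] = []
    for c in word:
        if c not in seen:
            seen.append(c)
    return "".join(seen)


def _ssm_layer(n: int) -> list[Equation]:
    g = Permutation.from_cycles("(AT)(CG)")
    return [
        Equation(w, apply(g, w), "SSM") for w in all_words(n) if w[0] in ("A", "C")
    ]


def _k81_layer(n: int) -> list[Equation]:
    g = Permutation.from_cycles("(AC)(GT)")
    return [Equation(w, apply(g, w), "K81") for w in all_words(n) if w[0] == "A"]


def _k80_layer(n: int) -> list[Equation]:
    g = Permutation.from_cycles("(AG)")
    out = []
    for w in all_words(n):
        if w[0] != "A" or word_class(w).ag_ct:
            continue
        first_ct = next(c for c in w if c in ("C", "T"))
        if first_ct == "C":
            out.append(Equation(w, apply(g, w), "K80"))
    return out


def _jc69_layer(n: int) -> list[Equation]:
    g_ac = Permutation.from_cycles("(AC)")
    g_at = Permutation.from_cycles("(AT)")
    out = []
    for w in all_words(n):
        letters = set(w)
        if letters <= {"A", "C"} and w[0] == "A" and "C" in w:
            # words A^l C^m ... over {A,C}: merge with the (AT)-image orbit
            out.append(Equation(w, apply(g_at, w), "JC69"))
        elif _first_appearance(w) in ("ACG", "ACGT"):
            # >= 3 distinct letters, canonical representative of its orbit
            out.append(Equation(w, apply(g_ac, w), "JC69"))
            out.append(Equation(w, apply(g_at, w), "JC69"))
    return out


_LAYER_BUILDERS = {
    "SSM": _ssm_layer,
    "K81": _k81_layer,
    "K80": _k80_layer,
    "JC69": _jc69_layer,
}


@lru_cache(maxsize=64)
def equations(model: str, n: int) -> EquationSet:
    """The minimal nested equation system ``E_M`` for ``model`` on ``n`` taxa.

    GMM yields the empty system (the whole tensor space).  For the other
    models the layers accumulate along SSM -> K81 -> K80 -> JC69, each stage
    adding one equation per orbit newly merged at that stage.
    """
    _validate_model(model)
    if n < 2:
        raise ValueError("equation systems require n >= 2")
    eqs: list[Equation] = []
    if model != "GMM":
        for layer in _LAYER_ORDER:
            eqs.extend(_LAYER_BUILDERS[layer](n))
            if layer == model:
                break
    return EquationSet(model=model, n=n, equations=tuple(eqs))


# -- orbit machinery on coordinate indices ----------------------------------


@lru_cache(maxsize=64)
def _orbit_rep_array(model: str, n: int) -> np.ndarray:
    """For each coordinate index, the least index in its G-orbit."""
    G = model_group(model)
    size = 4**n
    digits = np.empty((size, n), dtype=np.int64)
    idx = np.arange(size)
    for pos in range(n - 1, -1, -1):
        digits[:, pos] = idx % 4
        idx = idx // 4
    powers = 4 ** np.arange(n - 1, -1, -1, dtype=np.int64)
    rep = np.arange(size, dtype=np.int64)
    for g in G:
        mapped = np.asarray(g.mapping, dtype=np.int64)[digits] @ powers
        np.minimum(rep, mapped, out=rep)
    return rep


def count_orbits(model: str, n: int) -> int:
    """Number of G-orbits on length-``n`` words by explicit enumeration
    (independent of the Burnside/character route)."""
    return int(np.unique(_orbit_rep_array(model, n)).size)


def project(p: Sequence, model: str):
    """Orthogonal projection onto ``L^G``: replace each coordinate by the mean
    over its G-orbit.  Idempotent; the output satisfies every model equation
    exactly.  Accepts float arrays (returns ``np.ndarray``) or exact rational
    sequences (returns a list of :class:`~fractions.Fraction`).
    """
    _validate_model(model)
    size = len(p)
    n = 0
    while 4**n < size:
        n += 1
    if 4**n != size or size < 4:
        raise ValueError(f"tensor length {size} is not a power of 4")
    rep = _orbit_rep_array(model, n)
    arr = np.asarray(p)
    if arr.dtype == object:
        sums: dict[int, Fraction] = {}
        counts: dict[int, int] = {}
        for i, r in enumerate(rep):
            sums[int(r)] = sums.get(int(r), 0) + p[i]
            counts[int(r)] = counts.get(int(r), 0) + 1
        means = {r: Fraction(s) / counts[r] for r, s in sums.items()}
        return [means[int(r)] for r in rep]
    arr = arr.astype(float)
    sums = np.zeros(size)
    counts = np.zeros(size)
    np.add.at(sums, rep, arr)
    np.add.at(counts, rep, 1.0)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return means[rep]


# -- verification ------------------------------------------------------------


@dataclass(frozen=True)
class VerificationReport:
    """Outcome of the exact soundness/completeness check of an equation set."""

    sound: bool
    complete: bool
    rank: int
    expected_rank: int
    violations: tuple[Equation, ...]


def _exact_rank(eqs: EquationSet) -> int:
    """Exact rank over Q of the +1/-1 constraint system.

    Each equation couples exactly two coordinates, so the system is the
    incidence system of a graph on the 4**n coordinates and its rank is
    (number of vertices touched) - (number of connected components touched),
    computed by union-find.  Exact; no tolerances involved.
    """
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    rank = 0
    for eq in eqs:
        a, b = eq.left_index, eq.right_index
        for v in (a, b):
            if v not in parent:
                parent[v] = v
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            rank += 1
    return rank


def verify_equation_set(eqs: EquationSet) -> VerificationReport:
    """Exact check that an equation system is sound and complete for its model.

    Soundness: every equation annihilates every orbit-indicator tensor of the
    model's group, i.e. each equation's two words lie in a common G-orbit.
    Completeness: the exact rank of the system equals ``4**n - dim L^G``.
    A failed check is reported, not raised.
    """
    rep = _orbit_rep_array(eqs.model, eqs.n)
    violations = tuple(
        eq for eq in eqs if rep[eq.left_index] != rep[eq.right_index]
    )
    rank = _exact_rank(eqs)
    expected = 4**eqs.n - dimension_character(eqs.model, eqs.n)
    return VerificationReport(
        sound=not violations,
        complete=rank == expected,
        rank=rank,
        expected_rank=expected,
        violations=violations,
    )


def expected_layer_count(layer: str, n: int) -> int:
    """Closed-form number of equations each nested stage adds."""
    two = Fraction(2)
    if layer == "SSM":
        value = two ** (2 * n - 1)
    elif layer == "K81":
        value = Fraction(4) ** (n - 1)
    elif layer == "K80":
        value = two ** (2 * n - 3) - two ** (n - 2)
    elif layer == "JC69":
        value = (two ** (n - 1) - 1) + 2 * ((two ** (2 * n - 3) + 1) / 3 - two ** (n - 2))
    else:
        raise ValueError(f"unknown layer {layer!r}")
    assert value.denominator == 1
    return int(value)


def orbit_count_check(model: str, n: int) -> bool:
    """Cross-validate Burnside counting against explicit enumeration."""
    return orbit_count_burnside(model_group(model), n) == count_orbits(model, n)
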