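"""Alphabet, words, and nucleotide-permutation groups.

The five classical equivariant substitution models are each determined by a
permutation group acting on the nucleotide alphabet ``{A, C, G, T}``:

========  =====================================  =====
model     group                                  order
========  =====================================  =====
JC69      the full symmetric group S4              24
K80       ⟨(ACGT), (AG)⟩ (dihedral)                 8
K81       ⟨(AC)(GT), (AG)(CT)⟩ (Klein four)         4
SSM       ⟨(AT)(CG)⟩ (strand complementation)       2
GMM       ⟨e⟩ (trivial)                             1
========  =====================================  =====

A transition matrix belongs to a model iff it commutes with every permutation
matrix of the model's group; the linear space of mixture distributions is cut
out by coordinate equalities indexed by group orbits on site patterns (words).
This module provides the word/index machinery and the exhaustive group
operations (orbits, stabilisers, characters, conjugacy classes) that every
other module builds on.

Words are strings over ``ACGT``; the coordinate index of a word is big-endian
in leaf order (leaf 1 most significant), so the 4**n coordinates are listed
``p_{A...A}, p_{A...C}, ..., p_{T...T}``.
"""

from __future__ import annotations

import itertools
import re
from functools import lru_cache
from typing import Iterable, Iterator

ALPHABET = "ACGT"
_LETTER_TO_DIGIT = {c: i for i, c in enumerate(ALPHABET)}

#: The five supported model names, from smallest to largest mixture space.
MODEL_NAMES = ("JC69", "K80", "K81", "SSM", "GMM")

#: Printed generators of each model's symmetry group.
MODEL_GENERATORS = {
    "JC69": ("(AC)", "(ACGT)"),  # generates all of S4
    "K80": ("(ACGT)", "(AG)"),
    "K81": ("(AC)(GT)", "(AG)(CT)"),
    "SSM": ("(AT)(CG)",),
    "GMM": (),
}


def letter_digit(letter: str) -> int:
    """Digit value 0-3 of a letter under the fixed order A < C < G < T."""
    try:
        return _LETTER_TO_DIGIT[letter]
    except KeyError:
        raise ValueError(f"not a nucleotide letter: {letter!r}") from None


def word_to_index(word: str) -> int:
    """Big-endian coordinate index of a word (leaf 1 most significant)."""
    idx = 0
    for c in word:
        idx = 4 * idx + letter_digit(c)
    return idx


def index_to_word(index: int, n: int) -> str:
    """Inverse of :func:`word_to_index` for words of length ``n``."""
    if not 0 <= index < 4**n:
        raise ValueError(f"index {index} out of range for n={n}")
    letters = []
    for _ in range(n):
        index, d = divmod(index, 4)
        letters.append(ALPHABET[d])
    return "".join(reversed(letters))


def all_words(n: int) -> Iterator[str]:
    """All length-``n`` words in index order."""
    for tup in itertools.product(ALPHABET, repeat=n):
        yield "".join(tup)


_CYCLE_RE = re.compile(r"\(([ACGT]*)\)")


class Permutation:
    """A permutation of the four nucleotide letters.

    Stored as an explicit 4-entry mapping ``mapping[i] = image digit of
    letter i``; constructed from cycle notation such as ``"(ACGT)"`` or
    ``"(AC)(GT)"`` (``"e"`` denotes the identity).
    """

    __slots__ = ("mapping",)

    def __init__(self, mapping: Iterable[int]):
        mapping = tuple(mapping)
        if sorted(mapping) != [0, 1, 2, 3]:
            raise ValueError(f"not a bijection of 4 letters: {mapping}")
        object.__setattr__(self, "mapping", mapping)

    def __setattr__(self, name, value):  # immutability guard
        raise AttributeError("Permutation is immutable")

    @classmethod
    def identity(cls) -> "Permutation":
        return cls((0, 1, 2, 3))

    @classmethod
    def from_cycles(cls, text: str) -> "Permutation":
        """Parse cycle notation: ``"(ACGT)"``, ``"(AC)(GT)"``, ``"e"``, ``"()"``."""
        s = text.strip().replace(" ", "")
        if s in ("", "e", "()"):
            return cls.identity()
        if not re.fullmatch(r"(\([ACGT]*\))+", s):
            raise ValueError(f"malformed cycle notation: {text!r}")
        mapping = list(range(4))
        seen: set[int] = set()
        for cycle in _CYCLE_RE.findall(s):
            digits = [letter_digit(c) for c in cycle]
            if len(set(digits)) != len(digits):
                raise ValueError(f"repeated letter within a cycle: {text!r}")
            if seen & set(digits):
                raise ValueError(f"cycles are not disjoint: {text!r}")
            seen.update(digits)
            for i, d in enumerate(digits):
                mapping[d] = digits[(i + 1) % len(digits)]
        return cls(mapping)

    def __call__(self, letter: str) -> str:
        """Image of a single letter."""
        return ALPHABET[self.mapping[letter_digit(letter)]]

    def apply_digit(self, d: int) -> int:
        return self.mapping[d]

    def __mul__(self, other: "Permutation") -> "Permutation":
        """Composition ``self ∘ other`` (apply ``other`` first)."""
        return Permutation(self.mapping[d] for d in other.mapping)

    def inverse(self) -> "Permutation":
        inv = [0] * 4
        for i, j in enumerate(self.mapping):
            inv[j] = i
        return Permutation(inv)

    def order(self) -> int:
        g, k = self, 1
        while g.mapping != (0, 1, 2, 3):
            g, k = g * self, k + 1
        return k

    @property
    def cycle_text(self) -> str:
        """Canonical cycle notation (each cycle starts at its least letter,
        cycles sorted by first letter; identity renders as ``"e"``)."""
        cycles = []
        done: set[int] = set()
        for start in range(4):
            if start in done:
                continue
            cyc = [start]
            done.add(start)
            nxt = self.mapping[start]
            while nxt != start:
                cyc.append(nxt)
                done.add(nxt)
                nxt = self.mapping[nxt]
            if len(cyc) > 1:
                cycles.append(cyc)
        if not cycles:
            return "e"
        return "".join("(" + "".join(ALPHABET[d] for d in c) + ")" for c in cycles)

    def __eq__(self, other) -> bool:
        return isinstance(other, Permutation) and self.mapping == other.mapping

    def __hash__(self) -> int:
        return hash(self.mapping)

    def __repr__(self) -> str:
        return f"Permutation({self.cycle_text!r})"


def apply(g: Permutation, word: str) -> str:
    """Letterwise action of a permutation on a word."""
    return "".join(ALPHABET[g.mapping[letter_digit(c)]] for c in word)


def character(g: Permutation) -> int:
    """Number of letters fixed by ``g`` — the trace of its permutation matrix."""
    return sum(1 for i, j in enumerate(g.mapping) if i == j)


class PermGroup:
    """A permutation group on the nucleotide alphabet, materialized as an
    explicit element set (at most 24 elements)."""

    def __init__(self, name: str, generators: Iterable[Permutation]):
        self.name = name
        self.generators = tuple(generators)
        self.elements = self._closure(self.generators)

    @staticmethod
    def _closure(gens: tuple[Permutation, ...]) -> tuple[Permutation, ...]:
        elems = {Permutation.identity()}
        frontier = list(elems)
        while frontier:
            nxt = []
            for h in frontier:
                for g in gens:
                    prod = g * h
                    if prod not in elems:
                        elems.add(prod)
                        nxt.append(prod)
            frontier = nxt
        return tuple(sorted(elems, key=lambda p: p.mapping))

    @property
    def order(self) -> int:
        return len(self.elements)

    def __iter__(self) -> Iterator[Permutation]:
        return iter(self.elements)

    def __contains__(self, g: Permutation) -> bool:
        return g in set(self.elements)

    def __len__(self) -> int:
        return len(self.elements)

    def __repr__(self) -> str:
        return f"PermGroup({self.name!r}, order={self.order})"


@lru_cache(maxsize=None)
def model_group(model_name: str) -> PermGroup:
    """The symmetry group of one of the five equivariant models.

    Returns the closure of the model's printed generators: S4 for JC69,
    ⟨(ACGT),(AG)⟩ for K80, ⟨(AC)(GT),(AG)(CT)⟩ for K81, ⟨(AT)(CG)⟩ for SSM and
    the trivial group for GMM.
    """
    if model_name not in MODEL_NAMES:
        raise ValueError(
            f"unknown model {model_name!r}; valid names are {', '.join(MODEL_NAMES)}"
        )
    gens = [Permutation.from_cycles(t) for t in MODEL_GENERATORS[model_name]]
    return PermGroup(model_name, gens)


def orbit(word: str, G: PermGroup) -> frozenset[str]:
    """The set of images ``{gX : g in G}`` of a word; its size divides |G|."""
    return frozenset(apply(g, word) for g in G)


def stabiliser(letter: str, G: PermGroup) -> frozenset[Permutation]:
    """The subgroup of ``G`` fixing one letter."""
    letter_digit(letter)  # validate
    return frozenset(g for g in G if g(letter) == letter)


def conjugacy_classes(G: PermGroup) -> list[tuple[Permutation, int]]:
    """Conjugacy classes ``C(g) = {h^-1 g h : h in G}`` as
    ``(representative, class size)`` pairs; sizes sum to |G| and the character
    is constant on each class."""
    remaining = set(G.elements)
    classes = []
    # deterministic order: identity first, then by moved-letter count / mapping
    key = lambda p: (4 - character(p), p.mapping)
    while remaining:
        g = min(remaining, key=key)
        cls = {h.inverse() * g * h for h in G}
        remaining -= cls
        classes.append((g, len(cls)))
    return classes


def orbit_count_burnside(G: PermGroup, n: int) -> int:
    """Number of G-orbits on length-``n`` words, by Burnside's lemma:
    ``(1/|G|) * sum_g chi(g)**n``."""
    total = sum(character(g) ** n for g in G)
    q, r = divmod(total, G.order)
    assert r == 0, "Burnside sum must be divisible by the group order"
    return q
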