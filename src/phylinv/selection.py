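"""Alignment-driven model-fit scoring against equivariant mixture spaces.

Because the mixture space of each model is linear and cut out by coordinate
equalities on the pattern-frequency tensor, an alignment can be scored against
a model purely geometrically: count site patterns, normalize to a frequency
tensor, and measure how far the tensor is from satisfying the model's
equations.  Exact membership means the data are consistent with *some* mixture
of trees under that model (any topologies, any number of classes); sampling
noise makes the residuals of the generating model small but nonzero.

The scores are geometric residuals only — no statistical calibration,
p-values or information criteria are produced, and a small residual is
evidence of consistency with the model class, not an inference of a tree.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .invariants import equations, project, space_info
from .tree_model import MixtureSpec, mix
from .wordspace import ALPHABET, MODEL_NAMES, word_to_index

#: nesting order, largest space first: L^JC69 ⊆ L^K80 ⊆ L^K81 ⊆ L^SSM ⊆ L^GMM
NESTING = ("GMM", "SSM", "K81", "K80", "JC69")


@dataclass
class PatternCounts:
    """Site-pattern counts from an alignment.

    Columns containing any character outside A/C/G/T (after uppercasing and
    mapping U to T) are discarded whole and tallied in ``discarded_sites``.
    """

    n: int
    counts: dict[str, int]
    total_sites: int
    discarded_sites: int


def _open_source(source):
    if hasattr(source, "read"):
        return source, False
    return open(os.fspath(source)), True


def read_alignment(source, by_name: bool = False) -> PatternCounts:
    """Count column patterns of a FASTA alignment.

    ``source`` is a path or an open text handle.  Sequences map to leaves in
    file order (record i ↔ leaf i) unless ``by_name`` is set, in which case
    records are sorted by name first.  Requires at least two sequences of
    equal length.
    """
    handle, close = _open_source(source)
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if close:
            handle.close()
    if len(records) < 2:
        raise ValueError(f"alignment needs at least 2 sequences, got {len(records)}")
    if by_name:
        records.sort(key=lambda r: r.id)
    seqs = [str(r.seq).upper().replace("U", "T") for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    (length,) = lengths
    valid = set(ALPHABET)
    counts: dict[str, int] = {}
    discarded = 0
    for j in range(length):
        column = "".join(s[j] for s in seqs)
        if set(column) <= valid:
            counts[column] = counts.get(column, 0) + 1
        else:
            discarded += 1
    return PatternCounts(
        n=len(seqs),
        counts=counts,
        total_sites=length - discarded,
        discarded_sites=discarded,
    )


def empirical_tensor(counts: PatternCounts) -> np.ndarray:
    """Relative pattern frequencies as a 4**n tensor (coordinates sum to 1)."""
    if counts.total_sites <= 0:
        raise ValueError("no usable sites in the alignment")
    p = np.zeros(4**counts.n)
    for word, c in counts.counts.items():
        p[word_to_index(word)] = c
    return p / counts.total_sites


@dataclass
class ModelScore:
    """Geometric fit of one tensor against one model's mixture space."""

    model: str
    dim: int
    n_equations: int
    max_residual: float
    l2_residual: float
    projection_distance: float

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "dim": self.dim,
            "n_equations": self.n_equations,
            "max_residual": self.max_residual,
            "l2_residual": self.l2_residual,
            "projection_distance": self.projection_distance,
        }


def _infer_n(p: np.ndarray) -> int:
    n = 0
    while 4**n < p.size:
        n += 1
    if 4**n != p.size:
        raise ValueError(f"tensor length {p.size} is not a power of 4")
    return n


def score(p: np.ndarray, model: str) -> ModelScore:
    """Evaluate every model equation on a normalized tensor.

    Reports the largest single-equation residual ``max |p_X - p_Y|``, the
    root-sum-square of all residuals, and the Euclidean distance to the
    orthogonal projection onto the model's space.  All three vanish iff the
    tensor lies in the space.
    """
    p = np.asarray(p, dtype=float)
    n = _infer_n(p)
    total = p.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"tensor is not normalized (sum {total})")
    info = space_info(model, n)
    if model == "GMM":
        return ModelScore(model, info.dim, 0, 0.0, 0.0, 0.0)
    eqs = equations(model, n)
    pairs = eqs.index_pairs()
    resid = np.abs(p[pairs[:, 0]] - p[pairs[:, 1]])
    proj = project(p, model)
    return ModelScore(
        model=model,
        dim=info.dim,
        n_equations=len(eqs),
        max_residual=float(resid.max(initial=0.0)),
        l2_residual=float(np.sqrt((resid**2).sum())),
        projection_distance=float(np.linalg.norm(p - proj)),
    )


@dataclass
class FitReport:
    """Scores of one tensor against all five model spaces.

    ``ranking`` lists models from best fit (smallest projection distance) to
    worst; since the spaces are nested, the distances are non-decreasing from
    GMM toward JC69 for every input, so the ranking mostly reflects how far
    down the nesting chain the tensor remains consistent.
    """

    n: int
    scores: dict[str, ModelScore]
    ranking: list[str]
    note: str = (
        "Scores are geometric residuals of the linear invariant systems; no "
        "statistical calibration is applied. Model spaces are nested "
        "JC69 within K80 within K81 within SSM within GMM."
    )

    def summary(self) -> str:
        lines = [
            f"{'model':<6} {'dim':>8} {'n_eq':>8} {'max_resid':>12} "
            f"{'l2_resid':>12} {'proj_dist':>12}"
        ]
        for m in NESTING:
            s = self.scores[m]
            lines.append(
                f"{m:<6} {s.dim:>8} {s.n_equations:>8} {s.max_residual:>12.3e} "
                f"{s.l2_residual:>12.3e} {s.projection_distance:>12.3e}"
            )
        lines.append("ranking (best fit first): " + " > ".join(self.ranking))
        lines.append(self.note)
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "scores": {m: s.to_dict() for m, s in self.scores.items()},
                "ranking": self.ranking,
                "note": self.note,
            },
            indent=2,
        )


def fit_all(p: np.ndarray) -> FitReport:
    """Score a normalized tensor against all five models."""
    p = np.asarray(p, dtype=float)
    n = _infer_n(p)
    scores = {m: score(p, m) for m in MODEL_NAMES}
    ranking = sorted(
        NESTING, key=lambda m: (scores[m].projection_distance, NESTING.index(m))
    )
    return FitReport(n=n, scores=scores, ranking=ranking)


def simulate_alignment(spec: MixtureSpec, sites: int, seed) -> str:
    """Simulate a FASTA alignment by i.i.d. multinomial sampling of site
    columns from a mixture tensor; deterministic given the seed."""
    if sites < 0:
        raise ValueError("sites must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.asarray(mix(spec), dtype=float)
    if p.min() < -1e-12:
        raise ValueError(
            f"mixture tensor has negative coordinates (min {p.min()}); "
            "only stochastic mixtures can be sampled"
        )
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    n = spec.n
    if sites == 0:
        columns = np.empty(0, dtype=np.int64)
    else:
        columns = rng.choice(p.size, size=sites, p=p)
    # decode column indices into one sequence per leaf
    digits = np.empty((sites, n), dtype=np.int64)
    rem = columns.copy()
    for pos in range(n - 1, -1, -1):
        digits[:, pos] = rem % 4
        rem //= 4
    letters = np.array(list(ALPHABET))
    out = io.StringIO()
    for leaf in range(n):
        seq = "".join(letters[digits[:, leaf]])
        out.write(f">{leaf + 1}\n")
        for start in range(0, max(len(seq), 1), 60):
            out.write(seq[start : start + 60] + "\n")
    return out.getvalue()
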