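"""Mixture identifiability bounds for the equivariant models.

For a model whose continuous parameters are generically identifiable on
unmixed trivalent trees, an h-class mixture on n taxa has at most
``edim(h) = h*s(n) + h - 1`` degrees of freedom, where ``s(n)`` is the
parameter count of the model on one trivalent tree (2n-3 edges).  Once
``edim(h)`` reaches the dimension of the full mixture space the parameter
count exceeds the data, and neither the tree topologies nor the continuous
parameters can be recovered.  The crossover is

    h0(n) = dim(D_M) / (s(n) + 1),

kept here as an exact rational; mixtures with ``h >= h0(n)`` classes are not
identifiable.  This is a negative bound only: nothing is claimed below the
threshold (identifiability there is open in general).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from fractions import Fraction

from .invariants import dimension_character
from .wordspace import MODEL_NAMES

#: per-edge free stochastic parameters and root degrees of freedom
_EDGE_DOF = {"GMM": 12, "SSM": 6, "K81": 3, "K80": 2, "JC69": 1}
_ROOT_DOF = {"GMM": 3, "SSM": 1, "K81": 0, "K80": 0, "JC69": 0}


def _validate(model: str, n: int) -> None:
    if model not in MODEL_NAMES:
        raise ValueError(
            f"unknown model {model!r}; valid names are {', '.join(MODEL_NAMES)}"
        )
    if n < 3:
        raise ValueError("identifiability bounds require n >= 3 (trivalent trees)")


def param_count(model: str, n: int) -> int:
    """Free stochastic parameters ``s(n)`` on a trivalent n-leaf tree:
    12(2n-3)+3 for GMM, 6(2n-3)+1 for SSM, 3(2n-3) for K81, 2(2n-3) for K80
    and 2n-3 for JC69 — per-edge free entries plus root degrees of freedom."""
    _validate(model, n)
    return _EDGE_DOF[model] * (2 * n - 3) + _ROOT_DOF[model]


def h0(model: str, n: int) -> Fraction:
    """The exact non-identifiability bound ``dim(D_M) / (s(n) + 1)``, with the
    dimension computed by the character/Burnside route."""
    _validate(model, n)
    return Fraction(dimension_character(model, n), param_count(model, n) + 1)


def mixture_threshold(model: str, n: int) -> int:
    """Least integer h with ``h >= h0(n)``: mixtures on that many or more
    classes are not identifiable."""
    return math.ceil(h0(model, n))


def edim(model: str, n: int, h: int) -> int:
    """Expected dimension ``h*s(n) + h - 1`` of the h-class mixture variety."""
    _validate(model, n)
    return h * param_count(model, n) + h - 1


def corollary32_closed_form(model: str, n: int) -> Fraction:
    """The printed closed forms of h0(n); must equal :func:`h0` exactly:

    GMM: 4^n / (12(2n-3)+4);  SSM: 2^(2n-1) / (6(2n-3)+2);
    K81: 4^(n-1) / (3(2n-3)+1);  K80: (2^(2n-3)+2^(n-2)) / (2(2n-3)+1);
    JC69: (2^(2n-3)+3*2^(n-2)+1) / (3(2n-2)).
    """
    _validate(model, n)
    if model == "GMM":
        return Fraction(4**n, 12 * (2 * n - 3) + 4)
    if model == "SSM":
        return Fraction(2 ** (2 * n - 1), 6 * (2 * n - 3) + 2)
    if model == "K81":
        return Fraction(4 ** (n - 1), 3 * (2 * n - 3) + 1)
    if model == "K80":
        return Fraction(2 ** (2 * n - 3) + 2 ** (n - 2), 2 * (2 * n - 3) + 1)
    return Fraction(2 ** (2 * n - 3) + 3 * 2 ** (n - 2) + 1, 3 * (2 * n - 2))


def rhodes_sullivant_note(n: int) -> dict:
    """The complementary positive bound for GMM mixtures on one trivalent
    topology: such h-mixtures are generically identifiable for h below a
    bound whose printed rendering is ambiguous between ``4^(ceil(n/4)-1)``
    and ``4^(ceil(n/4))-1``.  Both readings are reported with the ambiguity
    flagged; this record is informational only and never feeds the
    non-identifiability threshold."""
    if n < 3:
        raise ValueError("n must be >= 3")
    k = math.ceil(n / 4)
    return {
        "n": n,
        "applies_to": "GMM h-mixtures on a single trivalent tree topology",
        "exponent_argument": k,
        "readings": {
            "4^(ceil(n/4)-1)": 4 ** (k - 1),
            "4^(ceil(n/4))-1": 4**k - 1,
        },
        "ambiguous": True,
        "informational_only": True,
    }


@dataclass(frozen=True)
class IdentReport:
    """Non-identifiability summary for one model and taxa count."""

    model: str
    n: int
    dim_DM: int
    s: int
    h0: Fraction
    threshold: int

    def edim(self, h: int) -> int:
        return h * self.s + h - 1

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "n": self.n,
            "dim_DM": self.dim_DM,
            "s": self.s,
            "h0": str(self.h0),
            "h0_float": float(self.h0),
            "threshold": self.threshold,
            "statement": (
                f"{self.model} h-mixtures on {self.n} taxa are not identifiable "
                f"for h >= {self.threshold}; nothing is claimed below"
            ),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def summary(self) -> str:
        d = self.to_dict()
        return "\n".join(f"{k}: {v}" for k, v in d.items())


def report(model: str, n: int) -> IdentReport:
    """Assemble the identifiability report for one model and taxa count."""
    _validate(model, n)
    bound = h0(model, n)
    assert bound == corollary32_closed_form(model, n)
    return IdentReport(
        model=model,
        n=n,
        dim_DM=dimension_character(model, n),
        s=param_count(model, n),
        h0=bound,
        threshold=math.ceil(bound),
    )
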