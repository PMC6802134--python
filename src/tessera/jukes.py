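"""Random-assignment model of a primitive tetracodon code (Jukes-type).

The 256 tetracodons split into 32 symmetric ones (palindromic or
self-complementary) and 224 with no symmetry.  An element (amino acid or
stop) anchored by a symmetric tetracodon is read by a reversible adaptor
with degeneracy 2; an asymmetric anchor gives degeneracy 4.  Assigning E
distinct anchors at random, the number k of degeneracy-2 elements follows a
hypergeometric law (anchors drawn without replacement) or, as a robustness
variant, a binomial law with p = S/N (independent draws).

With the defaults N = 256, S = 32, E = 17 the modal composition is
(deg2, deg4) = (2, 15): fifteen 4-fold elements, one 2-fold amino acid and a
2-fold stop — exactly the composition of Jukes' primitive code.

Probabilities are computed with exact integer combinatorics (``Fraction``)
and converted to floats only on output.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Dict

WITHOUT_REPLACEMENT = "without_replacement"
INDEPENDENT = "independent"
SAMPLING_MODES = (WITHOUT_REPLACEMENT, INDEPENDENT)


@dataclass(frozen=True)
class AssignmentModel:
    N: int = 256
    S: int = 32
    E: int = 17
    sampling: str = WITHOUT_REPLACEMENT

    def __post_init__(self):
        if not (0 <= self.S <= self.N):
            raise ValueError("need 0 <= S <= N")
        if not (1 <= self.E <= self.N):
            raise ValueError("need 1 <= E <= N")
        if self.sampling not in SAMPLING_MODES:
            raise ValueError(f"unknown sampling mode {self.sampling!r}")


@dataclass(frozen=True)
class DegeneracyComposition:
    deg2_count: int
    deg4_count: int

    @property
    def elements(self) -> int:
        return self.deg2_count + self.deg4_count

    @property
    def codon_budget(self) -> int:
        return 2 * self.deg2_count + 4 * self.deg4_count


@dataclass(frozen=True)
class ModalResult:
    composition: DegeneracyComposition
    tied: bool


def assignment_pmf_exact(model: AssignmentModel) -> Dict[int, Fraction]:
    """Exact pmf of k = number of symmetric anchors among the E drawn."""
    N, S, E = model.N, model.S, model.E
    pmf: Dict[int, Fraction] = {}
    if model.sampling == WITHOUT_REPLACEMENT:
        denom = comb(N, E)
        for k in range(E + 1):
            pmf[k] = Fraction(comb(S, k) * comb(N - S, E - k), denom)
    else:
        p = Fraction(S, N)
        for k in range(E + 1):
            pmf[k] = comb(E, k) * p ** k * (1 - p) ** (E - k)
    return pmf


def assignment_pmf(model: AssignmentModel) -> Dict[int, float]:
    """Float pmf over k (number of degeneracy-2 elements)."""
    return {k: float(v) for k, v in assignment_pmf_exact(model).items()}


def modal_composition(model: AssignmentModel) -> ModalResult:
    """Most probable composition; smallest k on ties, with the tie flagged."""
    pmf = assignment_pmf_exact(model)
    best = max(pmf.values())
    modes = sorted(k for k, v in pmf.items() if v == best)
    k = modes[0]
    return ModalResult(
        composition=DegeneracyComposition(deg2_count=k, deg4_count=model.E - k),
        tied=len(modes) > 1,
    )


def jukes_reference() -> Dict[str, int]:
    """Jukes' primitive code composition and its codon budget.

    Fifteen degeneracy-4 amino acids plus two degeneracy-2 elements (one
    amino acid and the stop pair) use 15*4 + 2*2 = 64 codons across 17
    elements.
    """
    comp = DegeneracyComposition(deg2_count=2, deg4_count=15)
    return {
        "deg2_count": comp.deg2_count,
        "deg4_count": comp.deg4_count,
        "elements": comp.elements,
        "codon_budget": comp.codon_budget,
    }
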