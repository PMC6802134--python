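"""Non-power (redundant) integer representation systems.

A representation system is a non-increasing vector of six non-negative
integer weights (w1 ≥ … ≥ w6).  A length-6 bit string s represents the value
Σ s_i · w_i.  When the weights grow more slowly than powers of two — the
*completeness* condition: every weight is at most 1 + the sum of all smaller
weights — every integer from 0 to Σ w_i is representable, and most values
have several representations.  The multiplicity histogram over the 64 bit
strings is a degeneracy distribution formally identical to those of genetic
codes: with total 23 the system (8, 8, 4, 2, 1, 0) reproduces the vertebrate
mitochondrial distribution {2: 16, 4: 8} and (8, 7, 4, 2, 1, 1) the euplotid
distribution {1: 2, 2: 12, 3: 2, 4: 8}.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import product
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

WORD_LENGTH = 6

#: The two code-matching targets, by short name.
NAMED_TARGETS: Dict[str, Dict[int, int]] = {
    "mito": {2: 16, 4: 8},
    "euplotid": {1: 2, 2: 12, 3: 2, 4: 8},
}


def _clean_weights(weights: Sequence[int]) -> Tuple[int, ...]:
    w = tuple(int(x) for x in weights)
    if len(w) != WORD_LENGTH:
        raise ValueError(f"expected {WORD_LENGTH} weights, got {len(w)}")
    if any(x < 0 for x in w):
        raise ValueError("weights must be non-negative")
    if any(a < b for a, b in zip(w, w[1:])):
        raise ValueError("weights must be non-increasing")
    return w


def representation_value(bits: Sequence[int], weights: Sequence[int]) -> int:
    """Value of a 6-bit string under the weight vector."""
    w = _clean_weights(weights)
    b = [int(x) for x in bits]
    if len(b) != WORD_LENGTH or any(x not in (0, 1) for x in b):
        raise ValueError(f"bits must be {WORD_LENGTH} binary digits")
    return sum(x * wi for x, wi in zip(b, w))


def is_complete(weights: Sequence[int]) -> bool:
    """Whether every value 0 … Σw is representable (contiguous coverage).

    Holds iff each weight is at most 1 + the sum of all smaller weights.
    """
    w = _clean_weights(weights)
    for i, wi in enumerate(w):
        if wi > 1 + sum(w[i + 1:]):
            return False
    return True


@dataclass(frozen=True)
class RepresentationHistogram:
    weights: Tuple[int, ...]
    value_counts: Tuple[Tuple[int, int], ...]     # value -> number of bit strings
    class_distribution: Tuple[Tuple[int, int], ...]  # multiplicity -> number of values

    def counts(self) -> Dict[int, int]:
        return dict(self.value_counts)

    def distribution(self) -> Dict[int, int]:
        return dict(self.class_distribution)


def degeneracy_histogram(weights: Sequence[int]) -> RepresentationHistogram:
    """Enumerate the 64 bit strings and histogram representation multiplicities."""
    w = _clean_weights(weights)
    per_value = Counter(
        sum(x * wi for x, wi in zip(bits, w)) for bits in product((0, 1), repeat=WORD_LENGTH)
    )
    classes = Counter(per_value.values())
    return RepresentationHistogram(
        weights=w,
        value_counts=tuple(sorted(per_value.items())),
        class_distribution=tuple(sorted(classes.items())),
    )


def is_unimodal_profile(weights: Sequence[int]) -> bool:
    """Whether the multiplicity profile over values 0 … Σw rises then falls.

    In a complete system the representable values are contiguous and the
    multiplicity count is symmetric about the midpoint (complementing the
    bits sends value v to Σw − v).  Requiring the profile to be unimodal —
    degeneracy grows towards the centre of the range and never dips back up —
    pins down the block structure that lets the system be read as two merged
    dinucleotide half-systems.  Both code-matching solutions have this shape.
    """
    h = degeneracy_histogram(weights)
    counts = dict(h.value_counts)
    seq = [counts.get(v, 0) for v in range(sum(h.weights) + 1)]
    falling = False
    for a, b in zip(seq, seq[1:]):
        if b < a:
            falling = True
        elif b > a and falling:
            return False
    return True


def _nonincreasing_tuples(length: int, total: int, cap: int) -> Iterable[Tuple[int, ...]]:
    if length == 0:
        if total == 0:
            yield ()
        return
    # remaining weights are each <= first, so prune on total > first * length
    for first in range(min(cap, total), -1, -1):
        if first * length < total:
            break
        for rest in _nonincreasing_tuples(length - 1, total - first, first):
            yield (first,) + rest


def search_weights(
    total: int = 23,
    target: "Mapping[int, int] | str | None" = None,
    length: int = WORD_LENGTH,
    require_complete: bool = True,
    require_unimodal: bool = True,
) -> List[Tuple[int, ...]]:
    """All weight vectors with the given total whose multiplicity histogram
    matches *target* (multiplicity -> value count).

    Candidates are non-increasing non-negative 6-tuples; by default they must
    be complete (contiguous value coverage) and have a unimodal multiplicity
    profile (see :func:`is_unimodal_profile`); either constraint can be
    relaxed for sensitivity checks.  *target* may also be one of the named
    targets ``"mito"`` / ``"euplotid"``.  Returns a lexicographically sorted
    list; an infeasible target yields an empty list.
    """
    if isinstance(target, str):
        target = NAMED_TARGETS[target]
    if target is None:
        raise ValueError("a target class distribution is required")
    target = {int(k): int(v) for k, v in target.items()}
    if length != WORD_LENGTH:
        raise ValueError(f"only length {WORD_LENGTH} systems are supported")
    # quick feasibility: the multiplicities must account for all 2^6 strings
    if sum(k * v for k, v in target.items()) != 2 ** WORD_LENGTH:
        return []
    hits = []
    for w in _nonincreasing_tuples(length, total, total):
        if require_complete and not is_complete(w):
            continue
        if require_unimodal and not is_unimodal_profile(w):
            continue
        if degeneracy_histogram(w).distribution() == target:
            hits.append(w)
    hits.sort()
    return hits
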