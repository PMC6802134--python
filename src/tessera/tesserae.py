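"""The tessera set: 64 four-base codons with built-in redundancy.

A tessera is a quadruplet b1 b2 b3 b4 over {A, C, G, U} whose second doublet
is the image of the first under one Klein-group base exchange g, i.e.
b3 b4 = g(b1 b2).  Equivalently, the transform taking b1 to b3 equals the
transform taking b2 to b4.  There are exactly 16 * 4 = 64 tesserae.

Two structural facts drive everything downstream:

* redundancy — any three letters of a tessera determine the fourth, so a
  tessera carries no more information than a trinucleotide codon;
* error immunity — no single point mutation converts one tessera into
  another (the set has minimum pairwise Hamming distance 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, product
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple, Union

from .symmetry import (
    KLEIN_ELEMENTS,
    RNA_ALPHABET,
    apply_base_transform,
    canonical_representative,
    clean_oligo,
    symmetry_class,
    transform_between,
    transform_oligo,
)

#: Characters accepted as the missing-position marker in reconstruction.
MISSING_MARKERS = "?N.-"


@dataclass(frozen=True, order=True)
class Tessera:
    """A validated tessera with its generator and adjacent-letter transforms.

    ``generator`` is the unique g with b3b4 = g(b1b2); ``t12`` and ``t23``
    are the transforms between letters 1-2 and 2-3.  The transform between
    letters 3-4 always equals ``t12``, so only two of the three adjacent
    transforms are independent (``t23`` composed with ``t12`` gives the
    generator).
    """

    oligo: str
    generator: str
    t12: str
    t23: str

    @property
    def t34(self) -> str:
        return self.t12

    @classmethod
    def from_oligo(cls, s: str) -> "Tessera":
        s = clean_oligo(s)
        ok, gen = is_tessera(s)
        if not ok:
            raise ValueError(f"{s} is not a tessera: positions 1->3 and 2->4 disagree")
        return cls(
            oligo=s,
            generator=gen,
            t12=transform_between(s[0], s[1]),
            t23=transform_between(s[1], s[2]),
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.oligo


def _as_oligo(t: Union[str, Tessera]) -> str:
    return t.oligo if isinstance(t, Tessera) else clean_oligo(t)


def is_tessera(s: str) -> Tuple[bool, Optional[str]]:
    """Whether a length-4 oligo is a tessera; returns (flag, generator)."""
    s = clean_oligo(s)
    if len(s) != 4:
        raise ValueError(f"tessera test requires length 4, got length {len(s)}")
    g13 = transform_between(s[0], s[2])
    g24 = transform_between(s[1], s[3])
    if g13 == g24:
        return True, g13
    return False, None


@lru_cache(maxsize=None)
def generate_tesserae() -> Tuple[Tessera, ...]:
    """All 64 tesserae: append g(d) to each dinucleotide d for each g.

    Returned sorted by oligo (A < C < G < U); cached after first call.
    """
    out = []
    for d in ("".join(p) for p in product(RNA_ALPHABET, repeat=2)):
        for g in KLEIN_ELEMENTS:
            out.append(Tessera.from_oligo(d + transform_oligo(g, d)))
    out.sort(key=lambda t: t.oligo)
    return tuple(out)


@lru_cache(maxsize=None)
def tessera_oligos() -> FrozenSet[str]:
    """The 64 tessera sequences as a frozenset of strings."""
    return frozenset(t.oligo for t in generate_tesserae())


def adjacency_transforms(t: Union[str, Tessera]) -> Tuple[str, str, str]:
    """(t12, t23, t34) for a tessera; t34 always equals t12."""
    tes = t if isinstance(t, Tessera) else Tessera.from_oligo(t)
    return tes.t12, tes.t23, tes.t34


def reconstruct_missing(partial: str) -> str:
    """Recover the one missing letter of a tessera from the other three.

    *partial* is a 4-character string with exactly one missing-position
    marker (``?``, ``N``, ``.`` or ``-``), e.g. ``"A?UA"`` → ``"U"``.

    The generator g links positions (1,3) and (2,4); whichever of those
    diagonal pairs is fully known determines g by the regular group action,
    and g (its own inverse) then fills the gap.
    """
    partial = str(partial).upper()
    if len(partial) != 4:
        raise ValueError(f"expected 4 characters, got {len(partial)}")
    missing = [i for i, ch in enumerate(partial) if ch in MISSING_MARKERS]
    if len(missing) != 1:
        raise ValueError("exactly one position must be marked missing")
    p = missing[0]
    known = {i: clean_oligo(ch, name=f"position {i + 1}") for i, ch in enumerate(partial) if i != p}
    if p in (0, 2):
        g = transform_between(known[1], known[3])
        other = known[2] if p == 0 else known[0]
    else:
        g = transform_between(known[0], known[2])
        other = known[3] if p == 1 else known[1]
    return apply_base_transform(g, other)


def complete_oligo(partial: str) -> str:
    """The full tessera obtained by filling the missing position of *partial*."""
    base = reconstruct_missing(partial)
    p = next(i for i, ch in enumerate(str(partial).upper()) if ch in MISSING_MARKERS)
    filled = list(str(partial).upper())
    filled[p] = base
    return clean_oligo("".join(filled))


def hamming(a: str, b: str) -> int:
    a, b = clean_oligo(a), clean_oligo(b)
    if len(a) != len(b):
        raise ValueError("Hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def min_pairwise_hamming(seqs: Iterable[Union[str, Tessera]]) -> int:
    """Minimum Hamming distance over all unordered pairs of distinct oligos."""
    pool = sorted({_as_oligo(s) for s in seqs})
    if len(pool) < 2:
        raise ValueError("need at least 2 distinct sequences")
    return min(hamming(a, b) for a, b in combinations(pool, 2))


def rumer_transform(s: str) -> str:
    """Rumer's transformation: the KM exchange applied to the first doublet."""
    s = clean_oligo(s)
    if len(s) < 2:
        raise ValueError("Rumer transform needs at least 2 letters")
    return transform_oligo("KM", s[:2]) + s[2:]


def quartet_table(layout: str = "table4a") -> Dict:
    """The 64 tesserae organized into 16 quartets.

    ``table4a`` keys quartets by the pair (t12, t23) of adjacent-letter
    transforms; the four members share both coordinates.  ``table1`` keys
    them by the first dinucleotide, with members ordered by generator
    (I, SW, YR, KM).
    """
    tesserae = generate_tesserae()
    if layout == "table4a":
        table: Dict[Tuple[str, str], Tuple[str, ...]] = {}
        for t12 in KLEIN_ELEMENTS:
            for t23 in KLEIN_ELEMENTS:
                members = tuple(sorted(t.oligo for t in tesserae if (t.t12, t.t23) == (t12, t23)))
                table[(t12, t23)] = members
        return table
    if layout == "table1":
        by_dinuc: Dict[str, Tuple[str, ...]] = {}
        for d in ("".join(p) for p in product(RNA_ALPHABET, repeat=2)):
            by_dinuc[d] = tuple(d + transform_oligo(g, d) for g in KLEIN_ELEMENTS)
        return by_dinuc
    raise ValueError(f"unknown layout {layout!r}; expected 'table4a' or 'table1'")


def table_rows() -> List[Dict[str, str]]:
    """Flat per-tessera annotation rows for TSV/JSON export."""
    rows = []
    for t in generate_tesserae():
        rows.append(
            {
                "tessera": t.oligo,
                "generator": t.generator,
                "t12": t.t12,
                "t23": t.t23,
                "symmetry": symmetry_class(t.oligo),
                "orbit_representative": canonical_representative(t.oligo),
            }
        )
    return rows
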