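"""Reversible-adaptor reading model and orbit-based degeneracy distributions.

A primeval adaptor is modelled by its anticodon and a reading mode:

* ``unidirectional`` — ordinary antiparallel pairing; reads exactly the
  reverse complement of the anticodon.
* ``bidirectional`` — a reversible adaptor that can also pair in parallel
  orientation, base-wise complementary; reads {complement, reverse
  complement} of the anticodon.
* ``dual_anticodon`` — an adaptor presenting the anticodon in all four
  spatial configurations; reads the full-group orbit of the reverse
  complement.

The degeneracy of the amino acid carried by an adaptor is the number of
distinct codons it reads; the more symmetric the anticodon, the smaller the
readable set.  Partitioning a closed codon set into orbits under the
sequence-symmetry group turns this reading model into a degeneracy
distribution: each orbit is one amino-acid (or stop) class and its size is
the class degeneracy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import product
from typing import Dict, FrozenSet, Iterable, List, Tuple, Union

from . import symmetry
from .symmetry import (
    FULL_GROUP,
    RNA_ALPHABET,
    clean_oligo,
    complement,
    is_symmetric,
    orbit,
    orbit_partition,
    reverse_complement,
    validate_group,
)
from .tesserae import tessera_oligos

UNIDIRECTIONAL = "unidirectional"
BIDIRECTIONAL = "bidirectional"
DUAL_ANTICODON = "dual_anticodon"
MODES = (UNIDIRECTIONAL, BIDIRECTIONAL, DUAL_ANTICODON)


@dataclass(frozen=True)
class Adaptor:
    anticodon: str
    mode: str = BIDIRECTIONAL

    def __post_init__(self):
        object.__setattr__(self, "anticodon", clean_oligo(self.anticodon, name="anticodon"))
        if self.mode not in MODES:
            raise ValueError(f"unknown adaptor mode {self.mode!r}; expected one of {MODES}")


def _as_adaptor(a: Union[Adaptor, str], mode: str = None) -> Adaptor:
    if isinstance(a, Adaptor):
        return a if mode is None else Adaptor(a.anticodon, mode)
    return Adaptor(a, mode or BIDIRECTIONAL)


def readable_codons(a: Union[Adaptor, str], mode: str = None) -> FrozenSet[str]:
    """The set of codons an adaptor can pair with, by reading mode."""
    ad = _as_adaptor(a, mode)
    rc = reverse_complement(ad.anticodon)
    if ad.mode == UNIDIRECTIONAL:
        return frozenset({rc})
    if ad.mode == BIDIRECTIONAL:
        return frozenset({complement(ad.anticodon), rc})
    return orbit(rc, FULL_GROUP)


def adaptor_degeneracy(a: Union[Adaptor, str], mode: str = None) -> int:
    """Number of distinct codons read — the degeneracy of the carried amino acid."""
    return len(readable_codons(a, mode))


@dataclass(frozen=True)
class DegeneracyDistribution:
    """Orbit-size histogram of a codon set under a symmetry group.

    ``entries`` maps degeneracy (orbit size) to the number of classes of that
    size; ``codon_total`` is the size of the partitioned set and
    ``symmetric_count`` the number of palindromic or self-complementary
    members.
    """

    entries: Tuple[Tuple[int, int], ...]
    codon_total: int
    symmetric_count: int

    def as_dict(self) -> Dict[int, int]:
        return dict(self.entries)

    @property
    def total_classes(self) -> int:
        return sum(n for _, n in self.entries)

    def __post_init__(self):
        assert sum(d * n for d, n in self.entries) == self.codon_total


def degeneracy_distribution(
    codons: Iterable[str], group: Iterable[str] = FULL_GROUP
) -> DegeneracyDistribution:
    """Partition a group-closed codon set into orbits and count them by size.

    Raises ``ValueError`` naming a violating element if the set is not closed
    under the group.
    """
    g = validate_group(group)
    pool = {clean_oligo(c) for c in codons}
    if not pool:
        raise ValueError("empty codon set")
    lengths = {len(c) for c in pool}
    if len(lengths) != 1:
        raise ValueError(f"codons must share one length, found lengths {sorted(lengths)}")
    for c in sorted(pool):
        for op in sorted(g):
            img = symmetry.apply_sequence_operator(op, c)
            if img not in pool:
                raise ValueError(f"set not closed under group: {op}({c}) = {img} is missing")
    parts = orbit_partition(pool, g)
    sizes = Counter(len(p) for p in parts)
    return DegeneracyDistribution(
        entries=tuple(sorted(sizes.items())),
        codon_total=len(pool),
        symmetric_count=sum(1 for c in pool if is_symmetric(c)),
    )


def all_oligos(n: int) -> List[str]:
    """All 4^n oligos of length n in lexicographic order."""
    if n < 1:
        raise ValueError("length must be >= 1")
    return ["".join(p) for p in product(RNA_ALPHABET, repeat=n)]


@dataclass(frozen=True)
class Table2Row:
    label: str
    codon_count: int
    symmetric_count: int
    distribution: Tuple[Tuple[int, int], ...]

    def as_dict(self) -> Dict:
        return {
            "codon_length": self.label,
            "codon_count": self.codon_count,
            "symmetric_count": self.symmetric_count,
            "distribution": dict(self.distribution),
        }


def table2(
    lengths: Iterable[int] = (2, 3, 4, 5),
    include_tessera_row: bool = True,
    group: Iterable[str] = FULL_GROUP,
) -> List[Table2Row]:
    """Codon count, symmetric count and degeneracy distribution per codon length.

    The ``4T`` row (the tessera set, placed after length 4) is the only case
    whose distribution matches the vertebrate mitochondrial degeneracy
    {2: 16, 4: 8}.
    """
    keyed: List[Tuple[Tuple[float, int], Table2Row]] = []
    for n in lengths:
        dist = degeneracy_distribution(all_oligos(n), group)
        keyed.append(
            ((float(n), 0),
             Table2Row(str(n), dist.codon_total, dist.symmetric_count, dist.entries))
        )
    if include_tessera_row:
        dist = degeneracy_distribution(tessera_oligos(), group)
        keyed.append(
            ((4.0, 1), Table2Row("4T", dist.codon_total, dist.symmetric_count, dist.entries))
        )
    keyed.sort(key=lambda kr: kr[0])
    return [row for _, row in keyed]


def adaptor_inventory(
    distribution: DegeneracyDistribution, stop_classes: int = 2
) -> Tuple[int, int]:
    """Class and adaptor bookkeeping: (total classes, adaptors after stops).

    Each degeneracy class needs one adaptor; classes assigned to stop signals
    need none.  For the tessera distribution {2: 16, 4: 8} this yields 24
    classes, 22 adaptors with the two stop pairs removed, and a ceiling of 23
    representable amino acids with a single stop class.
    """
    entries = distribution.as_dict()
    if stop_classes < 0 or stop_classes > entries.get(2, 0):
        raise ValueError(
            f"stop_classes = {stop_classes} exceeds available degeneracy-2 classes "
            f"({entries.get(2, 0)})"
        )
    total = distribution.total_classes
    return total, total - stop_classes
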