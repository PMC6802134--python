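"""Extant genetic-code tables and their degeneracy / symmetry structure.

Tables are the NCBI translation tables (1 standard, 2 vertebrate
mitochondrial, 10 euplotid nuclear), taken from Biopython's codon-table data
and re-validated on load.  Codons are RNA strings; stops are ``*``.

The analyses here are the quartet-local ones: a *box* is the set of four
codons sharing a first doublet; a *family* box codes a single element with
all four codons; a *split* box codes two elements 2 + 2.  Under the
``split6`` convention a 6-fold degenerate amino acid contributes one quartet
and one pair (its codons are grouped per box), which is the convention every
degeneracy distribution in this package uses by default.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from itertools import product
from typing import Dict, FrozenSet, List, Mapping, Tuple

from Bio.Data import CodonTable as _ncbi

from .symmetry import RNA_ALPHABET, clean_oligo, expand_degenerate, transform_oligo

STOP = "*"

SUPPORTED_TABLES = {
    1: "Standard",
    2: "Vertebrate Mitochondrial",
    10: "Euplotid Nuclear",
}

_GROUP_KINDS = {1: "singleton", 2: "pair", 3: "triple", 4: "quartet", 6: "sextet"}

FAMILY = "family"
SPLIT = "split"
MIXED = "mixed"


@dataclass(frozen=True)
class GeneticCodeTable:
    """An NCBI translation table as a total map over the 64 RNA codons."""

    id: int
    name: str
    codons: Mapping[str, str]

    def translate(self, codon: str) -> str:
        codon = clean_oligo(codon, name="codon")
        if len(codon) != 3:
            raise ValueError("codon must have length 3")
        return self.codons[codon]

    @property
    def stop_codons(self) -> FrozenSet[str]:
        return frozenset(c for c, aa in self.codons.items() if aa == STOP)


@dataclass(frozen=True)
class SynonymGroup:
    codons: FrozenSet[str]
    element: str          # one-letter amino acid or '*'
    kind: str             # singleton | pair | triple | quartet | sextet
    box: str              # shared first doublet ('' when split6 is off and boxes differ)


@dataclass(frozen=True)
class BoxType:
    dinucleotide: str
    type: str             # family | split | mixed
    elements: Tuple[str, ...]


@dataclass(frozen=True)
class RumerReport:
    per_box: Tuple[Tuple[str, bool], ...]
    satisfied: int
    total: int

    def as_dict(self) -> Dict[str, bool]:
        return dict(self.per_box)


_VALIDATIONS = {
    1: {"UAA": STOP, "UAG": STOP, "UGA": STOP, "AUG": "M", "UGG": "W"},
    2: {"AGA": STOP, "AGG": STOP, "AUA": "M", "UGA": "W", "UAA": STOP, "UAG": STOP},
    10: {"UGA": "C", "UAA": STOP, "UAG": STOP, "AUG": "M"},
}


def load_code(table_id: int) -> GeneticCodeTable:
    """Load and validate an embedded NCBI translation table (1, 2 or 10)."""
    if table_id not in SUPPORTED_TABLES:
        raise ValueError(
            f"unknown code table {table_id!r}; available: {sorted(SUPPORTED_TABLES)}"
        )
    src = _ncbi.unambiguous_rna_by_id[table_id]
    codons = {}
    for codon in ("".join(p) for p in product(RNA_ALPHABET, repeat=3)):
        codons[codon] = src.forward_table.get(codon, STOP)
    if len(codons) != 64:
        raise AssertionError("code table must map all 64 codons")
    for codon, expected in _VALIDATIONS[table_id].items():
        if codons[codon] != expected:
            raise AssertionError(
                f"table {table_id} failed validation: {codon} -> {codons[codon]}, "
                f"expected {expected}"
            )
    return GeneticCodeTable(id=table_id, name=SUPPORTED_TABLES[table_id], codons=codons)


def synonym_groups(table: GeneticCodeTable, split6: bool = True) -> List[SynonymGroup]:
    """Partition the 64 codons into synonym groups.

    With ``split6`` (default) codons are grouped by (element, box), so a
    6-fold amino acid splits into a quartet plus a pair and every group lives
    inside one box.  Stops form their own per-box groups.  With ``split6``
    off, grouping is by element alone.
    """
    buckets: Dict[Tuple, List[str]] = defaultdict(list)
    for codon, aa in table.codons.items():
        key = (aa, codon[:2]) if split6 else (aa,)
        buckets[key].append(codon)
    groups = []
    for key in sorted(buckets):
        codons = sorted(buckets[key])
        boxes = {c[:2] for c in codons}
        groups.append(
            SynonymGroup(
                codons=frozenset(codons),
                element=key[0],
                kind=_GROUP_KINDS.get(len(codons), f"size{len(codons)}"),
                box=codons[0][:2] if len(boxes) == 1 else "",
            )
        )
    return groups


def code_distribution(table: GeneticCodeTable, split6: bool = True) -> Dict[int, int]:
    """Degeneracy distribution of a code: group size -> number of groups."""
    sizes = Counter(len(g.codons) for g in synonym_groups(table, split6))
    return dict(sorted(sizes.items()))


def box_type(table: GeneticCodeTable, dinucleotide: str) -> BoxType:
    """Classify the box of a (concrete) first doublet as family, split or mixed."""
    d = clean_oligo(dinucleotide, name="dinucleotide")
    if len(d) != 2:
        raise ValueError("dinucleotide must have length 2")
    elements = tuple(table.codons[d + b] for b in RNA_ALPHABET)
    counts = sorted(Counter(elements).values(), reverse=True)
    if counts == [4]:
        kind = FAMILY
    elif counts == [2, 2]:
        kind = SPLIT
    else:
        kind = MIXED
    return BoxType(dinucleotide=d, type=kind, elements=elements)


def query_boxes(table: GeneticCodeTable, pattern: str) -> List[BoxType]:
    """Box types for a possibly degenerate dinucleotide pattern (e.g. ``WG``)."""
    dinucs = expand_degenerate(pattern)
    if any(len(d) != 2 for d in dinucs):
        raise ValueError("box pattern must have length 2")
    return [box_type(table, d) for d in dinucs]


def rumer_check(table: GeneticCodeTable) -> RumerReport:
    """Per-box test of Rumer's symmetry.

    For each of the 16 boxes, checks whether the KM exchange applied to the
    first doublet sends a family box to a non-family box and vice versa.  In
    the vertebrate mitochondrial code all 16 boxes satisfy the swap.
    """
    flags = []
    for d in ("".join(p) for p in product(RNA_ALPHABET, repeat=2)):
        here = box_type(table, d).type == FAMILY
        there = box_type(table, transform_oligo("KM", d)).type == FAMILY
        flags.append((d, here != there))
    return RumerReport(
        per_box=tuple(flags),
        satisfied=sum(ok for _, ok in flags),
        total=len(flags),
    )


def amino_acid_count(table: GeneticCodeTable) -> int:
    """Number of distinct amino-acid symbols (stops excluded)."""
    return len({aa for aa in table.codons.values() if aa != STOP})


def table_rows(table: GeneticCodeTable, split6: bool = True) -> List[Dict[str, str]]:
    """Per-codon export rows: codon, element, box, box type, group kind."""
    kind_of: Dict[str, str] = {}
    for g in synonym_groups(table, split6):
        for c in g.codons:
            kind_of[c] = g.kind
    rows = []
    for codon in sorted(table.codons):
        rows.append(
            {
                "codon": codon,
                "element": table.codons[codon],
                "box": codon[:2],
                "box_type": box_type(table, codon[:2]).type,
                "group_kind": kind_of[codon],
            }
        )
    return rows
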