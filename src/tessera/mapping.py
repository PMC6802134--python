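"""Bijective mapping between the 64 tesserae and the 64 trinucleotide codons.

The construction encodes the adjacent-letter transforms of a tessera as the
first two codon letters and its last base as the third:

1. compute (t12, t23) for the tessera;
2. if the pair is one of the two swapped quadrant pairs —
   (YR, SW) ↔ (SW, YR) and (KM, SW) ↔ (I, YR) — replace it by its partner
   (these swaps encode the wobble-strategy exceptions of extant codes, where
   SUN boxes are families despite the weak centre and WGN boxes are split
   despite the strong centre);
3. turn the effective pair into codon letters x1 x2 through the fixed
   correspondence I→A, SW→U, KM→C, YR→G;
4. x3 = KM(b4) if b4 is a keto base (U/T or G), else x3 = b4.

Every step is invertible, so the map is a bijection; ``verify_mapping``
checks that it transports the tessera orbit structure exactly onto the
split6 synonym groups of the vertebrate mitochondrial code, including
Rumer's symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple, Union

from .adaptors import degeneracy_distribution
from .codes import FAMILY, GeneticCodeTable, box_type, load_code, synonym_groups
from .symmetry import (
    FULL_GROUP,
    apply_base_transform,
    clean_oligo,
    orbit_partition,
)
from .tesserae import Tessera, generate_tesserae, rumer_transform, tessera_oligos

#: Transform -> codon letter correspondence.
TRANSFORM_TO_BASE = {"I": "A", "SW": "U", "KM": "C", "YR": "G"}
BASE_TO_TRANSFORM = {b: t for t, b in TRANSFORM_TO_BASE.items()}

#: The two quadrant swaps, stored symmetrically (the relocation is an involution).
QUADRANT_SWAPS: Dict[Tuple[str, str], Tuple[str, str]] = {
    ("YR", "SW"): ("SW", "YR"),
    ("SW", "YR"): ("YR", "SW"),
    ("KM", "SW"): ("I", "YR"),
    ("I", "YR"): ("KM", "SW"),
}

KETO = {"U", "G"}


@dataclass(frozen=True)
class MappingEntry:
    tessera: str
    t12: str
    t23: str
    swapped: bool
    codon: str


@dataclass(frozen=True)
class MappingReport:
    bijective: bool
    orbit_count: int
    groups_matched: bool
    rumer_transport_ok: bool
    mismatches: Tuple[str, ...]

    @property
    def ok(self) -> bool:
        return self.bijective and self.groups_matched and self.rumer_transport_ok


def _effective_quadrant(t12: str, t23: str) -> Tuple[Tuple[str, str], bool]:
    if (t12, t23) in QUADRANT_SWAPS:
        return QUADRANT_SWAPS[(t12, t23)], True
    return (t12, t23), False


def map_tessera_to_codon(t: Union[str, Tessera]) -> str:
    """Forward map: tessera → codon (see module docstring for the four steps)."""
    tes = t if isinstance(t, Tessera) else Tessera.from_oligo(t)
    (e12, e23), _ = _effective_quadrant(tes.t12, tes.t23)
    b4 = tes.oligo[3]
    x3 = apply_base_transform("KM", b4) if b4 in KETO else b4
    return TRANSFORM_TO_BASE[e12] + TRANSFORM_TO_BASE[e23] + x3


def map_codon_to_tessera(c: str) -> Tessera:
    """Inverse map: codon → tessera, inverting each forward step."""
    c = clean_oligo(c, name="codon")
    if len(c) != 3:
        raise ValueError("codon must have length 3")
    e12, e23 = BASE_TO_TRANSFORM[c[0]], BASE_TO_TRANSFORM[c[1]]
    (t12, t23), _ = _effective_quadrant(e12, e23)  # the swap is its own inverse
    x3 = c[2]
    b4 = apply_base_transform("KM", x3) if x3 in KETO else x3
    # t34 = t12 links b3 -> b4; t23 links b2 -> b3; t12 links b1 -> b2.
    b3 = apply_base_transform(t12, b4)
    b2 = apply_base_transform(t23, b3)
    b1 = apply_base_transform(t12, b2)
    return Tessera.from_oligo(b1 + b2 + b3 + b4)


def mapping_table() -> List[MappingEntry]:
    """All 64 mapping rows, sorted by tessera."""
    rows = []
    for tes in generate_tesserae():
        _, swapped = _effective_quadrant(tes.t12, tes.t23)
        rows.append(
            MappingEntry(
                tessera=tes.oligo,
                t12=tes.t12,
                t23=tes.t23,
                swapped=swapped,
                codon=map_tessera_to_codon(tes),
            )
        )
    return rows


def verify_mapping(code: Optional[GeneticCodeTable] = None) -> MappingReport:
    """Verify the mapping against a genetic code (default: NCBI table 2).

    Checks: (i) the 64 tesserae map onto all 64 codons (bijection);
    (ii) the image of every tessera orbit is exactly one split6 synonym
    group of the code; (iii) Rumer transport — the KM exchange on a
    tessera's first doublet flips the family status of the image codon's box.
    """
    if code is None:
        code = load_code(2)
    mismatches: List[str] = []

    forward = {t: map_tessera_to_codon(t) for t in sorted(tessera_oligos())}
    bijective = len(set(forward.values())) == 64
    if not bijective:
        dup = sorted(c for c in forward.values() if list(forward.values()).count(c) > 1)
        mismatches.append(f"collisions in codon image: {dup}")

    orbits = orbit_partition(tessera_oligos(), FULL_GROUP)
    groups = {g.codons for g in synonym_groups(code, split6=True)}
    images = {frozenset(forward[t] for t in orb) for orb in orbits}
    groups_matched = images == groups
    if not groups_matched:
        for img in sorted(map(sorted, images - groups)):
            mismatches.append(f"orbit image {img} is not a synonym group of table {code.id}")
        for grp in sorted(map(sorted, groups - images)):
            mismatches.append(f"synonym group {grp} is not an orbit image")

    rumer_ok = True
    for t in sorted(tessera_oligos()):
        flip = rumer_transform(t)
        fam_here = box_type(code, forward[t][:2]).type == FAMILY
        fam_there = box_type(code, forward[flip][:2]).type == FAMILY
        if fam_here == fam_there:
            rumer_ok = False
            mismatches.append(
                f"Rumer transport fails: {t} -> {forward[t]} and {flip} -> {forward[flip]} "
                "share family status"
            )

    return MappingReport(
        bijective=bijective,
        orbit_count=len(orbits),
        groups_matched=groups_matched,
        rumer_transport_ok=rumer_ok,
        mismatches=tuple(mismatches),
    )


def mapped_distribution() -> Dict[int, int]:
    """Degeneracy distribution of tessera orbits (equals the code's {2:16, 4:8})."""
    return degeneracy_distribution(tessera_oligos(), FULL_GROUP).as_dict()
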