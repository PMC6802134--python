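"""Nucleotide alphabet, the Klein four-group of base exchanges, and the
sequence symmetry operators.

The four bases {A, C, G, U} admit three chemically meaningful fixed-point-free
pairings, each exchanging the members of one dichotomy:

* ``SW`` — strong/weak, i.e. the Watson–Crick complement: A↔U, C↔G
* ``YR`` — pyrimidine/purine: A↔G, C↔U
* ``KM`` — keto/amino (Rumer's exchange): A↔C, G↔U

Together with the identity ``I`` these form a group isomorphic to the Klein
four-group, acting *regularly* on the alphabet: for every ordered pair of
bases exactly one element maps the first onto the second.  The same abstract
group reappears at the sequence level as {identity, reverse, complement,
reverse-complement}; orbits of oligonucleotides under that group (or a
subgroup) are the degeneracy classes used throughout this package.

All sequences are plain Python strings over ACGU, read 5'→3'.  DNA input is
accepted anywhere: ``T`` is normalized to ``U`` on the way in.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, List, Set

RNA_ALPHABET = "ACGU"

#: Klein four-group elements, in the canonical order used for tables.
KLEIN_ELEMENTS = ("I", "SW", "YR", "KM")

TRANSFORMS: Dict[str, Dict[str, str]] = {
    "I": {"A": "A", "C": "C", "G": "G", "U": "U"},
    "SW": {"A": "U", "U": "A", "C": "G", "G": "C"},
    "YR": {"A": "G", "G": "A", "C": "U", "U": "C"},
    "KM": {"A": "C", "C": "A", "G": "U", "U": "G"},
}

#: IUPAC degenerate base codes resolvable in box queries.
DEGENERATE_BASES: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "N": "ACGU",
    "W": "AU",
    "S": "CG",
    "K": "GU",
    "M": "AC",
    "Y": "CU",
    "R": "AG",
}


def clean_base(b: str) -> str:
    """Normalize a single base symbol (uppercase, T→U) and validate it."""
    b = str(b).upper()
    if b == "T":
        b = "U"
    if b not in RNA_ALPHABET:
        raise ValueError(f"invalid base symbol {b!r}; expected one of A, C, G, U (or T)")
    return b


def clean_oligo(s: str, name: str = "sequence") -> str:
    """Normalize an oligonucleotide string; reject empty or non-ACGU(T) input.

    Raises ``ValueError`` naming the first offending character and its
    0-based offset.
    """
    raw = str(s).upper()
    out = []
    for i, ch in enumerate(raw):
        if ch == "T":
            ch = "U"
        if ch not in RNA_ALPHABET:
            raise ValueError(f"illegal character {ch!r} at offset {i} in {name}")
        out.append(ch)
    if not out:
        raise ValueError(f"empty {name}")
    return "".join(out)


def format_oligo(s: str, alphabet: str = "rna") -> str:
    """Render an oligo in the requested output alphabet (``rna`` or ``dna``)."""
    if alphabet == "rna":
        return s
    if alphabet == "dna":
        return s.replace("U", "T")
    raise ValueError(f"unknown alphabet {alphabet!r}; expected 'rna' or 'dna'")


def _validate_transform(t: str) -> str:
    if t not in TRANSFORMS:
        raise ValueError(f"unknown base transform {t!r}; expected one of {KLEIN_ELEMENTS}")
    return t


def apply_base_transform(t: str, b: str) -> str:
    """Image of base *b* under the named Klein-group element."""
    return TRANSFORMS[_validate_transform(t)][clean_base(b)]


def transform_oligo(t: str, s: str) -> str:
    """Apply a base transform position-wise to a whole oligo."""
    action = TRANSFORMS[_validate_transform(t)]
    return "".join(action[b] for b in clean_oligo(s))


# Precomputed group structure: composition table and the regular-action
# lookup base pair -> unique transform.
def _build_compose() -> Dict[tuple, str]:
    table = {}
    for a in KLEIN_ELEMENTS:
        for b in KLEIN_ELEMENTS:
            perm = {base: TRANSFORMS[a][TRANSFORMS[b][base]] for base in RNA_ALPHABET}
            for name, action in TRANSFORMS.items():
                if action == perm:
                    table[(a, b)] = name
                    break
    return table


_COMPOSE: Dict[tuple, str] = _build_compose()

_BETWEEN: Dict[tuple, str] = {
    (b1, TRANSFORMS[t][b1]): t for t in KLEIN_ELEMENTS for b1 in RNA_ALPHABET
}


def compose_transforms(t1: str, t2: str) -> str:
    """The unique element of the group acting as *t1* after *t2* (commutative)."""
    return _COMPOSE[(_validate_transform(t1), _validate_transform(t2))]


def transform_between(b1: str, b2: str) -> str:
    """The unique Klein-group element mapping base *b1* onto base *b2*.

    Well defined because the group acts regularly on the alphabet.
    """
    return _BETWEEN[(clean_base(b1), clean_base(b2))]


# ---------------------------------------------------------------------------
# Sequence operators

IDENTITY = "identity"
REVERSE = "reverse"
COMPLEMENT = "complement"
REVERSE_COMPLEMENT = "reverse_complement"

OPERATOR_NAMES = (IDENTITY, REVERSE, COMPLEMENT, REVERSE_COMPLEMENT)

#: The full sequence-symmetry group.
FULL_GROUP: FrozenSet[str] = frozenset(OPERATOR_NAMES)
#: The two-element subgroup used for reading-direction-only degeneracy.
REVERSE_GROUP: FrozenSet[str] = frozenset({IDENTITY, REVERSE})

_OP_COMPOSE: Dict[tuple, str] = {}
for _a, _ka in ((IDENTITY, (False, False)), (REVERSE, (True, False)),
                (COMPLEMENT, (False, True)), (REVERSE_COMPLEMENT, (True, True))):
    for _b, _kb in ((IDENTITY, (False, False)), (REVERSE, (True, False)),
                    (COMPLEMENT, (False, True)), (REVERSE_COMPLEMENT, (True, True))):
        _kc = (_ka[0] ^ _kb[0], _ka[1] ^ _kb[1])
        _OP_COMPOSE[(_a, _b)] = {
            (False, False): IDENTITY,
            (True, False): REVERSE,
            (False, True): COMPLEMENT,
            (True, True): REVERSE_COMPLEMENT,
        }[_kc]
del _a, _b, _ka, _kb, _kc


def reverse(s: str) -> str:
    """3'→5' reading of the oligo."""
    return clean_oligo(s)[::-1]


def complement(s: str) -> str:
    """Base-wise Watson–Crick complement (the SW exchange applied position-wise)."""
    return transform_oligo("SW", s)


def reverse_complement(s: str) -> str:
    return complement(s)[::-1]


_OPERATOR_ACTIONS = {
    IDENTITY: lambda s: s,
    REVERSE: reverse,
    COMPLEMENT: complement,
    REVERSE_COMPLEMENT: reverse_complement,
}


def apply_sequence_operator(op: str, s: str) -> str:
    """Apply one of the four sequence operators to an oligo."""
    if op not in _OPERATOR_ACTIONS:
        raise ValueError(f"unknown sequence operator {op!r}; expected one of {OPERATOR_NAMES}")
    return _OPERATOR_ACTIONS[op](clean_oligo(s))


PALINDROMIC = "palindromic"
SELF_COMPLEMENTARY = "self_complementary"
ASYMMETRIC = "asymmetric"


def symmetry_class(s: str) -> str:
    """Classify an oligo as palindromic, self-complementary or asymmetric.

    Palindromic means fixed by reversal; self-complementary means fixed by
    reverse-complement.  No oligo can be both, since that would force a base
    fixed by the (fixed-point-free) complement.
    """
    s = clean_oligo(s)
    if s == s[::-1]:
        return PALINDROMIC
    if s == reverse_complement(s):
        return SELF_COMPLEMENTARY
    return ASYMMETRIC


def is_symmetric(s: str) -> bool:
    return symmetry_class(s) != ASYMMETRIC


def validate_group(group: Iterable[str]) -> FrozenSet[str]:
    """Check *group* is a subgroup of the four operators containing identity."""
    g = frozenset(group)
    unknown = g - FULL_GROUP
    if unknown:
        raise ValueError(f"unknown sequence operators: {sorted(unknown)}")
    if IDENTITY not in g:
        raise ValueError("operator group must contain the identity")
    for a in g:
        for b in g:
            if _OP_COMPOSE[(a, b)] not in g:
                raise ValueError(
                    f"operator set is not closed: {a} o {b} = {_OP_COMPOSE[(a, b)]} missing"
                )
    return g


def orbit(s: str, group: Iterable[str] = FULL_GROUP) -> FrozenSet[str]:
    """Orbit of an oligo under a subgroup of the sequence-symmetry group."""
    g = validate_group(group)
    s = clean_oligo(s)
    return frozenset(_OPERATOR_ACTIONS[op](s) for op in g)


def canonical_representative(s: str, group: Iterable[str] = FULL_GROUP) -> str:
    """Lexicographically smallest member of the orbit (A < C < G < U)."""
    return min(orbit(s, group))


def orbit_partition(seqs: Iterable[str], group: Iterable[str] = FULL_GROUP) -> List[FrozenSet[str]]:
    """Partition a set of equal-length oligos into orbits.

    The caller is responsible for closure of the set under the group; members
    of an orbit falling outside *seqs* are simply not restricted here.
    """
    g = validate_group(group)
    pool: Set[str] = {clean_oligo(s) for s in seqs}
    parts: List[FrozenSet[str]] = []
    for s in sorted(pool):
        if s not in pool:
            continue
        orb = orbit(s, g)
        parts.append(orb)
        pool -= orb
    return parts


def expand_degenerate(pattern: str) -> List[str]:
    """Expand IUPAC degenerate base codes (N, W, S, K, M, Y, R) to concrete oligos."""
    pattern = str(pattern).upper().replace("T", "U")
    choices = []
    for i, ch in enumerate(pattern):
        if ch not in DEGENERATE_BASES:
            raise ValueError(f"unknown base code {ch!r} at offset {i} in pattern")
        choices.append(DEGENERATE_BASES[ch])
    out = [""]
    for opts in choices:
        out = [prefix + b for prefix in out for b in opts]
    return out
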