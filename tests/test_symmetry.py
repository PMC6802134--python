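"""Klein-group structure of the base exchanges and sequence operators."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from tessera import symmetry as sym

oligos = st.text(alphabet="ACGU", min_size=1, max_size=8)


@pytest.mark.parametrize(
    "transform, base, expected",
    [("SW", "A", "U"), ("I", "G", "G"), ("YR", "C", "U"), ("KM", "A", "C"), ("KM", "G", "U")],
)
def test_base_transform_images(transform, base, expected):
    assert sym.apply_base_transform(transform, base) == expected


def test_klein_group_table():
    """All 16 compositions close, commute, and every element is self-inverse."""
    for a, b in itertools.product(sym.KLEIN_ELEMENTS, repeat=2):
        c = sym.compose_transforms(a, b)
        assert c in sym.KLEIN_ELEMENTS
        assert c == sym.compose_transforms(b, a)
    for a in sym.KLEIN_ELEMENTS:
        assert sym.compose_transforms(a, a) == "I"
        assert sym.compose_transforms("I", a) == a
    assert sym.compose_transforms("SW", "YR") == "KM"


def test_regular_action():
    """Exactly one transform maps any ordered base pair; it round-trips."""
    for b1, b2 in itertools.product(sym.RNA_ALPHABET, repeat=2):
        t = sym.transform_between(b1, b2)
        assert sym.apply_base_transform(t, b1) == b2
        others = [u for u in sym.KLEIN_ELEMENTS if sym.apply_base_transform(u, b1) == b2]
        assert others == [t]


def test_involutions_are_fixed_point_free():
    for t in ("SW", "YR", "KM"):
        for b in sym.RNA_ALPHABET:
            assert sym.apply_base_transform(t, b) != b


@pytest.mark.parametrize(
    "op, seq, expected",
    [
        ("reverse_complement", "AUC", "GAU"),
        ("reverse", "AUUA", "AUUA"),
        ("complement", "AUUA", "UAAU"),
        ("identity", "ACGU", "ACGU"),
    ],
)
def test_sequence_operators(op, seq, expected):
    assert sym.apply_sequence_operator(op, seq) == expected


@given(oligos)
def test_reverse_and_reverse_complement_are_involutions(s):
    assert sym.reverse(sym.reverse(s)) == s
    assert sym.reverse_complement(sym.reverse_complement(s)) == s
    assert sym.complement(sym.complement(s)) == s


@given(oligos)
def test_complement_has_no_fixed_base(s):
    assert all(a != b for a, b in zip(s, sym.complement(s)))


@pytest.mark.parametrize(
    "seq, label",
    [("AUUA", "palindromic"), ("ACGU", "self_complementary"), ("CGUA", "asymmetric")],
)
def test_symmetry_class_examples(seq, label):
    assert sym.symmetry_class(seq) == label


@given(oligos)
def test_no_oligo_is_both_palindromic_and_self_complementary(s):
    assert not (s == sym.reverse(s) and s == sym.reverse_complement(s))


@pytest.mark.parametrize(
    "seq, group, expected",
    [
        ("AUUA", sym.FULL_GROUP, {"AUUA", "UAAU"}),
        ("CGUA", sym.FULL_GROUP, {"CGUA", "AUGC", "GCAU", "UACG"}),
        ("AAAA", sym.REVERSE_GROUP, {"AAAA"}),
    ],
)
def test_orbit_examples(seq, group, expected):
    assert sym.orbit(seq, group) == frozenset(expected)


def test_orbit_size_two_iff_symmetric():
    """Exhaustive for lengths 2-5: full-group orbit size is 2 or 4, 2 iff symmetric."""
    for n in range(2, 6):
        for tup in itertools.product(sym.RNA_ALPHABET, repeat=n):
            s = "".join(tup)
            size = len(sym.orbit(s))
            assert size in (2, 4)
            assert (size == 2) == sym.is_symmetric(s)


def test_orbits_partition_closed_sets():
    seqs = ["".join(t) for t in itertools.product(sym.RNA_ALPHABET, repeat=3)]
    parts = sym.orbit_partition(seqs)
    assert sum(len(p) for p in parts) == 64
    seen = set()
    for p in parts:
        assert not (p & seen)
        seen |= p


def test_group_validation_rejects_unclosed_sets():
    with pytest.raises(ValueError, match="not closed"):
        sym.orbit("ACGU", {"identity", "reverse", "complement"})
    with pytest.raises(ValueError, match="identity"):
        sym.orbit("ACGU", {"reverse"})


def test_input_normalization_and_errors():
    assert sym.clean_oligo("acgt") == "ACGU"
    assert sym.format_oligo("ACGU", "dna") == "ACGT"
    with pytest.raises(ValueError, match="offset 2"):
        sym.clean_oligo("ACNU")
    with pytest.raises(ValueError, match="empty"):
        sym.clean_oligo("")
    with pytest.raises(ValueError):
        sym.apply_base_transform("XX", "A")


def test_expand_degenerate():
    assert sym.expand_degenerate("WG") == ["AG", "UG"]
    assert len(sym.expand_degenerate("NN")) == 16
    assert sorted(sym.expand_degenerate("K")) == ["G", "U"]
    with pytest.raises(ValueError, match="unknown base code"):
        sym.expand_degenerate("XZ")
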