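"""Generation, recognition, redundancy and error immunity of the tessera set."""

import itertools
from collections import Counter

import pytest

from tessera import symmetry as sym
from tessera import tesserae as tz


def test_generation_yields_64_distinct(tessera_set):
    assert len(tessera_set) == 64


def test_seed_examples():
    """The two generation examples: dinucleotides from A, tesserae from AU."""
    assert {"A" + sym.apply_base_transform(g, "A") for g in sym.KLEIN_ELEMENTS} == {
        "AA", "AU", "AG", "AC"
    }
    assert {"AU" + sym.transform_oligo(g, "AU") for g in sym.KLEIN_ELEMENTS} == {
        "AUAU", "AUUA", "AUGC", "AUCG"
    }


def test_symmetry_census(tessera_set):
    census = Counter(sym.symmetry_class(t) for t in tessera_set)
    assert census == {"palindromic": 16, "self_complementary": 16, "asymmetric": 32}


@pytest.mark.parametrize(
    "seq, flag, gen",
    [("AUUA", True, "SW"), ("AACC", True, "KM"), ("AAAU", False, None)],
)
def test_is_tessera_examples(seq, flag, gen):
    assert tz.is_tessera(seq) == (flag, gen)


def test_is_tessera_matches_generated_set(tessera_set):
    """Membership oracle: the predicate agrees with generation on all 256 4-mers."""
    for tup in itertools.product(sym.RNA_ALPHABET, repeat=4):
        s = "".join(tup)
        assert tz.is_tessera(s)[0] == (s in tessera_set)


def test_is_tessera_rejects_wrong_length():
    with pytest.raises(ValueError, match="length 4"):
        tz.is_tessera("AUU")


@pytest.mark.parametrize(
    "seq, expected",
    [("AUCG", ("SW", "YR", "SW")), ("AAAA", ("I", "I", "I")), ("AACC", ("I", "KM", "I"))],
)
def test_adjacency_transforms(seq, expected):
    assert tz.adjacency_transforms(seq) == expected


def test_adjacency_transform_dependency(tesserae):
    """t34 = t12 and t23 = generator o t12 for every tessera."""
    for t in tesserae:
        assert sym.transform_between(t.oligo[2], t.oligo[3]) == t.t12
        assert sym.compose_transforms(t.generator, t.t12) == t.t23


def test_adjacency_rejects_non_tessera():
    with pytest.raises(ValueError, match="not a tessera"):
        tz.adjacency_transforms("AAAU")


def test_closure_under_sequence_operators(tessera_set):
    for op in sym.OPERATOR_NAMES:
        assert {sym.apply_sequence_operator(op, t) for t in tessera_set} == tessera_set


def test_rumer_flip_swaps_symmetry_and_degeneracy(tessera_set):
    """KM on the first doublet is an involution on tesserae that swaps
    symmetric (orbit 2) with asymmetric (orbit 4) members."""
    assert tz.rumer_transform("AUUA") == "CGUA"
    for t in tessera_set:
        image = tz.rumer_transform(t)
        assert image in tessera_set
        assert tz.rumer_transform(image) == t
        assert sym.is_symmetric(t) != sym.is_symmetric(image)
        assert {len(sym.orbit(t)), len(sym.orbit(image))} == {2, 4}


@pytest.mark.parametrize(
    "partial, base", [("A?UA", "U"), ("?ACC", "A"), ("AAA?", "A")]
)
def test_reconstruct_missing_examples(partial, base):
    assert tz.reconstruct_missing(partial) == base


def test_reconstruction_inverts_deletion(tessera_set):
    """For all 64 tesserae and 4 positions the deleted base is recovered and
    is the only completion: the other 3 candidates give non-tesserae."""
    for t in sorted(tessera_set):
        for p in range(4):
            partial = t[:p] + "?" + t[p + 1:]
            assert tz.reconstruct_missing(partial) == t[p]
            assert tz.complete_oligo(partial) == t
            completions = [
                b for b in sym.RNA_ALPHABET if tz.is_tessera(t[:p] + b + t[p + 1:])[0]
            ]
            assert completions == [t[p]]


def test_reconstruct_missing_input_errors():
    with pytest.raises(ValueError, match="exactly one"):
        tz.reconstruct_missing("A??A")
    with pytest.raises(ValueError, match="4 characters"):
        tz.reconstruct_missing("A?A")


def test_min_pairwise_hamming(tessera_set):
    assert tz.min_pairwise_hamming(tessera_set) == 2
    assert tz.min_pairwise_hamming({"AAAA", "AAUU"}) == 2
    with pytest.raises(ValueError, match="at least 2"):
        tz.min_pairwise_hamming({"AAAA", "AAAA"})


def test_no_single_point_mutation_links_tesserae(tessera_set):
    """Brute force over 64 x 12 single mutations: none lands on another tessera."""
    for t in tessera_set:
        for p in range(4):
            for b in sym.RNA_ALPHABET:
                if b == t[p]:
                    continue
                assert t[:p] + b + t[p + 1:] not in tessera_set


def test_quartet_table_table4a(tessera_set):
    table = tz.quartet_table("table4a")
    assert len(table) == 16
    assert table[("I", "I")] == ("AAAA", "CCCC", "GGGG", "UUUU")
    assert table[("I", "KM")] == ("AACC", "CCAA", "GGUU", "UUGG")
    members = [t for quartet in table.values() for t in quartet]
    assert len(members) == 64 and set(members) == tessera_set
    for (t12, t23), quartet in table.items():
        for t in quartet:
            assert tz.adjacency_transforms(t)[:2] == (t12, t23)


def test_quartet_table_table1(tessera_set):
    table = tz.quartet_table("table1")
    assert len(table) == 16
    assert table["AU"] == ("AUAU", "AUUA", "AUGC", "AUCG")
    members = [t for quartet in table.values() for t in quartet]
    assert len(members) == 64 and set(members) == tessera_set


def test_quartet_table_unknown_layout():
    with pytest.raises(ValueError, match="layout"):
        tz.quartet_table("table9")


def test_table_rows_annotation(tessera_set):
    rows = tz.table_rows()
    assert len(rows) == 64
    by_oligo = {r["tessera"]: r for r in rows}
    assert by_oligo["AUUA"]["symmetry"] == "palindromic"
    assert by_oligo["AUUA"]["generator"] == "SW"
    for r in rows:
        assert r["orbit_representative"] in tessera_set
        assert r["orbit_representative"] <= r["tessera"]
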