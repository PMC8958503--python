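"""Formula arithmetic, exact masses and library enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepdcl.chemlib import (
    MolecularFormula,
    adduct_formula,
    degeneracy_groups,
    enumerate_library,
    isotopologue_masses,
    monoisotopic_mass,
    parse_formula,
)

# Neutral monoisotopic masses printed for every isolated compound; the
# bromo compounds list their 79Br/81Br isotopologue pair.
PRINTED_MASSES = {
    "3FF": [514.3308],
    "3GG": [514.3308],
    "3KK": [542.3621],
    "3NN": [482.3409],
    "3OO": [630.1416, 632.1396],
    "3A": [308.2576],
    "3AC": [486.3359],
    "3AF": [464.3151],
    "3AG": [464.3151],
    "3AN": [448.3202],
    "3J": [308.2576],
    "3FJ": [464.3151],
    "3O": [416.1787, 418.1766],
    "3FO": [572.2362, 574.2342],
    "3LO": [556.2413, 558.2392],
}


def test_parse_formula_grammar():
    assert parse_formula("C32H42N4O2").counts == {"C": 32, "H": 42, "N": 4, "O": 2}
    assert parse_formula("C10H26N4").counts == {"C": 10, "H": 26, "N": 4}
    assert parse_formula("").counts == {}
    assert monoisotopic_mass(parse_formula("")) == 0.0
    assert parse_formula("CHBr").counts == {"C": 1, "H": 1, "Br": 1}


@pytest.mark.parametrize("bad", ["C32X", "c10", "H-2", "12C", "C3.5"])
def test_parse_formula_rejects_malformed(bad):
    with pytest.raises(ValueError):
        parse_formula(bad)


def test_formula_roundtrip_and_hill_order():
    for text in ["C31H42N4O", "C26H40Br2N4O4", "H2O", "BrH"]:
        assert parse_formula(parse_formula(text).hill()).counts == \
            parse_formula(text).counts
    assert parse_formula("O2H42C32N4").hill() == "C32H42N4O2"


def test_subtraction_never_negative():
    with pytest.raises(ValueError):
        parse_formula("CH4") - parse_formula("O")
    assert (parse_formula("CH4O") - parse_formula("O")).hill() == "CH4"


_formula_st = st.dictionaries(
    st.sampled_from(["C", "H", "N", "O", "S", "Br"]),
    st.integers(min_value=0, max_value=60),
    max_size=6,
)


@settings(max_examples=200, deadline=None)
@given(_formula_st, _formula_st)
def test_mass_additivity(c1, c2):
    f1, f2 = MolecularFormula(c1), MolecularFormula(c2)
    assert monoisotopic_mass(f1 + f2) == pytest.approx(
        monoisotopic_mass(f1) + monoisotopic_mass(f2), abs=1e-9
    )


@settings(max_examples=100, deadline=None)
@given(_formula_st)
def test_mass_agrees_with_pyteomics(counts):
    """Independent exact-mass oracle: pyteomics' isotope tables."""
    pyteomics_mass = pytest.importorskip("pyteomics.mass")
    f = MolecularFormula(counts)
    if not f:
        return
    expected = pyteomics_mass.calculate_mass(formula=f.hill())
    assert monoisotopic_mass(f) == pytest.approx(expected, abs=1e-4)


def test_all_printed_masses_reproduce(library):
    by_id = {m.id: m for m in library}
    for mid, masses in PRINTED_MASSES.items():
        member = by_id[mid]
        iso = [m for m, _ in member.isotopologue_masses]
        for printed, computed in zip(masses, iso):
            assert computed == pytest.approx(printed, abs=5e-4), mid


def test_adduct_formula_arithmetic(registry, core):
    spermine = parse_formula("C10H26N4")
    assert core.formula.counts == spermine.counts
    f_ff = adduct_formula(core, [registry["F"], registry["F"]])
    assert f_ff.hill() == "C32H42N4O2"
    f_a = adduct_formula(core, [registry["A"]])
    assert f_a.hill() == "C17H32N4O"
    assert adduct_formula(core, []).counts == spermine.counts
    with pytest.raises(ValueError):
        adduct_formula(core, [registry["A"]] * 3)


def test_isotopologue_ladder(registry, core):
    f = adduct_formula(core, [registry["O"]])
    ladder = isotopologue_masses(f)
    assert [k for _, k in ladder] == [0, 1]
    assert ladder[0][0] == pytest.approx(416.1787, abs=5e-4)
    assert ladder[1][0] == pytest.approx(418.1766, abs=5e-4)
    masses = [m for m, _ in ladder]
    assert masses == sorted(masses)
    # Br-free formula: single entry equal to the monoisotopic mass
    f0 = parse_formula("C17H32N4O")
    assert isotopologue_masses(f0) == [(monoisotopic_mass(f0), 0)]


@pytest.mark.parametrize("n", [1, 2, 5, 15])
def test_enumeration_count_closed_form(core, aldehydes, n):
    members = enumerate_library(core, aldehydes[:n])
    assert len(members) == n + n * (n + 1) // 2
    assert len({m.id for m in members}) == len(members)


def test_enumeration_two_aldehydes(core, registry):
    members = enumerate_library(core, [registry["A"], registry["B"]])
    assert sorted(m.id for m in members) == ["3A", "3AA", "3AB", "3B", "3BB"]


def test_member_id_order_independent(core, registry):
    a, c = registry["A"], registry["C"]
    from hepdcl.chemlib import _member

    assert _member(core, [a, c]).id == _member(core, [c, a]).id == "3AC"


def test_degeneracy_groups_paper_cases(library):
    groups = degeneracy_groups(library, tol=0.02)
    gid = {m.id: i for i, grp in enumerate(groups) for m in grp}
    assert gid["3AA"] == gid["3AJ"] == gid["3JJ"]
    assert gid["3A"] == gid["3J"]
    assert gid["3AA"] != gid["3A"]
    assert gid["3AF"] == gid["3AG"] == gid["3FJ"]


def test_degeneracy_groups_partition_properties(library):
    rng = np.random.default_rng(0)
    shuffled = list(library)
    rng.shuffle(shuffled)
    groups = degeneracy_groups(library, tol=0.02)
    groups_shuffled = degeneracy_groups(shuffled, tol=0.02)
    as_ids = lambda gs: sorted(tuple(m.id for m in g) for g in gs)
    assert as_ids(groups) == as_ids(groups_shuffled)
    # disjoint and covering
    flat = [m.id for g in groups for m in g]
    assert sorted(flat) == sorted(m.id for m in library)
    # single member is a singleton group
    assert degeneracy_groups(library[:1], tol=0.02) == [[library[0]]]
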