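"""Selector laws: filters, union/idempotence/commutation, altloc policy."""

from __future__ import annotations

import pytest

from pdbtk.records import AtomRecord, records_from_text, render
from pdbtk.selectors import (
    UsageError,
    delete_element,
    delete_hetatm,
    keep_coordinates,
    parse_residue_ranges,
    select_altloc,
    select_atom_names,
    select_chains,
    select_residue_ranges,
)

from conftest import ANISOU_PAIR


def atoms(records_or_text):
    if isinstance(records_or_text, str):
        records_or_text = records_from_text(records_or_text)
    return [r for r in records_or_text if isinstance(r, AtomRecord)]


def atom_multiset(records):
    return sorted((a.chain, a.resseq, a.icode, a.atom_name, a.altloc, a.serial)
                  for a in records)


# --- chain selection --------------------------------------------------------

def test_chain_union_equals_combined_selection(messy):
    text, _ = messy
    a = atoms(select_chains(records_from_text(text), {"A"}))
    b = atoms(select_chains(records_from_text(text), {"B"}))
    ab = atoms(select_chains(records_from_text(text), {"A", "B"}))
    assert atom_multiset(a) + atom_multiset(b) == atom_multiset(ab)


def test_absent_chain_selects_nothing(basic):
    text, _ = basic
    assert atoms(select_chains(records_from_text(text), {"Z"})) == []


def test_chain_selection_keeps_matching_ter_only(basic):
    text, _ = basic
    from pdbtk.records import TerRecord
    ters = [r for r in select_chains(records_from_text(text), {"A"})
            if isinstance(r, TerRecord)]
    assert [t.chain for t in ters] == ["A"]


def test_empty_chain_set_is_usage_error(basic):
    text, _ = basic
    with pytest.raises(UsageError):
        list(select_chains(records_from_text(text), set()))


# --- residue ranges ---------------------------------------------------------

@pytest.mark.parametrize("option,expected", [
    ("1:30", [(1, 30)]),
    ("5", [(5, 5)]),
    ("-3:2", [(-3, 2)]),
    ("10:,-5", [(10, None), (-5, -5)]),
    (":4", [(None, 4)]),
    ("1:3,8:9", [(1, 3), (8, 9)]),
])
def test_range_grammar(option, expected):
    assert parse_residue_ranges(option) == expected


@pytest.mark.parametrize("option", ["5:1", "a:b", "", ",", "1:2:3"])
def test_malformed_ranges_are_usage_errors(option):
    with pytest.raises(UsageError):
        parse_residue_ranges(option)


def test_residue_selection_matches_linear_scan(messy):
    """Negative residue numbers: selection equals a brute-force scan."""
    text, _ = messy
    ranges = [(-3, 2)]
    got = atoms(select_residue_ranges(records_from_text(text), ranges))
    oracle = [a for a in atoms(text) if -3 <= a.resseq <= 2]
    assert atom_multiset(got) == atom_multiset(oracle)
    assert got  # the fixture does contain residues in the range


def test_full_extent_range_is_identity_on_atoms(messy):
    text, _ = messy
    got = atoms(select_residue_ranges(records_from_text(text), [(None, None)]))
    assert atom_multiset(got) == atom_multiset(atoms(text))


# --- atom names and elements ------------------------------------------------

def test_atom_name_selection_count_matches_tally(messy):
    text, tallies = messy
    got = atoms(select_atom_names(records_from_text(text), {"CA"}))
    assert len(got) == tallies["per_name"]["CA"]
    assert all(a.atom_name == "CA" for a in got)


def test_delete_element_count_matches_tally(messy):
    text, tallies = messy
    n_total = tallies["n_atom"] + tallies["n_hetatm"]
    kept = atoms(delete_element(records_from_text(text), {"O"}))
    assert len(kept) == n_total - tallies["per_element"]["O"]


def test_delete_element_falls_back_to_name_when_columns_blank():
    lines = [ln[:76] + "    " for ln in ANISOU_PAIR[:1]]   # blank element cols
    kept = atoms(delete_element(records_from_text("\n".join(lines)), {"C"}))
    assert kept == []


def test_delete_hetatm_removes_waters(messy):
    text, tallies = messy
    kept = atoms(delete_hetatm(records_from_text(text)))
    assert len(kept) == tallies["n_atom"]
    assert all(a.kind == "ATOM" for a in kept)


def test_dropped_atom_takes_its_anisou_along():
    text = "\n".join(ANISOU_PAIR)
    out = list(delete_element(records_from_text(text), {"C"}))
    assert out == []


def test_keep_coordinates_idempotent(messy):
    text, _ = messy
    once = render(keep_coordinates(records_from_text(text)))
    twice = render(keep_coordinates(records_from_text(once)))
    assert once == twice


# --- altloc policy ----------------------------------------------------------

def altloc_demo():
    from pdbtk.fixtures import FixtureSpec, make_structure
    return make_structure(FixtureSpec(n_chains=1, residues_per_chain=10,
                                      atoms_per_residue=4, altloc_fraction=1.0,
                                      seed=13))


def test_highest_occupancy_altloc_survives_and_is_blanked():
    text, tallies = altloc_demo()
    out = atoms(select_altloc(records_from_text(text)))
    # every residue's CA was split A(0.60)/B(0.40): A's coordinates survive
    cas = [a for a in out if a.atom_name == "CA"]
    assert len(cas) == tallies["n_residues"]["A"]
    assert all(a.altloc == " " for a in out)
    assert all(a.occupancy == pytest.approx(0.60) for a in cas)


def test_explicit_altloc_is_kept():
    text, _ = altloc_demo()
    out = atoms(select_altloc(records_from_text(text), loc="B"))
    cas = [a for a in out if a.atom_name == "CA"]
    assert cas and all(a.occupancy == pytest.approx(0.40) for a in cas)
    assert all(a.altloc == " " for a in cas)


def test_missing_explicit_altloc_drops_group_with_warning():
    text, _ = altloc_demo()
    warnings: list[str] = []
    out = atoms(select_altloc(records_from_text(text), loc="C",
                              warn=warnings.append))
    assert all(a.atom_name != "CA" for a in out)
    assert warnings


def test_altloc_tie_keeps_first_in_file_order():
    from dataclasses import replace
    text, _ = altloc_demo()
    recs = [replace(r, occupancy=0.50) if isinstance(r, AtomRecord) and r.altloc != " "
            else r for r in records_from_text(text)]
    out = atoms(select_altloc(iter(recs)))
    cas = [a for a in out if a.atom_name == "CA"]
    # altloc A is written first by the generator
    originals = [a for a in recs if isinstance(a, AtomRecord) and a.altloc == "A"]
    assert [a.serial for a in cas] == [a.serial for a in originals]


def test_stream_without_altlocs_passes_unchanged(basic):
    text, _ = basic
    assert render(select_altloc(records_from_text(text))) == \
        render(records_from_text(text))


# --- general selector laws --------------------------------------------------

SELECTORS = [
    ("selchain", lambda rs: select_chains(rs, {"A", "B"})),
    ("selres", lambda rs: select_residue_ranges(rs, [(1, 5)])),
    ("selatom", lambda rs: select_atom_names(rs, {"CA", "N"})),
    ("delhetatm", delete_hetatm),
    ("delelement", lambda rs: delete_element(rs, {"S"})),
    ("keepcoord", keep_coordinates),
    ("selaltloc", select_altloc),
]


@pytest.mark.parametrize("name,op", SELECTORS)
def test_selectors_are_idempotent(name, op, messy):
    text, _ = messy
    once = render(op(records_from_text(text)))
    twice = render(op(records_from_text(once)))
    assert once == twice


def test_independent_selectors_commute(messy):
    text, _ = messy
    ab = render(select_atom_names(
        select_chains(records_from_text(text), {"A"}), {"CA"}))
    ba = render(select_chains(
        select_atom_names(records_from_text(text), {"CA"}), {"A"}))
    assert ab == ba


@pytest.mark.parametrize("name,op", SELECTORS)
def test_selectors_only_ever_remove_records(name, op, messy):
    text, _ = messy
    inp = atom_multiset(atoms(text))
    out_atoms = atoms(op(records_from_text(text)))
    # up to altloc blanking, every output atom is an input atom
    out = sorted((a.chain, a.resseq, a.icode, a.atom_name, a.serial)
                 for a in out_atoms)
    inp_no_altloc = sorted((c, r, i, n, s) for c, r, i, n, _, s in inp)
    assert set(out) <= set(inp_no_altloc)
    assert len(out) <= len(inp)
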