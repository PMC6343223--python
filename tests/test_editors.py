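"""Editors: renumbering conservation, merge counting, sort oracle, tidy laws."""

from __future__ import annotations

import random

import pytest

from pdbtk.editors import (
    merge_streams,
    renumber_residues,
    renumber_serials,
    rename_chains,
    sort_records,
    tidy,
)
from pdbtk.fixtures import FixtureSpec, make_structure
from pdbtk.records import (
    AnisouRecord,
    AtomRecord,
    FormatOverflowError,
    TerRecord,
    records_from_text,
    render,
)
from pdbtk.selectors import UsageError, select_chains
from pdbtk.validator import validate_text

from conftest import ANISOU_PAIR


def atoms(it):
    return [r for r in it if isinstance(r, AtomRecord)]


# --- residue renumbering ----------------------------------------------------

def test_reres_identity_when_already_consecutive(basic):
    text, _ = basic
    assert render(renumber_residues(records_from_text(text), 1)) == text


def test_reres_first_appearance_order_and_icode_clearing():
    """Residues 5, 5A, 6 (insertion codes) become 1, 2, 3 with blank icodes."""
    text, _ = make_structure(FixtureSpec(n_chains=1, residues_per_chain=6,
                                         atoms_per_residue=2,
                                         insertion_codes=True, seed=9))
    src = atoms(records_from_text(text))
    assert any(a.icode != " " for a in src)   # fixture really has insertions
    out = atoms(renumber_residues(records_from_text(text), 1))
    seen: list[int] = []
    for a in out:
        if not seen or a.resseq != seen[-1]:
            seen.append(a.resseq)
        assert a.icode == " "
    assert seen == list(range(1, len(seen) + 1))


def test_reres_preserves_everything_but_numbering(messy):
    text, _ = messy
    src = atoms(records_from_text(text))
    out = atoms(renumber_residues(records_from_text(text), 1))
    assert len(src) == len(out)
    for a, b in zip(src, out):
        assert (a.serial, a.name, a.x, a.y, a.z, a.occupancy, a.bfactor,
                a.chain) == (b.serial, b.name, b.x, b.y, b.z, b.occupancy,
                             b.bfactor, b.chain)


def test_reres_per_chain_and_per_model(multimodel):
    text, _ = multimodel
    out = atoms(renumber_residues(records_from_text(text), 1))
    firsts = {}
    for a in out:
        firsts.setdefault(a.chain, a.resseq)
    assert set(firsts.values()) == {1}


def test_reres_overflow_is_an_error():
    text, _ = make_structure(FixtureSpec(n_chains=1, residues_per_chain=3,
                                         atoms_per_residue=1, seed=0))
    with pytest.raises(FormatOverflowError):
        list(renumber_residues(records_from_text(text), 9999))


# --- serial renumbering -----------------------------------------------------

def test_reatom_identity_on_consecutive_serials(basic):
    text, _ = basic
    assert render(renumber_serials(records_from_text(text), 1)) == text


def test_reatom_is_stable_under_repetition(messy):
    text, _ = messy
    once = render(renumber_serials(records_from_text(text), 1))
    assert render(renumber_serials(records_from_text(once), 1)) == once


def test_reatom_anisou_copies_parent_serial():
    text = "\n".join(ANISOU_PAIR)
    out = list(renumber_serials(records_from_text(text), 500))
    atom, anisou = out
    assert isinstance(anisou, AnisouRecord)
    assert atom.serial == anisou.serial == 500


def test_merge_then_renumber_counts_ter(basic):
    text, tallies = basic
    merged = list(merge_streams([records_from_text(text), records_from_text(text)]))
    n_coord = sum(1 for r in merged if isinstance(r, (AtomRecord, TerRecord)))
    assert n_coord == 2 * (tallies["n_atom"] + tallies["n_hetatm"] + tallies["n_ter"])
    serials = [r.serial for r in merged if isinstance(r, (AtomRecord, TerRecord))]
    assert serials == list(range(1, n_coord + 1))


# --- merge ------------------------------------------------------------------

def test_merge_conserves_coordinate_records(messy):
    text, tallies = messy
    k = 8
    merged = render(merge_streams([records_from_text(text) for _ in range(k)]))
    n = tallies["n_atom"] + tallies["n_hetatm"]
    assert len(atoms(records_from_text(merged))) == k * n
    assert sum(1 for ln in merged.splitlines() if ln.rstrip() == "END") == 1


def test_merge_roundtrip_through_chain_selection(basic):
    text, _ = basic
    a_only = render(select_chains(records_from_text(text), {"A"}))
    b_only = render(select_chains(records_from_text(text), {"B"}))
    merged = merge_streams([records_from_text(a_only), records_from_text(b_only)])
    back = render(select_chains(merged, {"A"}))
    back_atoms = atoms(records_from_text(back))
    orig_atoms = atoms(records_from_text(a_only))
    assert [(-1, a.atom_name, a.resseq, a.x) for a in back_atoms] == \
        [(-1, a.atom_name, a.resseq, a.x) for a in orig_atoms]


def test_merge_requires_two_streams(basic):
    text, _ = basic
    with pytest.raises(UsageError):
        list(merge_streams([records_from_text(text)]))


def test_rename_chains(basic):
    text, _ = basic
    out = atoms(rename_chains(records_from_text(text), "X"))
    assert {a.chain for a in out} == {"X"}


# --- sort -------------------------------------------------------------------

def test_sort_identity_on_sorted_input(basic):
    text, _ = basic
    assert render(sort_records(records_from_text(text))) == text


def test_sort_matches_total_order_oracle(messy):
    """Shuffled residues sort back to the brute-force total order."""
    text, _ = messy
    recs = list(records_from_text(text))
    rng = random.Random(4)
    atom_recs = [r for r in recs if isinstance(r, AtomRecord)]
    rng.shuffle(atom_recs)
    shuffled = render(iter(atom_recs))
    got = atoms(sort_records(records_from_text(shuffled)))
    oracle = sorted(atom_recs, key=lambda a: (a.chain, a.resseq, a.icode, a.serial))
    assert [(a.chain, a.resseq, a.icode, a.serial) for a in got] == \
        [(a.chain, a.resseq, a.icode, a.serial) for a in oracle]


def test_sort_is_idempotent(messy):
    text, _ = messy
    once = render(sort_records(records_from_text(text)))
    assert render(sort_records(records_from_text(once))) == once


# --- tidy -------------------------------------------------------------------

def tidied(text: str) -> str:
    return render(tidy(records_from_text(text)))


def test_tidy_output_validates_cleanly(basic, messy, multimodel):
    for text, _ in (basic, messy, multimodel):
        issues = validate_text(tidied(text))
        assert [i for i in issues if i.severity == "error"] == []


def test_tidy_is_idempotent(messy, multimodel):
    for text, _ in (messy, multimodel):
        once = tidied(text)
        assert tidied(once) == once


def test_tidy_repairs_dangling_ter_and_interior_end(basic):
    text, tallies = basic
    lines = text.splitlines()
    lines.insert(2, "TER")                       # dangling
    lines.insert(10, "END")                      # interior
    broken = "\n".join(lines) + "\n"
    assert any(i.rule in ("DANGLING_TER", "END_PLACEMENT")
               for i in validate_text(broken))
    fixed = tidied(broken)
    assert [i for i in validate_text(fixed) if i.severity == "error"] == []
    ters = [r for r in records_from_text(fixed) if isinstance(r, TerRecord)]
    assert len(ters) == tallies["n_ter"]         # one per ATOM-bearing chain


def test_tidy_single_chain_pipeline_ends_with_ter_and_end(basic):
    text, _ = basic
    out = render(tidy(select_chains(records_from_text(text), {"A"})))
    lines = [ln for ln in out.splitlines()]
    assert all(len(ln) == 80 for ln in lines)
    coord = [ln for ln in lines if ln[:6].strip() in
             ("ATOM", "HETATM", "TER", "END")]
    assert coord[-1].startswith("END")
    assert coord[-2].startswith("TER")
    chains = {ln[21] for ln in lines if ln.startswith("ATOM")}
    assert chains == {"A"}


def test_tidy_gives_no_ter_to_pure_hetatm_chain():
    text, _ = make_structure(FixtureSpec(n_chains=1, residues_per_chain=3,
                                         atoms_per_residue=2, hetatm_groups=4,
                                         seed=21))
    out = tidied(text)
    ters = [r for r in records_from_text(out) if isinstance(r, TerRecord)]
    assert [t.chain for t in ters] == ["A"]      # waters live on chain B, no TER
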