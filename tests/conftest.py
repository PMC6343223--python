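"""Shared fixtures: synthetic structures with ground-truth tallies and an
in-process tool runner."""

from __future__ import annotations

import io

import pytest

from pdbtk.cli import run_tool
from pdbtk.fixtures import FixtureSpec, make_structure

# a hand-written ATOM/ANISOU pair (exact 80-column layout) for tensor-line tests
ANISOU_PAIR = [
    "ATOM      1  CA  GLU A   1      17.706  17.982 -14.905  1.00 16.74           C  ",
    "ANISOU    1  CA  GLU A   1     2406   1892   1614    198    519   -328       C  ",
]


def run(name: str, argv: list[str], input_text: str = "") -> tuple[int, str, str]:
    """Run one CLI tool in-process; returns (exit code, stdout, stderr)."""
    out, err = io.StringIO(), io.StringIO()
    code = run_tool(name, argv, stdin=io.StringIO(input_text), stdout=out, stderr=err)
    return code, out.getvalue(), err.getvalue()


@pytest.fixture(scope="session")
def basic():
    """Two chains, five residues of four atoms, no complications."""
    return make_structure(FixtureSpec(n_chains=2, residues_per_chain=5,
                                      atoms_per_residue=4, seed=7))


@pytest.fixture(scope="session")
def messy():
    """Altlocs, insertion codes, waters, negative residue numbers."""
    return make_structure(FixtureSpec(
        n_chains=3, residues_per_chain=8, atoms_per_residue=6,
        altloc_fraction=0.4, hetatm_groups=5, insertion_codes=True,
        negative_start=True, seed=11))


@pytest.fixture(scope="session")
def multimodel():
    return make_structure(FixtureSpec(n_chains=2, residues_per_chain=4,
                                      atoms_per_residue=4, n_models=3, seed=3))


@pytest.fixture(scope="session")
def big():
    """Large enough to exercise the round-trip on >10^4 coordinate lines."""
    return make_structure(FixtureSpec(n_chains=3, residues_per_chain=250,
                                      atoms_per_residue=14, seed=5))
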