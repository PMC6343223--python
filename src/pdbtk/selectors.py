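"""Subsetting and deletion operations.

Every operation here is a *filter*: it takes an iterable of records and
yields a subset (altloc selection may additionally blank the altloc flag of
the surviving copy).  Relative record order is always preserved and
non-coordinate records pass through untouched, so filters compose freely in
pipelines and are idempotent.

An ANISOU record always shares the fate of the atom immediately preceding
it: when a filter drops an atom, its tensor line is dropped too.
"""

from __future__ import annotations

import sys
from dataclasses import replace
from typing import Callable, Iterable, Iterator

from .records import (
    AnisouRecord,
    AtomRecord,
    Record,
    TerRecord,
    element_of,
    is_coordinate,
)

__all__ = [
    "UsageError",
    "parse_chain_option",
    "parse_residue_ranges",
    "parse_name_option",
    "select_chains",
    "select_residue_ranges",
    "select_atom_names",
    "select_altloc",
    "delete_hetatm",
    "delete_element",
    "keep_coordinates",
]

OPEN = None  # open end of a residue range


class UsageError(Exception):
    """A malformed selection option (empty set, bad range grammar, ...)."""


# ---------------------------------------------------------------------------
# option grammar: comma-separated items; range item = N | N:M | N: | :M
# ---------------------------------------------------------------------------

def parse_chain_option(option: str) -> set[str]:
    chains = {c for c in option.split(",") if c}
    if not chains:
        raise UsageError("no chain identifiers given")
    bad = [c for c in chains if len(c) != 1]
    if bad:
        raise UsageError(f"chain identifiers must be one character: {bad}")
    return chains


def parse_residue_ranges(option: str) -> list[tuple[int | None, int | None]]:
    """Parse "1:30,45,60:" into inclusive (lo, hi) pairs; None is an open end."""
    ranges: list[tuple[int | None, int | None]] = []
    for item in option.split(","):
        item = item.strip()
        if not item:
            continue
        # split on the range colon; a leading '-' belongs to a negative number
        if ":" in item:
            lo_s, hi_s = item.split(":", 1)
            try:
                lo = int(lo_s) if lo_s else OPEN
                hi = int(hi_s) if hi_s else OPEN
            except ValueError:
                raise UsageError(f"malformed residue range {item!r}") from None
            if lo is not OPEN and hi is not OPEN and lo > hi:
                raise UsageError(f"empty residue range {item!r} (lo > hi)")
        else:
            try:
                lo = hi = int(item)
            except ValueError:
                raise UsageError(f"malformed residue number {item!r}") from None
        ranges.append((lo, hi))
    if not ranges:
        raise UsageError("no residue ranges given")
    return ranges


def parse_name_option(option: str) -> set[str]:
    names = {n.strip() for n in option.split(",") if n.strip()}
    if not names:
        raise UsageError("no atom names given")
    return names


# ---------------------------------------------------------------------------
# the generic atom filter: predicates on AtomRecord, ANISOU follows its atom
# ---------------------------------------------------------------------------

def _filter_atoms(records: Iterable[Record],
                  keep: Callable[[AtomRecord], bool],
                  keep_ter: Callable[[TerRecord], bool] = lambda t: True,
                  ) -> Iterator[Record]:
    last_atom_kept = True
    for r in records:
        if isinstance(r, AtomRecord):
            last_atom_kept = keep(r)
            if last_atom_kept:
                yield r
        elif isinstance(r, AnisouRecord):
            if last_atom_kept:
                yield r
        elif isinstance(r, TerRecord):
            if keep_ter(r):
                yield r
        else:
            yield r


def select_chains(records: Iterable[Record], chains: set[str]) -> Iterator[Record]:
    """Keep coordinate records of the given chains; TER follows its chain."""
    if not chains:
        raise UsageError("no chain identifiers given")
    return _filter_atoms(records,
                         keep=lambda a: a.chain in chains,
                         keep_ter=lambda t: t.chain in chains or t.chain == " ")


def select_residue_ranges(records: Iterable[Record],
                          ranges: list[tuple[int | None, int | None]],
                          ) -> Iterator[Record]:
    """Keep atoms whose residue number falls in any inclusive range.

    Applies to ATOM and HETATM alike (a residue filter, not a polymer
    filter).  TER records pass through; a selection that empties a chain may
    leave a dangling TER, which ``tidy`` repairs.
    """
    if not ranges:
        raise UsageError("no residue ranges given")

    def in_ranges(a: AtomRecord) -> bool:
        return any((lo is OPEN or a.resseq >= lo) and (hi is OPEN or a.resseq <= hi)
                   for lo, hi in ranges)

    return _filter_atoms(records, keep=in_ranges)


def select_atom_names(records: Iterable[Record], names: set[str]) -> Iterator[Record]:
    """Keep only ATOM/HETATM records whose stripped atom name matches."""
    if not names:
        raise UsageError("no atom names given")
    return _filter_atoms(records, keep=lambda a: a.atom_name in names)


def delete_hetatm(records: Iterable[Record]) -> Iterator[Record]:
    """Remove HETATM records (waters included) and their ANISOU lines."""
    return _filter_atoms(records, keep=lambda a: a.kind != "HETATM")


def delete_element(records: Iterable[Record], elements: set[str]) -> Iterator[Record]:
    """Remove atoms of the given elements (name-derived when cols 77-78 blank)."""
    if not elements:
        raise UsageError("no element symbols given")
    elements = {e.strip().upper() for e in elements}
    return _filter_atoms(records, keep=lambda a: element_of(a) not in elements)


def keep_coordinates(records: Iterable[Record]) -> Iterator[Record]:
    """Drop all non-coordinate content (headers, REMARK, CONECT, ...)."""
    return (r for r in records if is_coordinate(r))


# ---------------------------------------------------------------------------
# altloc resolution
# ---------------------------------------------------------------------------

def select_altloc(records: Iterable[Record],
                  loc: str | None = None,
                  warn: Callable[[str], None] | None = None,
                  ) -> Iterator[Record]:
    """Resolve alternate locations, keeping one position per atom.

    For every (residue, atom-name) group with more than one altloc — or a
    lone atom flagged with one — exactly one copy survives: the explicitly
    requested ``loc`` when given, else the highest-occupancy copy (ties go to
    file order).  The survivor's altloc flag is blanked.  Atoms with a blank
    altloc pass through unchanged.  When an explicit ``loc`` is absent from a
    conflicted group the whole group is dropped and a warning emitted.

    Buffers one residue at a time.
    """
    if warn is None:
        warn = lambda msg: print(msg, file=sys.stderr)  # noqa: E731

    buffer: list[Record] = []
    current_key: tuple[str, int, str] | None = None

    def flush() -> Iterator[Record]:
        if not buffer:
            return
        # group atom indices by stripped name
        by_name: dict[str, list[int]] = {}
        for i, r in enumerate(buffer):
            if isinstance(r, AtomRecord):
                by_name.setdefault(r.atom_name, []).append(i)
        drop: set[int] = set()
        blank: set[int] = set()
        for name, idxs in by_name.items():
            atoms = [(i, buffer[i]) for i in idxs]
            if all(a.altloc == " " for _, a in atoms):
                continue
            if loc is not None:
                chosen = [i for i, a in atoms if a.altloc == loc or a.altloc == " "]
                if not chosen:
                    a0 = atoms[0][1]
                    warn(f"altloc {loc!r} absent for atom {name} of "
                         f"{a0.resname_id} {a0.chain}{a0.resseq}; group dropped")
                    drop.update(i for i, _ in atoms)
                    continue
                survivor = chosen[0]
            else:
                survivor = max(atoms, key=lambda ia: ia[1].occupancy)[0]
            drop.update(i for i, _ in atoms if i != survivor)
            blank.add(survivor)
        for i, r in enumerate(buffer):
            if isinstance(r, AtomRecord):
                if i in drop:
                    continue
                if i in blank and r.altloc != " ":
                    yield replace(r, altloc=" ")
                else:
                    yield r
            elif isinstance(r, AnisouRecord):
                # tensor follows its atom (the record right before it)
                if i - 1 in drop:
                    continue
                if i - 1 in blank and r.altloc != " ":
                    yield replace(r, altloc=" ")
                else:
                    yield r
            else:
                yield r
        buffer.clear()

    for r in records:
        if isinstance(r, (AtomRecord, AnisouRecord)):
            key = (r.chain, r.resseq, r.icode)
            if key != current_key:
                yield from flush()
                current_key = key
            buffer.append(r)
        else:
            yield from flush()
            current_key = None
            yield r
    yield from flush()
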