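"""Mutating and assembling operations: renumbering, merging, sorting, tidying.

Renumbering operations stream (one-residue state); ``merge_streams`` and
``sort_records`` buffer by construction, and ``tidy`` buffers one MODEL block
to find the final polymer residue of each chain.  All operations preserve
atom names and coordinates bit-exact; only the bookkeeping fields they are
defined to change (serial, resseq, icode, chain, TER/END placement) change.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Iterator, Sequence

from .records import (
    AnisouRecord,
    AtomRecord,
    FormatOverflowError,
    ModelRecord,
    OtherRecord,
    Record,
    RESSEQ_MAX,
    SERIAL_MAX,
    TerRecord,
    pad80,
)
from .selectors import UsageError

__all__ = [
    "renumber_residues",
    "renumber_serials",
    "rename_chains",
    "merge_streams",
    "sort_records",
    "tidy",
]


def renumber_residues(records: Iterable[Record], start: int = 1) -> Iterator[Record]:
    """Renumber residues consecutively from ``start`` within each chain.

    Residues are numbered in order of first appearance in the file (per chain,
    per model), which makes the operation robust to unsorted input; compose
    with :func:`sort_records` first when numeric order is wanted.  Insertion
    codes are cleared — the new numbering is gap-free, so they carry no
    information.  ANISOU lines and TER records inherit the renumbering of
    their residue.
    """
    model = 0
    mapping: dict[tuple[int, str, int, str], int] = {}
    next_num: dict[tuple[int, str], int] = {}
    for r in records:
        if isinstance(r, ModelRecord):
            model = r.number
            yield r
        elif isinstance(r, (AtomRecord, AnisouRecord)):
            key = (model, r.chain, r.resseq, r.icode)
            if key not in mapping:
                n = next_num.get((model, r.chain), start)
                if n > RESSEQ_MAX:
                    raise FormatOverflowError("resseq", n)
                mapping[key] = n
                next_num[(model, r.chain)] = n + 1
            yield replace(r, resseq=mapping[key], icode=" ")
        elif isinstance(r, TerRecord) and r.resseq is not None:
            key = (model, r.chain, r.resseq, r.icode)
            new = mapping.get(key, next_num.get((model, r.chain), start) - 1)
            yield replace(r, resseq=new, icode=" ")
        else:
            yield r


def renumber_serials(records: Iterable[Record], start: int = 1) -> Iterator[Record]:
    """Renumber atom serials consecutively from ``start``.

    One continuous sequence across ATOM/HETATM/TER records (TER consumes a
    serial, per the format); ANISOU copies the serial of its parent atom.
    """
    n = start
    last = start
    for r in records:
        if isinstance(r, AtomRecord):
            if n > SERIAL_MAX:
                raise FormatOverflowError("serial", n)
            last = n
            yield replace(r, serial=n)
            n += 1
        elif isinstance(r, AnisouRecord):
            yield replace(r, serial=last)
        elif isinstance(r, TerRecord):
            if n > SERIAL_MAX:
                raise FormatOverflowError("serial", n)
            yield replace(r, serial=n)
            n += 1
        else:
            yield r


def rename_chains(records: Iterable[Record], chain: str) -> Iterator[Record]:
    """Set the chain identifier of every coordinate record."""
    if len(chain) != 1:
        raise UsageError("chain identifier must be exactly one character")
    for r in records:
        if isinstance(r, (AtomRecord, AnisouRecord, TerRecord)):
            yield replace(r, chain=chain)
        else:
            yield r


def merge_streams(streams: Sequence[Iterable[Record]]) -> Iterator[Record]:
    """Concatenate structures in argument order into one document.

    Coordinate records are concatenated, END records collapsed to a single
    final one, and serials renumbered from 1.  Chain identifier collisions
    are *not* resolved (the validator reports duplicate atoms); use
    :func:`rename_chains` on the inputs first.
    """
    if len(streams) < 2:
        raise UsageError("merge needs at least two input structures")

    def concat() -> Iterator[Record]:
        for stream in streams:
            for r in stream:
                if isinstance(r, OtherRecord) and r.tag == "END":
                    continue
                yield r
        yield OtherRecord(tag="END", text="END")

    return renumber_serials(concat())


def _sort_key_assigner():
    """Closure mapping records to sortable keys in one forward pass."""
    state = {"model": 0, "atom_key": (0, " ", 0, " ", 0)}

    def key(r: Record):
        if isinstance(r, AtomRecord):
            k = (state["model"], r.chain, r.resseq, r.icode, r.serial)
            state["atom_key"] = k
            return (*k, 0)
        if isinstance(r, AnisouRecord):
            return (*state["atom_key"], 1)   # tensor stays glued to its atom
        if isinstance(r, TerRecord):
            if r.resseq is not None:
                return (state["model"], r.chain, r.resseq, r.icode, SERIAL_MAX + 1, 2)
            return (*state["atom_key"], 2)
        raise AssertionError("only atom-level records are sorted")

    return state, key


def sort_records(records: Iterable[Record]) -> Iterator[Record]:
    """Stably sort coordinate records by (model, chain, resseq, icode, serial).

    The header block stays before the coordinates, MODEL/ENDMDL brackets are
    preserved around each model's sorted block, and END stays last.  Buffers
    the whole stream (documented exception to the streaming contract).
    """
    header: list[Record] = []
    trailer: list[Record] = []
    models: dict[int, list[tuple[tuple, Record]]] = {}
    state, key = _sort_key_assigner()
    seen_model_records = False

    for r in records:
        if isinstance(r, ModelRecord):
            state["model"] = r.number
            seen_model_records = True
            models.setdefault(r.number, [])
        elif isinstance(r, (AtomRecord, AnisouRecord, TerRecord)):
            models.setdefault(state["model"], []).append((key(r), r))
        elif isinstance(r, OtherRecord) and r.tag in ("END", "ENDMDL"):
            if r.tag == "END":
                trailer.append(r)
        elif not models:
            header.append(r)
        else:
            trailer.append(r)

    yield from header
    for model_num in sorted(models):
        if seen_model_records:
            yield ModelRecord(number=model_num)
        block = models[model_num]
        block.sort(key=lambda kr: kr[0])
        for _, r in block:
            yield r
        if seen_model_records:
            yield OtherRecord(tag="ENDMDL", text="ENDMDL")
    yield from trailer


def tidy(records: Iterable[Record]) -> Iterator[Record]:
    """Normalise a document's structural bookkeeping.

    Output lines are padded to 80 columns; every chain that contains ATOM
    records gets exactly one TER after its final polymer residue (per model);
    pure-HETATM chains get none; pre-existing TER and interior END records
    are discarded and rebuilt; exactly one END terminates the document; atom
    serials are renumbered from 1.  Idempotent, and its output validates
    cleanly.
    """
    def strip_and_place() -> Iterator[Record]:
        buffer: list[Record] = []   # one model block (or the whole single-model doc)

        def flush_block() -> Iterator[Record]:
            # index of the last ATOM record of each chain in this block
            last_atom: dict[str, int] = {}
            for i, r in enumerate(buffer):
                if isinstance(r, AtomRecord) and r.kind == "ATOM":
                    last_atom[r.chain] = i
            # an ANISOU directly after the last ATOM belongs before the TER
            for chain, i in list(last_atom.items()):
                j = i
                while j + 1 < len(buffer) and isinstance(buffer[j + 1], AnisouRecord):
                    j += 1
                last_atom[chain] = j
            for i, r in enumerate(buffer):
                yield r
                for chain, idx in last_atom.items():
                    if i == idx:
                        a = buffer[i]
                        ref = a if isinstance(a, AtomRecord) else buffer[i - 1]
                        yield TerRecord(serial=0, resname=ref.resname,
                                        chain=ref.chain, resseq=ref.resseq,
                                        icode=ref.icode)
            buffer.clear()

        for r in records:
            if isinstance(r, TerRecord):
                continue                      # rebuilt below
            if isinstance(r, OtherRecord) and r.tag == "END":
                continue                      # single END appended at the end
            if isinstance(r, ModelRecord):
                yield from flush_block()
                yield r
            elif isinstance(r, OtherRecord) and r.tag == "ENDMDL":
                yield from flush_block()
                yield r
            elif isinstance(r, (AtomRecord, AnisouRecord)):
                buffer.append(r)
            else:
                yield from flush_block()
                yield OtherRecord(tag=r.tag, text=pad80(r.text), lineno=r.lineno)
        yield from flush_block()
        yield OtherRecord(tag="END", text="END")

    return renumber_serials(strip_and_place())
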