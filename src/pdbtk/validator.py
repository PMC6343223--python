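"""Format validation: check PDB text against the record grammar and the
structural bookkeeping rules, reporting machine-readable issues.

The validator is read-only and total: it never raises on bad input — every
problem becomes a :class:`ValidationIssue` with a line number, a rule id and
a severity.  Formatting violations are errors; stylistic shortcomings that
do not impede interoperation (a missing element field, chains out of order)
are warnings.

Rules checked
-------------
``LINE_TOO_LONG``   line exceeds 80 characters (error)
``NON_ASCII``       non-ASCII byte in the line (error)
``UNKNOWN_RECORD``  record name outside the standard vocabulary (error)
``BAD_FIELD``       numeric field unparseable at its columns (error)
``SERIAL_ORDER``    atom serials not strictly increasing within a model (error)
``DUP_ATOM``        duplicate (residue, atom name, altloc) within a model (error)
``MISSING_END``     document does not end with END (error)
``END_PLACEMENT``   records after END, or more than one END (error)
``DANGLING_TER``    TER with no preceding atoms in its chain section (error)
``MODEL_PAIRING``   MODEL/ENDMDL not properly paired (error)
``MISSING_ELEMENT`` ATOM/HETATM with blank element columns (warning)
``UNSORTED_CHAIN``  a chain's records resume after another chain intervened
                    (warning)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .records import (
    AtomRecord,
    AnisouRecord,
    ModelRecord,
    OtherRecord,
    ParseError,
    RECORD_NAMES,
    TerRecord,
    parse_line,
)

__all__ = ["ValidationIssue", "validate_lines", "validate_text"]


@dataclass(frozen=True)
class ValidationIssue:
    lineno: int
    rule: str
    severity: str          # "error" | "warning"
    message: str

    def __str__(self) -> str:
        return f"{self.lineno}:{self.severity}:{self.rule}:{self.message}"


def validate_text(text: str) -> list[ValidationIssue]:
    return validate_lines(text.splitlines())


def validate_lines(lines: Iterable[str]) -> list[ValidationIssue]:
    """Validate raw PDB lines; returns a deterministic, line-ordered issue list."""
    issues: list[ValidationIssue] = []

    def add(lineno: int, rule: str, severity: str, message: str) -> None:
        issues.append(ValidationIssue(lineno, rule, severity, message))

    last_serial: int | None = None
    seen_atoms: set[tuple[int, str, int, str, str, str]] = set()
    model = 0
    model_open = False
    end_seen_at: int | None = None
    atoms_since_chain_start = 0
    closed_chains: set[tuple[int, str]] = set()
    current_chain: str | None = None
    lineno = 0

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r\n")
        if len(line.rstrip()) > 80:
            add(lineno, "LINE_TOO_LONG", "error",
                f"line is {len(line.rstrip())} characters (max 80)")
        if not line.isascii():
            add(lineno, "NON_ASCII", "error", "non-ASCII character in line")
            continue
        tag = line[0:6].strip()
        if not tag:
            continue
        if tag not in RECORD_NAMES:
            add(lineno, "UNKNOWN_RECORD", "error",
                f"record name {tag!r} is not a standard PDB record")
            continue
        if end_seen_at is not None:
            add(lineno, "END_PLACEMENT", "error",
                f"record after END (END at line {end_seen_at})")
        try:
            r = parse_line(line, lineno)
        except ParseError as exc:
            add(lineno, "BAD_FIELD", "error", str(exc))
            continue

        if isinstance(r, ModelRecord):
            if model_open:
                add(lineno, "MODEL_PAIRING", "error",
                    f"MODEL {r.number} opened before previous MODEL closed")
            model_open = True
            model = r.number
            last_serial = None
            current_chain = None
            atoms_since_chain_start = 0
        elif isinstance(r, OtherRecord) and r.tag == "ENDMDL":
            if not model_open:
                add(lineno, "MODEL_PAIRING", "error", "ENDMDL without open MODEL")
            model_open = False
            current_chain = None
        elif isinstance(r, OtherRecord) and r.tag == "END":
            end_seen_at = lineno
        elif isinstance(r, AtomRecord):
            if last_serial is not None and r.serial <= last_serial:
                add(lineno, "SERIAL_ORDER", "error",
                    f"serial {r.serial} not greater than previous {last_serial}")
            last_serial = r.serial
            key = (model, r.chain, r.resseq, r.icode, r.atom_name, r.altloc)
            if key in seen_atoms:
                add(lineno, "DUP_ATOM", "error",
                    f"duplicate atom {r.atom_name} altloc {r.altloc!r} in "
                    f"residue {r.resname_id} {r.chain}{r.resseq}{r.icode.strip()}")
            seen_atoms.add(key)
            if not r.element.strip():
                add(lineno, "MISSING_ELEMENT", "warning",
                    "element columns 77-78 are blank")
            if r.chain != current_chain:
                # trailing HETATM groups (waters, ligands) conventionally
                # revisit earlier chains; only polymer records are checked
                if r.kind == "ATOM" and (model, r.chain) in closed_chains:
                    add(lineno, "UNSORTED_CHAIN", "warning",
                        f"chain {r.chain!r} resumes after other chains")
                if current_chain is not None:
                    closed_chains.add((model, current_chain))
                current_chain = r.chain
                atoms_since_chain_start = 0
            atoms_since_chain_start += 1
        elif isinstance(r, AnisouRecord):
            pass
        elif isinstance(r, TerRecord):
            if atoms_since_chain_start == 0:
                add(lineno, "DANGLING_TER", "error",
                    "TER without preceding coordinate records in its chain")
            if current_chain is not None:
                closed_chains.add((model, current_chain))
            current_chain = None
            atoms_since_chain_start = 0
            if r.serial is not None and last_serial is not None:
                if r.serial <= last_serial:
                    add(lineno, "SERIAL_ORDER", "error",
                        f"TER serial {r.serial} not greater than previous "
                        f"{last_serial}")
                else:
                    last_serial = r.serial

    if model_open:
        add(lineno, "MODEL_PAIRING", "error", "MODEL never closed by ENDMDL")
    if end_seen_at is None and lineno > 0:
        add(lineno, "MISSING_END", "error", "document does not end with END")
    issues.sort(key=lambda i: (i.lineno, i.rule))
    return issues
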